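"""Synthetic multiplexed CITE-seq experiments with per-droplet ground truth.

The generator emulates a cell-hashing design: PBMC-like cells from several
donors are cultured under a small set of conditions (baseline, LPS,
anti-CD3/CD28), each condition is tagged with one hashtag oligo (HTO), and
everything is pooled into one droplet run. A droplet may be empty (ambient
material only), contain one cell, a cross-condition doublet/triplet
(co-encapsulation of cells carrying different hashtags), a cross-donor
doublet (same condition, two donors), or a biological cross-cell-type
doublet (two interacting cells from the same sample).

Counts are negative binomial in a mean/dispersion parameterization
(variance = mu + dispersion * mu^2). HTO counts are bimodal: every droplet
sees a fixed ambient background per tag, and each contained cell adds
``hto_separation`` x background to its condition's tag. RNA is structured by
cell type (constitutive marker genes) and by a continuous activation level
in [0, 1] that scales two waves of activation-signature genes: an early
wave peaking mid-gradient and a late wave rising monotonically — so
pseudotime recovery against the planted gradient is well-posed. Surface
proteins (ADTs) follow per-type positive/negative profiles, with CD45RA/RO
splitting T cells into naive/memory and CD69/CD25 marking activation.

Ground truth records, per droplet, the hashing-visible kind (the number of
distinct condition tags present: empty/singlet/doublet/triplet), the
contained conditions, donors and cell types, and the mean activation level.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import MultiModalCounts

DEFAULT_CONDITIONS = ("baseline", "LPS", "aCD3CD28")

# 39-plex surface panel (BioLegend-style PBMC immunophenotyping panel)
DEFAULT_ADT_PANEL = (
    "CD3", "CD4", "CD8", "CD14", "CD16", "CD19", "CD20", "CD56", "CD11c",
    "CD28", "CD45RA", "CD45RO", "CD69", "CD25", "CD5", "CD7", "CD127",
    "CD11b", "CD33", "CD40", "HLA-DR", "CD57", "CD2", "CD10", "CD27",
    "CD38", "CD44", "CD48", "CD52", "CD58", "CD62L", "CD71", "CD80",
    "CD86", "CD95", "CD161", "CCR6", "CCR7", "PD-1",
)

_N_MARKER_GENES = 25          # constitutive marker genes per cell type
_N_WAVE_GENES = 15            # genes per activation wave (early / late)
_SIGNATURE_START = 200        # first gene index used for activation waves


@dataclass(frozen=True)
class CellTypeProfile:
    """One simulated cell type: frequency, surface profile, gene programs."""

    name: str
    frequency: float
    adt_positive: tuple[str, ...]
    marker_genes: tuple[str, ...] = ()
    signature_early: tuple[str, ...] = ()
    signature_late: tuple[str, ...] = ()

    @property
    def signature(self) -> tuple[str, ...]:
        return self.signature_early + self.signature_late


def _gene(i: int) -> str:
    return f"G{i:04d}"


def default_cell_types() -> tuple[CellTypeProfile, ...]:
    """Five PBMC populations with frequencies in the range typical of blood.

    Marker-gene and activation-signature indices are fixed slices of the
    gene panel so that the bundled inflammation stand-in panel (the monocyte
    activation signature) is stable across runs.
    """
    specs = [
        ("CD4_T", 0.40, ("CD3", "CD4", "CD5", "CD7", "CD28", "CD127", "CD2")),
        ("CD8_T", 0.25, ("CD3", "CD8", "CD5", "CD7", "CD2")),
        ("CD14_monocyte", 0.18, ("CD14", "CD11c", "CD11b", "CD33", "HLA-DR")),
        ("NK", 0.10, ("CD56", "CD16", "CD7", "CD57")),
        ("B", 0.07, ("CD19", "CD20", "CD40", "HLA-DR")),
    ]
    out = []
    for i, (name, freq, adt) in enumerate(specs):
        markers = tuple(_gene(j) for j in
                        range(i * _N_MARKER_GENES, (i + 1) * _N_MARKER_GENES))
        s0 = _SIGNATURE_START + i * 2 * _N_WAVE_GENES
        early = tuple(_gene(j) for j in range(s0, s0 + _N_WAVE_GENES))
        late = tuple(_gene(j) for j in
                     range(s0 + _N_WAVE_GENES, s0 + 2 * _N_WAVE_GENES))
        out.append(CellTypeProfile(name, freq, adt, markers, early, late))
    return tuple(out)


def default_activation_gradient() -> dict[str, dict[str, float]]:
    """Per-condition, per-type maximum activation: LPS hits only monocytes;
    anti-CD3/CD28 hits T cells directly and NK/B cells indirectly."""
    return {
        "baseline": {},
        "LPS": {"CD14_monocyte": 1.0},
        "aCD3CD28": {"CD4_T": 1.0, "CD8_T": 1.0, "NK": 0.7, "B": 0.5},
    }


def default_inflammation_panel() -> list[str]:
    """Stand-in inflammation gene panel.

    The monocyte late activation wave: pro-inflammatory mediators rise
    monotonically with activation, whereas the early wave (alarmin-like
    genes) peaks mid-trajectory and does not belong to an inflammation
    panel.
    """
    for ct in default_cell_types():
        if ct.name == "CD14_monocyte":
            return list(ct.signature_late)
    raise RuntimeError("default cell types lack a CD14_monocyte profile")


@dataclass
class SynthConfig:
    """Configuration of one synthetic multiplexed experiment.

    Rates are probabilities over droplets; ``hto_separation`` is the ratio of
    a positive tag's mean to the ambient background mean and must exceed 1.
    """

    n_donors: int = 10
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_droplets: int = 20000
    n_genes: int = 1500
    cell_types: tuple[CellTypeProfile, ...] = field(
        default_factory=default_cell_types)
    empty_rate: float = 0.09
    cross_condition_multiplet_rate: float = 0.13
    triplet_fraction: float = 0.10      # of cross-condition multiplets
                                        # (Poisson co-encapsulation ratio)
    cross_donor_doublet_rate: float = 0.02
    cross_celltype_doublet_rate: float = 0.02
    donor_ambiguous_rate: float = 0.02
    empty_ambiguous_rate: float = 0.85
    activation_gradient: dict[str, dict[str, float]] = field(
        default_factory=default_activation_gradient)
    hto_separation: float = 8.0
    hto_background_mean: float = 50.0   # nonspecific tag counts per cell
    hto_ambient_mean: float = 0.05      # free-antibody counts per tag, any droplet
    hto_dispersion: float = 0.05
    nb_dispersion: float = 0.3
    mean_umis: float = 1900.0
    libsize_sigma: float = 0.35
    ambient_umis: float = 50.0
    adt_positive_mean: float = 500.0
    adt_negative_mean: float = 5.0
    adt_ambient_mean: float = 3.0
    activation_amplitude: float = 6.0
    cd69_level: float = 0.2             # activation level turning CD69 on
    cd25_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 10:
            raise ValueError("n_droplets must be at least 10")
        if not self.cell_types:
            raise ValueError("cell_types must not be empty")
        for name in ("empty_rate", "cross_condition_multiplet_rate",
                     "triplet_fraction", "cross_donor_doublet_rate",
                     "cross_celltype_doublet_rate", "donor_ambiguous_rate",
                     "empty_ambiguous_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = (self.empty_rate + self.cross_condition_multiplet_rate
                 + self.cross_donor_doublet_rate
                 + self.cross_celltype_doublet_rate)
        if total > 1.0:
            raise ValueError("droplet category rates sum above 1")
        freqs = sum(ct.frequency for ct in self.cell_types)
        if abs(freqs - 1.0) > 1e-8:
            raise ValueError(f"cell type frequencies sum to {freqs}, not 1")
        if self.hto_separation <= 1.0:
            raise ValueError("hto_separation must exceed 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        need = max(len(self.cell_types) * _N_MARKER_GENES,
                   _SIGNATURE_START
                   + len(self.cell_types) * 2 * _N_WAVE_GENES)
        if self.n_genes < need:
            raise ValueError(f"n_genes must be at least {need}")

    @property
    def gene_names(self) -> list[str]:
        return [_gene(i) for i in range(self.n_genes)]

    @property
    def hto_names(self) -> list[str]:
        return [f"HTO_{c}" for c in self.conditions]


@dataclass
class SimulatedExperiment:
    """Counts, the external donor-call table, and per-droplet ground truth."""

    counts: MultiModalCounts
    donor_calls: pd.DataFrame      # barcode, donor  (donor_id|ambiguous|doublet)
    ground_truth: pd.DataFrame
    cells: pd.DataFrame | None = None          # per-cell table (debug)
    rna_per_cell: sp.csr_matrix | None = None  # cells x genes (debug)


_KIND_NAMES = {0: "empty", 1: "singlet", 2: "doublet", 3: "triplet"}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu**2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.maximum(mu, 1e-300) * dispersion)
    lam[mu == 0] = 0.0
    return rng.poisson(lam)


def _early_factor(level: np.ndarray, amp: float) -> np.ndarray:
    """Early activation wave: a bump peaking at ~35% of the gradient."""
    return 1.0 + amp * np.exp(-((level - 0.35) ** 2) / (2 * 0.12**2))


def _late_factor(level: np.ndarray, amp: float) -> np.ndarray:
    """Late activation wave: rises monotonically toward full activation."""
    return 1.0 + amp * level**2


def simulate_experiment(config: SynthConfig,
                        return_cells: bool = False) -> SimulatedExperiment:
    """Generate one multiplexed experiment.

    Returns aligned RNA/ADT/HTO count matrices, a per-droplet donor-call
    table (standing in for genotype-based demultiplexing output) and the
    complete ground truth. With ``return_cells=True`` the per-cell RNA
    matrix and cell table are attached so that droplet counts can be checked
    against the sum of their contained cells.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_droplets
    n_cond = len(cfg.conditions)
    types = cfg.cell_types
    type_freqs = np.array([ct.frequency for ct in types])
    gene_index = {g: i for i, g in enumerate(cfg.gene_names)}
    adt_index = {p: i for i, p in enumerate(DEFAULT_ADT_PANEL)}
    grad = cfg.activation_gradient

    # --- droplet category -------------------------------------------------
    cat_p = np.array([
        cfg.empty_rate,
        cfg.cross_condition_multiplet_rate * (1 - cfg.triplet_fraction),
        cfg.cross_condition_multiplet_rate * cfg.triplet_fraction,
        cfg.cross_donor_doublet_rate,
        cfg.cross_celltype_doublet_rate,
    ])
    cat_p = np.append(cat_p, 1.0 - cat_p.sum())  # singlet
    category = rng.choice(6, size=n, p=cat_p)
    # categories: 0 empty, 1 cc-doublet, 2 cc-triplet, 3 donor-doublet,
    #             4 celltype-doublet, 5 singlet

    # --- contained cells --------------------------------------------------
    cell_rows: list[tuple[int, int, int, int]] = []  # droplet, cond, donor, type
    for d in range(n):
        c = category[d]
        if c == 0:
            continue
        if c == 1:                       # two distinct conditions
            conds = rng.choice(n_cond, size=2, replace=False)
            donors = rng.integers(0, cfg.n_donors, size=2)
            tps = rng.choice(len(types), size=2, p=type_freqs)
        elif c == 2:                     # three distinct conditions
            k = min(3, n_cond)
            conds = rng.choice(n_cond, size=k, replace=False)
            donors = rng.integers(0, cfg.n_donors, size=k)
            tps = rng.choice(len(types), size=k, p=type_freqs)
        elif c == 3:                     # same condition, two donors
            cond = rng.integers(0, n_cond)
            conds = np.array([cond, cond])
            donors = rng.choice(cfg.n_donors, size=2,
                                replace=cfg.n_donors < 2)
            tps = rng.choice(len(types), size=2, p=type_freqs)
        elif c == 4:                     # biological doublet: two cell types
            cond = rng.integers(0, n_cond)
            conds = np.array([cond, cond])
            donor = rng.integers(0, cfg.n_donors)
            donors = np.array([donor, donor])
            tps = rng.choice(len(types), size=2, replace=False,
                             p=type_freqs)
        else:                            # singlet
            conds = np.array([rng.integers(0, n_cond)])
            donors = np.array([rng.integers(0, cfg.n_donors)])
            tps = np.array([rng.choice(len(types), p=type_freqs)])
        for cond, donor, tp in zip(conds, donors, tps):
            cell_rows.append((d, int(cond), int(donor), int(tp)))

    cells = pd.DataFrame(cell_rows,
                         columns=["droplet", "condition", "donor", "cell_type"])
    n_cells = len(cells)

    # planted activation level: gradient ceiling x per-cell uniform draw
    ceiling = np.array([
        grad.get(cfg.conditions[c], {}).get(types[t].name, 0.0)
        for c, t in zip(cells["condition"], cells["cell_type"])])
    level = ceiling * rng.uniform(0.0, 1.0, size=n_cells)
    cells["activation_level"] = level
    # T cells split into naive / memory compartments
    is_t = np.array([types[t].name in ("CD4_T", "CD8_T")
                     for t in cells["cell_type"]])
    cells["memory"] = is_t & (rng.random(n_cells) < 0.5)

    # --- RNA --------------------------------------------------------------
    w = rng.lognormal(0.0, 1.0, cfg.n_genes)
    med = float(np.median(w))
    structured = sorted({gene_index[g] for ct in types
                         for g in ct.marker_genes + ct.signature})
    w[structured] = med * 1.5            # keep programs reliably detectable
    type_rel = np.tile(w, (len(types), 1))
    for ti, ct in enumerate(types):
        midx = [gene_index[g] for g in ct.marker_genes]
        type_rel[ti, midx] *= 5.0

    libsize = cfg.mean_umis * rng.lognormal(
        -cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, n_cells)

    droplet_rna = np.zeros((n, cfg.n_genes), dtype=np.int64)
    cell_chunks: list[sp.csr_matrix] = []
    tp_arr = cells["cell_type"].to_numpy()
    dp_arr = cells["droplet"].to_numpy()
    chunk = 2000
    for start in range(0, n_cells, chunk):
        sl = slice(start, min(start + chunk, n_cells))
        rel = type_rel[tp_arr[sl]].copy()
        lv = level[sl]
        for ti, ct in enumerate(types):
            rows = np.flatnonzero(tp_arr[sl] == ti)
            if rows.size == 0 or not ct.signature:
                continue
            eidx = [gene_index[g] for g in ct.signature_early]
            lidx = [gene_index[g] for g in ct.signature_late]
            rel[np.ix_(rows, eidx)] *= _early_factor(
                lv[rows], cfg.activation_amplitude)[:, None]
            rel[np.ix_(rows, lidx)] *= _late_factor(
                lv[rows], cfg.activation_amplitude)[:, None]
        mu = rel / rel.sum(axis=1, keepdims=True) * libsize[sl][:, None]
        counts = _nb_draw(rng, mu, cfg.nb_dispersion)
        np.add.at(droplet_rna, dp_arr[sl], counts)
        if return_cells:
            cell_chunks.append(sp.csr_matrix(counts))

    empty_d = np.flatnonzero(category == 0)
    if empty_d.size:
        mu_amb = np.tile(w / w.sum() * cfg.ambient_umis, (empty_d.size, 1))
        droplet_rna[empty_d] += _nb_draw(rng, mu_amb, cfg.nb_dispersion)

    # --- ADT --------------------------------------------------------------
    n_adt = len(DEFAULT_ADT_PANEL)
    pos = np.zeros((n_cells, n_adt), dtype=bool)
    for ti, ct in enumerate(types):
        rows = tp_arr == ti
        for p in ct.adt_positive:
            pos[rows, adt_index[p]] = True
    pos[is_t & cells["memory"].to_numpy(), adt_index["CD45RO"]] = True
    pos[is_t & ~cells["memory"].to_numpy(), adt_index["CD45RA"]] = True
    pos[level > cfg.cd69_level, adt_index["CD69"]] = True
    pos[level > cfg.cd25_level, adt_index["CD25"]] = True
    adt_mu = np.where(pos, cfg.adt_positive_mean, cfg.adt_negative_mean)
    adt_cells = _nb_draw(rng, adt_mu, cfg.nb_dispersion)
    droplet_adt = np.zeros((n, n_adt), dtype=np.int64)
    np.add.at(droplet_adt, dp_arr, adt_cells)
    if empty_d.size:
        droplet_adt[empty_d] += _nb_draw(
            rng, np.full((empty_d.size, n_adt), cfg.adt_ambient_mean),
            cfg.nb_dispersion)

    # --- HTO --------------------------------------------------------------
    # every droplet sees a tiny free-antibody ambient level; each contained
    # cell adds nonspecific background on all tags plus separation-scaled
    # counts on its own condition's tag (empty droplets thus have near-zero
    # tag totals, as in real hashing runs)
    hto_mu = np.full((n, n_cond), cfg.hto_ambient_mean)
    for c in range(n_cond):
        hto_mu[:, c] += cfg.hto_background_mean * np.bincount(
            dp_arr, minlength=n)
    pos_extra = (cfg.hto_separation - 1.0) * cfg.hto_background_mean
    np.add.at(hto_mu, (dp_arr, cells["condition"].to_numpy()), pos_extra)
    droplet_hto = _nb_draw(rng, hto_mu, cfg.hto_dispersion)

    # --- ground truth + donor calls --------------------------------------
    barcodes = pd.Index([f"BC{i:06d}" for i in range(n)], name="barcode")
    grp = cells.groupby("droplet")
    cond_sets = grp["condition"].agg(lambda s: tuple(sorted(set(s))))
    donor_sets = grp["donor"].agg(lambda s: tuple(sorted(set(s))))
    type_lists = grp["cell_type"].agg(lambda s: tuple(sorted(s)))
    mean_level = grp["activation_level"].mean()

    n_conds = np.zeros(n, dtype=int)
    n_conds[cond_sets.index] = [len(c) for c in cond_sets]
    gt = pd.DataFrame({
        "barcode": barcodes,
        "true_kind": [_KIND_NAMES[k] for k in n_conds],
        "n_cells": np.bincount(dp_arr, minlength=n),
        "true_conditions": "",
        "true_donors": "",
        "true_cell_types": "",
        "activation_level": np.nan,
    })
    gt.loc[cond_sets.index, "true_conditions"] = [
        ";".join(cfg.conditions[c] for c in cs) for cs in cond_sets]
    gt.loc[donor_sets.index, "true_donors"] = [
        ";".join(f"D{d}" for d in ds) for ds in donor_sets]
    gt.loc[type_lists.index, "true_cell_types"] = [
        ";".join(types[t].name for t in ts) for ts in type_lists]
    gt.loc[mean_level.index, "activation_level"] = mean_level.to_numpy()

    donor_call = np.empty(n, dtype=object)
    u = rng.random(n)
    for d in range(n):
        if category[d] == 0:
            donor_call[d] = ("ambiguous" if u[d] < cfg.empty_ambiguous_rate
                             else f"D{rng.integers(0, cfg.n_donors)}")
        else:
            ds = donor_sets.get(d, ())
            if len(ds) > 1:
                donor_call[d] = "doublet"
            elif u[d] < cfg.donor_ambiguous_rate:
                donor_call[d] = "ambiguous"
            else:
                donor_call[d] = f"D{ds[0]}"
    donor_calls = pd.DataFrame({"barcode": barcodes, "donor": donor_call})

    counts = MultiModalCounts(
        barcodes=barcodes,
        rna=sp.csr_matrix(droplet_rna.T),
        adt=sp.csr_matrix(droplet_adt.T),
        hto=sp.csr_matrix(droplet_hto.T),
        gene_names=cfg.gene_names,
        adt_names=list(DEFAULT_ADT_PANEL),
        hto_names=cfg.hto_names)

    exp = SimulatedExperiment(counts=counts, donor_calls=donor_calls,
                              ground_truth=gt)
    if return_cells:
        exp.cells = cells
        exp.rna_per_cell = (sp.vstack(cell_chunks).tocsr() if cell_chunks
                            else sp.csr_matrix((0, cfg.n_genes)))
    return exp


def write_ground_truth(gt: pd.DataFrame, path: str | Path) -> None:
    """Write the ground-truth table as TSV (lossless round trip)."""
    gt.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    gt = pd.read_csv(path, sep="\t", na_values=["NA"],
                     keep_default_na=False,
                     dtype={"true_conditions": str, "true_donors": str,
                            "true_cell_types": str})
    for col in ("true_conditions", "true_donors", "true_cell_types"):
        if col in gt.columns:
            gt[col] = gt[col].fillna("")
    return gt


def write_donor_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_donor_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
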