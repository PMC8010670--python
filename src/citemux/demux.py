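"""Hashtag (HTO) demultiplexing of droplets into conditions.

Each droplet's HTO counts are converted to within-droplet proportions,
log2-transformed with a small pseudocount, and z-scored per tag across
droplets. Each tag's normalized distribution across droplets is bimodal
(ambient background vs. tag-positive); a two-component Gaussian mixture per
tag yields a posterior of tag positivity per droplet. Droplets are then
classified by the number of positive tags: 0 = empty, 1 = singlet
(assigned to that tag's condition), 2 = doublet, 3 = triplet. Droplets with
zero total HTO counts skip normalization and are classified empty outright.

Condition calls are merged with an external per-droplet donor-call table
(genotype-based demultiplexing output: a donor id, "ambiguous" or
"doublet") and with a minimum detected-genes QC filter; a droplet is
retained for analysis only if it is an HTO singlet, assigned to a single
donor, and has at least ``min_genes_per_cell`` detected genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .io import MultiModalCounts
from .mixture import MixtureFit, fit_two_component

KINDS = ("empty", "singlet", "doublet", "triplet")


@dataclass
class HTONormalization:
    """Normalized HTO values plus the droplets that bypassed normalization."""

    values: np.ndarray          # tags x droplets, z-scored log2 proportions
    insufficient: np.ndarray    # boolean per droplet: too few HTO counts


def normalize_hto(hto: sp.spmatrix | np.ndarray,
                  pseudocount: float = 1e-4,
                  min_total: int = 10) -> HTONormalization:
    """Normalize raw HTO counts: per-droplet log2 proportions, per-tag z-score.

    For droplet j with total tag count T_j, tag i maps to
    ``log2(h_ij / T_j + pseudocount)``, then each tag is centered and unit
    scaled across droplets. Droplets without sufficient read counts for any
    tag — T_j below ``min_total`` (so, in particular, T_j = 0) — bypass
    normalization: proportions of a handful of reads are meaningless, and
    such droplets are pre-classified empty and excluded from the per-tag
    scaling statistics and from the downstream mixture fits.
    """
    h = np.asarray(hto.todense() if sp.issparse(hto) else hto, dtype=float)
    totals = h.sum(axis=0)
    insufficient = totals < min_total
    props = np.zeros_like(h)
    ok = ~insufficient
    props[:, ok] = h[:, ok] / totals[ok]
    v = np.log2(props + pseudocount)
    if ok.any():
        mean = v[:, ok].mean(axis=1, keepdims=True)
        sd = v[:, ok].std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        v = (v - mean) / sd
    v[:, insufficient] = np.nan
    return HTONormalization(values=v, insufficient=insufficient)


def fit_hto_mixture(values: np.ndarray, seed: int = 0) -> MixtureFit:
    """Fit the per-tag two-component mixture (see :mod:`citemux.mixture`).

    ``values`` are one tag's normalized values across droplets; NaNs
    (zero-total droplets) are excluded from the fit and get posterior 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    ok = ~np.isnan(x)
    fit = fit_two_component(x[ok], seed=seed)
    post = np.zeros(x.size)
    post[ok] = fit.posterior_positive
    return MixtureFit(means=fit.means, variances=fit.variances,
                      weights=fit.weights, posterior_positive=post,
                      converged=fit.converged)


def classify_droplets(posteriors: np.ndarray, tag_names: list[str],
                      barcodes: pd.Index,
                      threshold: float = 0.5,
                      insufficient: np.ndarray | None = None
                      ) -> pd.DataFrame:
    """Classify droplets by the set of positive tags.

    A tag is positive when its posterior strictly exceeds ``threshold``
    (ties count as negative). The resulting partition over
    empty/singlet/doublet/triplet is exhaustive and exclusive; singlets are
    assigned the condition of their unique positive tag.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.shape[0] != len(tag_names):
        raise ValueError("posteriors rows must match tag_names")
    positive = post > threshold
    if insufficient is not None:
        positive[:, np.asarray(insufficient, dtype=bool)] = False
    n_pos = positive.sum(axis=0)
    kind = np.where(n_pos >= 3, "triplet",
                    np.where(n_pos == 2, "doublet",
                             np.where(n_pos == 1, "singlet", "empty")))
    condition = np.full(len(barcodes), "", dtype=object)
    singles = np.flatnonzero(n_pos == 1)
    tag_arr = np.array(tag_names, dtype=object)
    condition[singles] = tag_arr[positive[:, singles].argmax(axis=0)]
    out = pd.DataFrame({
        "barcode": pd.Index(barcodes),
        "kind": kind,
        "condition": condition,
        "n_positive_tags": n_pos,
    })
    for i, t in enumerate(tag_names):
        out[f"posterior_{t}"] = post[i]
    return out


def filter_cells(rna: sp.spmatrix | np.ndarray, barcodes: pd.Index,
                 min_genes: int) -> pd.Series:
    """Per-barcode detected-gene counts and the QC decision.

    A barcode is kept iff the number of genes with nonzero counts is at
    least ``min_genes`` (strict "fewer than min_genes" removal).
    """
    m = sp.csc_matrix(rna)
    detected = np.asarray((m > 0).sum(axis=0)).ravel()
    return pd.Series(detected, index=pd.Index(barcodes), name="n_genes")


def merge_demux_calls(hto_calls: pd.DataFrame, donor_table: pd.DataFrame,
                      rna: sp.spmatrix, barcodes: pd.Index,
                      config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Combine HTO calls, donor calls and the gene-detection filter.

    Returns the per-droplet call table plus a concordance report: the
    fraction of HTO-empty droplets whose donor call is "ambiguous" (empty
    droplets carry only ambient RNA, so genotype demultiplexing cannot
    assign them), and the partition counts.
    """
    bc = pd.Index(barcodes)
    only_hto = set(hto_calls["barcode"]) - set(donor_table["barcode"])
    only_donor = set(donor_table["barcode"]) - set(hto_calls["barcode"])
    if only_hto or only_donor:
        raise ValueError(
            "barcodes present in only one table: "
            f"hto-only={sorted(only_hto)[:5]}, "
            f"donor-only={sorted(only_donor)[:5]}")

    merged = hto_calls.merge(donor_table, on="barcode", how="left")
    merged = merged.set_index("barcode").loc[bc].reset_index()
    n_genes = filter_cells(rna, bc, config.min_genes_per_cell)
    merged["n_genes"] = n_genes.to_numpy()
    is_donor = ~merged["donor"].isin(["ambiguous", "doublet"])
    merged["retained"] = ((merged["kind"] == "singlet") & is_donor
                          & (merged["n_genes"] >= config.min_genes_per_cell))

    empty_mask = merged["kind"] == "empty"
    n_empty = int(empty_mask.sum())
    concordance = (float((merged.loc[empty_mask, "donor"]
                          == "ambiguous").mean()) if n_empty else np.nan)
    counts = merged["kind"].value_counts().reindex(KINDS, fill_value=0)
    report = {
        "partition": {k: int(v) for k, v in counts.items()},
        "n_droplets": int(len(merged)),
        "n_retained": int(merged["retained"].sum()),
        "empty_ambiguous_concordance": concordance,
    }
    return merged, report


def demultiplex(counts: MultiModalCounts, donor_table: pd.DataFrame,
                config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Full demultiplexing stage: normalize, fit per-tag mixtures, classify,
    merge with donor calls and QC. Returns (droplet calls, report)."""
    norm = normalize_hto(counts.hto, pseudocount=config.hto_pseudocount,
                         min_total=config.min_hto_total)
    fits = {}
    post = np.zeros_like(norm.values)
    for i, tag in enumerate(counts.hto_names):
        fit = fit_hto_mixture(norm.values[i], seed=config.seeds.mixture + i)
        fits[tag] = fit
        post[i] = fit.posterior_positive
    # tags are named after the condition they mark (HTO_<condition>)
    conditions = [t.removeprefix("HTO_") for t in counts.hto_names]
    calls = classify_droplets(post, conditions, counts.barcodes,
                              threshold=config.posterior_threshold,
                              insufficient=norm.insufficient)
    merged, report = merge_demux_calls(calls, donor_table, counts.rna,
                                       counts.barcodes, config)
    report["mixtures"] = {
        tag: {"means": fit.means.tolist(),
              "variances": fit.variances.tolist(),
              "weights": fit.weights.tolist()}
        for tag, fit in fits.items()}
    return merged, report
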