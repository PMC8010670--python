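"""End-to-end orchestration of the multiplexed CITE-seq analysis.

``run_all`` chains every stage on one experiment: hashtag demultiplexing
and QC, surface-protein annotation and multiplet removal, joint
variable-feature clustering, per-cell-type differential expression against
baseline, inflammation scoring, and the monocyte LPS-response trajectory
(pseudotime + k-means activation states). ``evaluate_against_truth``
scores the result against the generator's ground truth.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sstats

from . import cluster as cl
from . import demux as dx
from . import destats as ds
from . import surface as sf
from . import trajectory as tj
from .config import PipelineConfig, Seeds
from .io import MultiModalCounts
from .simulate import (SimulatedExperiment, SynthConfig,
                       default_inflammation_panel, simulate_experiment)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the pipeline computes on one experiment."""

    droplet_calls: pd.DataFrame
    demux_report: dict
    annotations: pd.DataFrame          # retained droplets, surface stage
    cells: pd.DataFrame                # final analysis cells (flags removed)
    clusters: pd.DataFrame
    composition: pd.DataFrame
    composition_cv: pd.DataFrame
    de_tables: dict[tuple[str, str], pd.DataFrame]  # (cell_type, condition)
    scores: pd.DataFrame               # per-cell inflammation scores
    trajectory: pd.DataFrame | None
    state_markers: dict[str, list[str]] | None
    peak_times: pd.DataFrame | None
    variable_features: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_all(experiment: SimulatedExperiment,
            config: PipelineConfig | None = None,
            inflammation_panel: list[str] | None = None,
            baseline_condition: str = "baseline",
            trajectory_condition: str = "LPS",
            trajectory_cell_type: str = "CD14_monocyte") -> PipelineResult:
    """Run every stage on an experiment (simulated or loaded from disk)."""
    cfg = config or PipelineConfig()
    panel = inflammation_panel or default_inflammation_panel()
    counts = experiment.counts

    # --- demultiplex + QC -------------------------------------------------
    calls, report = dx.demultiplex(counts, experiment.donor_calls, cfg)
    retained_bc = calls.loc[calls["retained"], "barcode"]
    sub = counts.subset(pd.Index(retained_bc))
    call_info = calls.set_index("barcode").loc[sub.barcodes]

    # --- surface annotation + multiplet removal --------------------------
    ann = sf.annotate(sub.adt, list(sub.adt_names), sub.barcodes,
                      seed=cfg.seeds.mixture + 100,
                      clr_pseudocount=cfg.clr_pseudocount,
                      threshold=cfg.posterior_threshold)
    ann["condition"] = call_info["condition"].to_numpy()
    ann["donor"] = call_info["donor"].to_numpy()
    keep = ~ann["multiplet_flag"].to_numpy()
    cells = ann.loc[keep].reset_index(drop=True)
    final = sub.subset(pd.Index(cells["barcode"]))

    # --- normalization ----------------------------------------------------
    lognorm = ds.lognormalize(final.rna, scale=cfg.lognorm_scale)
    clr = sf.clr_normalize(final.adt, pseudocount=cfg.clr_pseudocount)
    joint = sp.vstack([lognorm, sp.csr_matrix(clr)]).tocsr()
    joint_names = list(final.gene_names) + list(final.adt_names)

    # --- clustering -------------------------------------------------------
    hvf = cl.select_variable_features(joint, joint_names,
                                      n=cfg.n_variable_features,
                                      span=cfg.loess_span)
    pcs = cl.embed_pca(joint, hvf["index"].to_numpy(), n_pcs=cfg.n_pcs)
    snn = cl.build_snn(pcs, k=cfg.snn_k, prune=cfg.snn_prune)
    labels = cl.cluster_modularity(snn, resolution=cfg.cluster_resolution,
                                   seed=cfg.seeds.clustering)
    clusters = pd.DataFrame({"barcode": cells["barcode"], "cluster": labels})
    composition, comp_cv = cl.composition_stats(cells)

    # --- differential expression per cell type vs baseline ---------------
    conditions = [c for c in cells["condition"].unique()
                  if c != baseline_condition]
    de_tables: dict[tuple[str, str], pd.DataFrame] = {}
    cond_arr = cells["condition"].to_numpy()
    type_arr = cells["cell_type"].to_numpy()
    for ct in sorted(set(type_arr) - {"unassigned"}):
        base_cols = np.flatnonzero((type_arr == ct)
                                   & (cond_arr == baseline_condition))
        for cond in conditions:
            stim_cols = np.flatnonzero((type_arr == ct) & (cond_arr == cond))
            if len(base_cols) < 3 or len(stim_cols) < 3:
                continue
            de = ds.wilcoxon_de(joint[:, stim_cols], joint[:, base_cols],
                                joint_names, config=cfg)
            de_tables[(ct, cond)] = de

    # --- inflammation scoring (baseline + LPS compartment) ---------------
    lps_mask = np.isin(cond_arr, [baseline_condition, trajectory_condition])
    score_df = ds.inflammation_score(lognorm[:, np.flatnonzero(lps_mask)],
                                     list(final.gene_names), panel)
    score_df.insert(0, "barcode", cells.loc[lps_mask, "barcode"].to_numpy())
    score_df["cell_type"] = type_arr[lps_mask]
    score_df["condition"] = cond_arr[lps_mask]

    # --- monocyte LPS trajectory ------------------------------------------
    traj_df = None
    state_markers = None
    peaks = None
    mono = np.flatnonzero((type_arr == trajectory_cell_type) & lps_mask)
    key = (trajectory_cell_type, trajectory_condition)
    if key in de_tables and mono.size >= 20:
        de = de_tables[key]
        de_feats = de.loc[de["significant"], "feature"].tolist()
        if de_feats:
            y_mono = joint[:, mono]
            is_base = cond_arr[mono] == baseline_condition
            pt, emb = tj.infer_pseudotime(y_mono, joint_names, de_feats,
                                          is_base, config=cfg)
            states = tj.kmeans_states(emb, pt, k=cfg.kmeans_k,
                                      seed=cfg.seeds.trajectory)
            traj_df = pd.DataFrame({
                "barcode": cells.loc[mono, "barcode"].to_numpy(),
                "condition": cond_arr[mono],
                "pseudotime": pt,
                "state": states.to_numpy(),
            })
            state_markers = tj.state_marker_genes(y_mono, joint_names,
                                                  states, config=cfg)
            induced = de.loc[de["significant"]
                             & (de["direction"] == "up"), "feature"]
            name_idx = pd.Index(joint_names)
            rows = []
            dense = np.asarray(y_mono.todense())
            for g in induced:
                i = name_idx.get_loc(g)
                rows.append({"feature": g,
                             "peak_pseudotime": tj.peak_time(
                                 dense[i], pt,
                                 bandwidth_frac=cfg.peak_bandwidth_frac)})
            peaks = pd.DataFrame(rows)

    return PipelineResult(
        droplet_calls=calls, demux_report=report, annotations=ann,
        cells=cells, clusters=clusters, composition=composition,
        composition_cv=comp_cv, de_tables=de_tables, scores=score_df,
        trajectory=traj_df, state_markers=state_markers, peak_times=peaks,
        variable_features=hvf)


def run_default(seed: int = 0, n_droplets: int = 20000,
                config: PipelineConfig | None = None
                ) -> tuple[SimulatedExperiment, PipelineResult]:
    """Simulate the default 10-donor x 3-condition experiment and run
    the full pipeline on it."""
    synth = SynthConfig(seed=seed, n_droplets=n_droplets)
    exp = simulate_experiment(synth)
    cfg = config or PipelineConfig(seeds=Seeds.from_base(seed))
    return exp, run_all(exp, config=cfg)


def evaluate_against_truth(exp: SimulatedExperiment,
                           result: PipelineResult) -> dict:
    """Score pipeline output against the generator's ground truth."""
    gt = exp.ground_truth.set_index("barcode")
    calls = result.droplet_calls.set_index("barcode")
    gt_kind = gt.loc[calls.index, "true_kind"]

    kind_acc = float((calls["kind"] == gt_kind).mean())
    nonempty = gt_kind != "empty"
    called_multi = calls["kind"].isin(["doublet", "triplet"])
    true_multi = gt_kind.isin(["doublet", "triplet"])
    sm_acc = float((called_multi == true_multi)[nonempty].mean())

    singlets = gt_kind == "singlet"
    cond_true = gt.loc[calls.index, "true_conditions"]
    cond_acc = float((calls.loc[singlets & (calls["kind"] == "singlet"),
                                "condition"]
                      == cond_true[singlets & (calls["kind"] == "singlet")]
                      ).mean())

    # cross-cell-type doublet recall among droplets reaching the surface stage
    ann = result.annotations.set_index("barcode")
    bio = gt.loc[ann.index]
    is_bio_doublet = (bio["n_cells"] == 2) & (bio["true_kind"] == "singlet") \
        & (bio["true_cell_types"].str.split(";").map(
            lambda t: len(set(t)) == 2))
    n_bio = int(is_bio_doublet.sum())
    recall = float(ann.loc[is_bio_doublet, "multiplet_flag"].mean()) \
        if n_bio else float("nan")

    # annotation accuracy + composition recovery on clean singlets
    clean = (bio["n_cells"] == 1)
    ann_clean = ann.loc[clean & ~ann["multiplet_flag"]]
    true_type = bio.loc[ann_clean.index, "true_cell_types"]
    type_acc = float((ann_clean["cell_type"] == true_type).mean())

    truth_tbl = pd.DataFrame({
        "donor": bio.loc[ann_clean.index, "true_donors"],
        "condition": bio.loc[ann_clean.index, "true_conditions"],
        "cell_type": true_type,
    })
    true_comp, _ = cl.composition_stats(truth_tbl)
    kept = result.cells.set_index("barcode")
    kept_clean = kept.loc[kept.index.intersection(ann_clean.index)]
    obs_comp, _ = cl.composition_stats(kept_clean.reset_index())
    merged = true_comp.merge(obs_comp, on=["donor", "condition", "cell_type"],
                             how="outer", suffixes=("_true", "_obs")).fillna(0)
    pearson = float(sstats.pearsonr(merged["proportion_true"],
                                    merged["proportion_obs"])[0])

    out = {
        "kind_accuracy": kind_acc,
        "singlet_multiplet_accuracy": sm_acc,
        "condition_accuracy": cond_acc,
        "celltype_doublet_recall": recall,
        "n_bio_doublets_seen": n_bio,
        "annotation_accuracy": type_acc,
        "composition_pearson": pearson,
    }

    if result.trajectory is not None:
        traj = result.trajectory.set_index("barcode")
        lvl = gt.loc[traj.index, "activation_level"]
        rho = float(sstats.spearmanr(traj["pseudotime"], lvl)[0])
        out["pseudotime_spearman"] = rho
    return out


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write every pipeline table under ``out_dir`` as TSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.droplet_calls.to_csv(out / "droplet_calls.tsv", sep="\t",
                                index=False)
    (out / "demux_report.json").write_text(
        json.dumps(result.demux_report, indent=2))
    result.annotations.to_csv(out / "cell_annotations.tsv", sep="\t",
                              index=False)
    flags = result.annotations.loc[result.annotations["multiplet_flag"],
                                   ["barcode", "rule_ids"]]
    flags.to_csv(out / "multiplet_flags.tsv", sep="\t", index=False)
    result.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    result.composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    result.composition_cv.to_csv(out / "composition_cv.tsv", sep="\t",
                                 index=False)
    result.variable_features.to_csv(out / "variable_features.tsv", sep="\t",
                                    index=False)
    result.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    for (ct, cond), de in result.de_tables.items():
        de.to_csv(out / f"de_{ct}_{cond}.tsv", sep="\t", index=False)
    if result.trajectory is not None:
        result.trajectory.to_csv(out / "trajectory.tsv", sep="\t",
                                 index=False)
    if result.state_markers is not None:
        rows = [{"state": s, "feature": g}
                for s, genes in result.state_markers.items() for g in genes]
        pd.DataFrame(rows).to_csv(out / "state_markers.tsv", sep="\t",
                                  index=False)
    if result.peak_times is not None:
        result.peak_times.to_csv(out / "peaks.tsv", sep="\t", index=False)
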