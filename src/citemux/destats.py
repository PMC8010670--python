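"""Log-normalization, rank-sum differential expression, and gene-set /
inflammation scoring.

Differential expression between two cell groups uses two-sided Wilcoxon
rank-sum tests (tie-corrected; exact for small groups) on log-normalized
values, restricted to features detected in at least ``de_min_detection`` of
BOTH groups, with Benjamini-Hochberg correction applied across the tested
features of the contrast. A feature is significant when q < ``de_fdr`` and
its absolute mean log-difference exceeds ``de_min_logdiff``.

The inflammation score of a cell is the share of its total normalized
expression attributable to a curated inflammation gene panel, min-max
scaled to [0, 1] across cells. Generic gene-set scores are per-cell means
of log-normalized expression over the set.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

log = logging.getLogger(__name__)


def lognormalize(rna: sp.spmatrix | np.ndarray,
                 scale: float = 10000.0) -> sp.csr_matrix:
    """Depth-normalize and log-transform: y = ln(1 + scale * x / total).

    ``rna`` is genes x cells with nonnegative integer counts; every cell
    must have a nonzero total (zero-total droplets should already be
    filtered out).
    """
    x = sp.csc_matrix(rna, dtype=float)
    totals = np.asarray(x.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = int((totals == 0).sum())
        raise ValueError(f"{bad} cell(s) have zero total counts; filter "
                         "before normalizing")
    y = x.multiply(scale / totals[None, :]).tocsr()
    y.data = np.log1p(y.data)
    return y


def _dense(m) -> np.ndarray:
    return np.asarray(m.todense() if sp.issparse(m) else m, dtype=float)


def wilcoxon_de(lognorm_a: sp.spmatrix | np.ndarray,
                lognorm_b: sp.spmatrix | np.ndarray,
                feature_names: list[str],
                config: PipelineConfig | None = None) -> pd.DataFrame:
    """Rank-sum differential expression of group A versus group B.

    Both inputs are features x cells of log-normalized values over the same
    features. Direction is the sign of (mean_a − mean_b): "up" means higher
    in group A. Returns one row per *tested* feature; if no feature passes
    the detection filter the table is empty (with a log note).
    """
    cfg = config or PipelineConfig()
    a, b = _dense(lognorm_a), _dense(lognorm_b)
    if a.shape[0] != b.shape[0] or a.shape[0] != len(feature_names):
        raise ValueError("feature dimensions disagree")
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("both groups need at least 3 cells")

    det_a = (a > 0).mean(axis=1)
    det_b = (b > 0).mean(axis=1)
    tested = (det_a >= cfg.de_min_detection) & (det_b >= cfg.de_min_detection)
    if not tested.any():
        log.info("no features pass the %.0f%% detection filter",
                 100 * cfg.de_min_detection)
        return pd.DataFrame(columns=[
            "feature", "mean_a", "mean_b", "pct_a", "pct_b", "log_diff",
            "p", "q", "significant", "direction"])

    ta, tb = a[tested], b[tested]
    res = stats.mannwhitneyu(ta, tb, axis=1, alternative="two-sided",
                             method="auto")
    pvals = np.atleast_1d(res.pvalue)
    mean_a, mean_b = ta.mean(axis=1), tb.mean(axis=1)
    log_diff = mean_a - mean_b
    q = multipletests(pvals, method="fdr_bh")[1]
    significant = (q < cfg.de_fdr) & (np.abs(log_diff) > cfg.de_min_logdiff)
    out = pd.DataFrame({
        "feature": np.asarray(feature_names, dtype=object)[tested],
        "mean_a": mean_a,
        "mean_b": mean_b,
        "pct_a": det_a[tested],
        "pct_b": det_b[tested],
        "log_diff": log_diff,
        "p": pvals,
        "q": q,
        "significant": significant,
        "direction": np.where(log_diff >= 0, "up", "down"),
    })
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def inflammation_score(lognorm: sp.spmatrix | np.ndarray,
                       feature_names: list[str],
                       panel: list[str]) -> pd.DataFrame:
    """Panel share of each cell's normalized expression, min-max scaled.

    raw_c = sum over panel genes of y_gc / sum over all genes of y_gc;
    score = (raw − min) / (max − min) across cells, so the extremes 0 and 1
    are attained whenever cells differ; if all cells are identical every
    score is 0.
    """
    names = pd.Index(feature_names)
    in_panel = names.isin(set(panel))
    if not in_panel.any():
        missing = [g for g in panel if g not in set(names)]
        raise ValueError(
            f"no panel gene found in the feature set; missing e.g. "
            f"{missing[:10]}")
    y = sp.csr_matrix(lognorm)
    total = np.asarray(y.sum(axis=0)).ravel()
    panel_sum = np.asarray(y[np.flatnonzero(in_panel)].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(total > 0, panel_sum / np.maximum(total, 1e-300), 0.0)
    lo, hi = raw.min(), raw.max()
    score = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return pd.DataFrame({"raw_fraction": raw, "inflammation_score": score})


def gene_set_score(lognorm: sp.spmatrix | np.ndarray,
                   feature_names: list[str], gene_set: list[str],
                   clusters: np.ndarray | None = None
                   ) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Per-cell mean log-normalized expression over a gene set.

    Returns the per-cell scores and, when ``clusters`` is given, a
    per-cluster mean summary.
    """
    names = pd.Index(feature_names)
    rows = np.flatnonzero(names.isin(set(gene_set)))
    if rows.size == 0:
        raise ValueError("gene set does not intersect the feature names")
    y = sp.csr_matrix(lognorm)
    per_cell = np.asarray(y[rows].mean(axis=0)).ravel()
    summary = None
    if clusters is not None:
        summary = (pd.DataFrame({"cluster": clusters, "score": per_cell})
                   .groupby("cluster")["score"].mean().reset_index())
    return per_cell, summary
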