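"""Pseudo-temporal ordering of baseline + activated cells and k-means
partitioning of the trajectory into activation states.

Cells are embedded on the top principal components of the differentially
expressed feature submatrix, and a single principal curve is fit by
alternating projection and smoothing: order cells along the current
pseudotime, smooth each embedding coordinate against it (lowess), rebuild
the curve as a polyline through a fixed number of knots, and re-project
every cell onto the polyline. Pseudotime is arc length from the curve end
nearest the centroid of baseline-condition cells, so the trajectory always
starts (pseudotime 0) in the resting population. This matches the reported
behavior of activation responses, which follow essentially linear
transitions from resting to activated states.

States are k-means clusters (default k = 4) on the same embedding, renamed
by ascending mean pseudotime: Baseline, then LPS1..LPS{k-1} (or a custom
prefix for other stimuli).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import PipelineConfig
from .destats import wilcoxon_de
from .cluster import embed_pca

log = logging.getLogger(__name__)


@dataclass
class PrincipalCurveFit:
    pseudotime: np.ndarray      # arc length per cell, start at 0
    knots: np.ndarray           # ordered curve knots (m x dims)
    converged: bool
    n_iter: int


def _project_polyline(points: np.ndarray,
                      knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points onto a polyline; return (arc length, projections)."""
    seg_vec = np.diff(knots, axis=0)                   # (m-1, d)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_len = np.maximum(seg_len, 1e-12)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # t of each point on each segment, clipped to [0, 1]
    diff = points[:, None, :] - knots[None, :-1, :]    # (n, m-1, d)
    t = np.einsum("nsd,sd->ns", diff, seg_vec) / seg_len**2
    t = np.clip(t, 0.0, 1.0)
    proj = knots[None, :-1, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    n = np.arange(points.shape[0])
    arc = cum[best] + t[n, best] * seg_len[best]
    return arc, proj[n, best]


def fit_principal_curve(points: np.ndarray, span: float = 0.6,
                        max_iter: int = 30, tol: float = 1e-4,
                        n_knots: int = 100) -> PrincipalCurveFit:
    """Iterative projection/smoothing principal curve through ``points``.

    Initialized on the first principal component; converges when the mean
    projection shift (relative to the data scale) drops below ``tol``. On
    non-convergence the last iterate is returned with a warning.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    lam = centered @ vt[0]
    scale = float(np.linalg.norm(pts.std(axis=0))) or 1.0
    prev_proj = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # smooth each coordinate against current pseudotime, at knot grid
        grid = np.quantile(lam, np.linspace(0, 1, n_knots))
        knots = np.empty((n_knots, pts.shape[1]))
        for d in range(pts.shape[1]):
            sm = lowess(pts[:, d], lam, frac=span, return_sorted=True,
                        xvals=grid)
            knots[:, d] = sm
        lam, proj = _project_polyline(pts, knots)
        if prev_proj is not None:
            shift = float(np.linalg.norm(proj - prev_proj, axis=1).mean())
            if shift / scale < tol:
                converged = True
                break
        prev_proj = proj
    if not converged:
        log.warning("principal curve did not converge in %d iterations; "
                    "using last iterate", max_iter)
    return PrincipalCurveFit(pseudotime=lam, knots=knots,
                             converged=converged, n_iter=it)


def infer_pseudotime(lognorm: sp.spmatrix | np.ndarray,
                     feature_names: list[str], de_features: list[str],
                     is_baseline: np.ndarray,
                     config: PipelineConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudotime (arc-length units, start 0 at the baseline end).

    ``lognorm`` is features x cells over baseline + activated cells;
    ``de_features`` are the differentially induced genes/proteins that
    define the response axis; ``is_baseline`` marks resting cells and
    anchors the curve orientation. Returns (pseudotime, embedding).
    """
    cfg = config or PipelineConfig()
    names = pd.Index(feature_names)
    rows = names.get_indexer(pd.Index(de_features).unique())
    rows = rows[rows >= 0]
    if rows.size == 0:
        raise ValueError("no DE feature found in the feature set")
    is_baseline = np.asarray(is_baseline, dtype=bool)
    n_cells = lognorm.shape[1]
    if n_cells < 20:
        raise ValueError(f"need at least 20 cells, got {n_cells}")
    if is_baseline.all() or not is_baseline.any():
        raise ValueError("both baseline and activated cells are required")

    emb = embed_pca(sp.csr_matrix(lognorm), rows,
                    n_pcs=min(cfg.n_pcs, 10))
    fit = fit_principal_curve(emb, span=cfg.curve_span,
                              max_iter=cfg.curve_max_iter,
                              tol=cfg.curve_tol)
    lam = fit.pseudotime
    base_centroid = emb[is_baseline].mean(axis=0)
    d_start = np.linalg.norm(fit.knots[0] - base_centroid)
    d_end = np.linalg.norm(fit.knots[-1] - base_centroid)
    if d_end < d_start:
        lam = lam.max() - lam
    return lam - lam.min(), emb


def kmeans_states(embedding: np.ndarray, pseudotime: np.ndarray,
                  k: int = 4, seed: int = 0,
                  state_prefix: str = "LPS") -> pd.Series:
    """Partition the trajectory into k states named by pseudotime order.

    K-means (10 restarts, fixed seed) on the trajectory embedding; clusters
    are renamed by ascending mean pseudotime: "Baseline", then
    ``{prefix}1`` .. ``{prefix}{k-1}``.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > embedding.shape[0]:
        raise ValueError("k exceeds the number of cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(embedding)
    order = (pd.DataFrame({"cluster": raw, "pt": pseudotime})
             .groupby("cluster")["pt"].mean().sort_values().index)
    names = ["Baseline"] + [f"{state_prefix}{i}" for i in range(1, k)]
    mapping = {c: names[i] for i, c in enumerate(order)}
    return pd.Series([mapping[c] for c in raw], name="state")


def state_marker_genes(lognorm: sp.spmatrix | np.ndarray,
                       feature_names: list[str], states: pd.Series,
                       config: PipelineConfig | None = None
                       ) -> dict[str, list[str]]:
    """Genes uniquely induced in exactly one activated state vs. Baseline.

    Runs rank-sum DE of each non-Baseline state against the Baseline state
    and intersects the significant-up sets: a gene belongs to a state's
    unique set iff it is significantly up in that state only.
    """
    states = pd.Series(np.asarray(states, dtype=object))
    uniq = [s for s in states.unique() if s != "Baseline"]
    if "Baseline" not in set(states) or not uniq:
        raise ValueError("need a Baseline state and at least one "
                         "activated state")
    y = sp.csc_matrix(lognorm)
    base_cols = np.flatnonzero((states == "Baseline").to_numpy())
    up_sets: dict[str, set[str]] = {}
    for s in uniq:
        cols = np.flatnonzero((states == s).to_numpy())
        de = wilcoxon_de(y[:, cols], y[:, base_cols], feature_names,
                         config=config)
        up_sets[s] = set(de.loc[de["significant"]
                                & (de["direction"] == "up"), "feature"])
    out: dict[str, list[str]] = {}
    for s in uniq:
        others = set().union(*(up_sets[o] for o in uniq if o != s)) \
            if len(uniq) > 1 else set()
        out[s] = sorted(up_sets[s] - others)
    return out


def peak_time(expression: np.ndarray, pseudotime: np.ndarray,
              bandwidth_frac: float = 0.1,
              n_grid: int = 100) -> float:
    """Pseudotime at which kernel-smoothed expression peaks.

    Gaussian-kernel (Nadaraya-Watson) smoothing on a regular grid spanning
    the trajectory; the bandwidth is ``bandwidth_frac`` of the pseudotime
    range. A constant expression profile has no peak and returns NaN.
    """
    y = np.asarray(expression, dtype=float).ravel()
    t = np.asarray(pseudotime, dtype=float).ravel()
    if y.size != t.size:
        raise ValueError("expression and pseudotime lengths differ")
    if np.ptp(y) == 0:
        return float("nan")
    span = np.ptp(t)
    if span == 0:
        return float("nan")
    h = bandwidth_frac * span
    grid = np.linspace(t.min(), t.max(), n_grid)
    wts = np.exp(-0.5 * ((grid[:, None] - t[None, :]) / h) ** 2)
    smoothed = (wts * y[None, :]).sum(axis=1) / wts.sum(axis=1)
    return float(grid[np.argmax(smoothed)])
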