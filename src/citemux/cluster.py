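"""Variable-feature selection, PCA, SNN graph, modularity clustering and
composition summaries.

Feature selection follows the variance-stabilizing scheme common in droplet
single-cell work: a loess curve of log10 variance against log10 mean gives
each feature an expected variance; values are standardized with the
observed mean and that expected variance, clipped at sqrt(n_cells), and
features are ranked by the variance of the clipped standardized values.
Genes and proteins are ranked jointly on the concatenated normalized
matrix. The selected submatrix is centered/unit-scaled, embedded with PCA,
turned into a shared-nearest-neighbor graph (edge weight = Jaccard overlap
of k-nearest-neighbor sets, self included), and clustered by seeded Leiden
modularity optimization.
"""
from __future__ import annotations

import logging

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

log = logging.getLogger(__name__)


def select_variable_features(matrix: sp.spmatrix | np.ndarray,
                             feature_names: list[str],
                             n: int = 500,
                             span: float = 0.3) -> pd.DataFrame:
    """Rank features by standardized (clipped) variance; return the top n.

    ``matrix`` is features x cells, already normalized (log-normalized RNA
    and CLR ADT may be concatenated). Features with zero variance get
    standardized variance 0 and rank last. Requires at least 3 distinct
    feature means for the loess fit.
    """
    x = sp.csr_matrix(matrix) if sp.issparse(matrix) else np.asarray(
        matrix, dtype=float)
    n_feat, n_cells = x.shape
    if sp.issparse(x):
        mean = np.asarray(x.mean(axis=1)).ravel()
        sq = np.asarray(x.multiply(x).mean(axis=1)).ravel()
    else:
        mean = x.mean(axis=1)
        sq = (x**2).mean(axis=1)
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)
    var = np.maximum(var, 0.0)

    usable = (var > 0) & (mean > 0)
    if len(np.unique(mean[usable])) < 3:
        raise ValueError("need at least 3 distinct feature means for the "
                         "variance-mean loess fit")
    lx = np.log10(mean[usable])
    ly = np.log10(var[usable])
    fit = lowess(ly, lx, frac=span, return_sorted=False)
    expected_var = np.zeros(n_feat)
    expected_var[usable] = 10.0**fit

    std_var = np.zeros(n_feat)
    clip = np.sqrt(n_cells)
    dense = np.asarray(x.todense()) if sp.issparse(x) else x
    for rows in np.array_split(np.flatnonzero(usable),
                               max(1, usable.sum() // 2000)):
        z = (dense[rows] - mean[rows, None]) / np.sqrt(
            expected_var[rows, None])
        np.clip(z, -clip, clip, out=z)
        std_var[rows] = z.var(axis=1, ddof=1)

    order = np.argsort(-std_var, kind="stable")[:n]
    return pd.DataFrame({
        "feature": np.asarray(feature_names, dtype=object)[order],
        "index": order,
        "mean": mean[order],
        "variance": var[order],
        "std_variance": std_var[order],
    }).reset_index(drop=True)


def embed_pca(matrix: sp.spmatrix | np.ndarray, feature_idx: np.ndarray,
              n_pcs: int = 20) -> np.ndarray:
    """PC scores (cells x n_pcs) of the centered, unit-scaled submatrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores deterministic across runs. If
    ``n_pcs`` exceeds the matrix rank the result is truncated with a
    warning.
    """
    sub = matrix[np.asarray(feature_idx)]
    dense = np.asarray(sub.todense() if sp.issparse(sub) else sub,
                       dtype=float).T  # cells x features
    dense -= dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    dense /= sd
    max_rank = min(dense.shape)
    k = min(n_pcs, max_rank)
    if k < n_pcs:
        log.warning("requested %d PCs but rank allows only %d", n_pcs, k)
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    scores = pca.fit_transform(dense)
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1
    return scores


def build_snn(scores: np.ndarray, k: int = 20,
              prune: float = 1.0 / 15.0) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Each cell's neighborhood is its k nearest neighbors in Euclidean PC
    space including itself (ties broken by index); the weight of edge
    (i, j) is |N(i) ∩ N(j)| / |N(i) ∪ N(j)|, and edges with weight <=
    ``prune`` are dropped. The returned matrix is symmetric with a zero
    diagonal.
    """
    n_cells = scores.shape[0]
    if k >= n_cells:
        raise ValueError(f"k={k} must be below the number of cells {n_cells}")
    nn = NearestNeighbors(n_neighbors=k).fit(scores)
    _, nbr = nn.kneighbors(scores)
    # guarantee self-inclusion (duplicates can displace it)
    self_missing = (nbr != np.arange(n_cells)[:, None]).all(axis=1)
    nbr[self_missing, -1] = np.flatnonzero(self_missing)

    rows = np.repeat(np.arange(n_cells), k)
    a = sp.csr_matrix((np.ones(n_cells * k), (rows, nbr.ravel())),
                      shape=(n_cells, n_cells))
    a.data[:] = 1.0  # collapse duplicate entries
    inter = (a @ a.T).tocoo()
    union = 2 * k - inter.data
    jac = inter.data / union
    keep = (jac > prune) & (inter.row != inter.col)
    g = sp.csr_matrix((jac[keep], (inter.row[keep], inter.col[keep])),
                      shape=(n_cells, n_cells))
    return g


def cluster_modularity(graph: sp.spmatrix, resolution: float = 0.8,
                       seed: int = 0) -> np.ndarray:
    """Seeded Leiden modularity clustering of the SNN graph.

    Labels are integers ordered by decreasing cluster size (0 = largest).
    """
    g = sp.coo_matrix(graph)
    if g.shape[0] == 0:
        raise ValueError("empty graph")
    upper = g.row < g.col
    edges = list(zip(g.row[upper].tolist(), g.col[upper].tolist()))
    weights = g.data[upper].tolist()
    graph_ig = ig.Graph(n=g.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph_ig, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=seed,
        n_iterations=2)
    labels = np.asarray(part.membership)
    sizes = np.bincount(labels)
    remap = np.empty_like(sizes)
    remap[np.argsort(-sizes, kind="stable")] = np.arange(sizes.size)
    return remap[labels]


def composition_stats(annotations: pd.DataFrame) -> tuple[pd.DataFrame,
                                                          pd.DataFrame]:
    """Cell-type proportions per donor x condition, and per-type CV.

    ``annotations`` needs columns cell_type, donor, condition (retained
    cells only). Proportions sum to 1 within each donor x condition;
    the coefficient of variation (sd/mean, ddof=1) of each type's
    proportion is taken across donors within each condition. Donors with
    zero cells in a condition are excluded from that condition's CV with a
    warning.
    """
    counts = (annotations.groupby(["donor", "condition", "cell_type"])
              .size().rename("n").reset_index())
    totals = counts.groupby(["donor", "condition"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals

    all_types = sorted(annotations["cell_type"].unique())
    pairs = counts[["donor", "condition"]].drop_duplicates()
    n_expected = annotations["donor"].nunique() * \
        annotations["condition"].nunique()
    if len(pairs) < n_expected:
        log.warning("%d donor x condition group(s) have zero cells and are "
                    "excluded", n_expected - len(pairs))

    wide = (counts.pivot_table(index=["donor", "condition"],
                               columns="cell_type", values="proportion",
                               fill_value=0.0)
            .reindex(columns=all_types, fill_value=0.0))
    cv_rows = []
    for cond, sub in wide.groupby(level="condition"):
        for ct in all_types:
            vals = sub[ct].to_numpy()
            m = vals.mean()
            cv = float(vals.std(ddof=1) / m) if (len(vals) > 1 and m > 0) \
                else 0.0
            cv_rows.append({"condition": cond, "cell_type": ct,
                            "mean_proportion": m, "cv": cv})
    return counts, pd.DataFrame(cv_rows)
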