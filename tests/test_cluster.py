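import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from citemux.cluster import (build_snn, cluster_modularity,
                             composition_stats, embed_pca,
                             select_variable_features)


def _variable_feature_oracle(x, n, span=0.3):
    """Plain dense-arithmetic reimplementation of the ranking."""
    n_feat, n_cells = x.shape
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    usable = (var > 0) & (mean > 0)
    fit = lowess(np.log10(var[usable]), np.log10(mean[usable]), frac=span,
                 return_sorted=False)
    exp_var = np.zeros(n_feat)
    exp_var[usable] = 10.0**fit
    std_var = np.zeros(n_feat)
    clip = np.sqrt(n_cells)
    for i in np.flatnonzero(usable):
        z = (x[i] - mean[i]) / np.sqrt(exp_var[i])
        z = np.clip(z, -clip, clip)
        std_var[i] = z.var(ddof=1)
    return np.argsort(-std_var, kind="stable")[:n], std_var


class TestVariableFeatures:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(0, 1, (50, 80))
        names = [f"F{i}" for i in range(50)]
        got = select_variable_features(sp.csr_matrix(x), names, n=20)
        order, std_var = _variable_feature_oracle(x, 20)
        assert got["index"].tolist() == order.tolist()
        np.testing.assert_allclose(got["std_variance"], std_var[order],
                                   rtol=1e-8)

    def test_zero_variance_ranked_last(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, (20, 50))
        x[7] = 3.0  # constant feature
        got = select_variable_features(x, [f"F{i}" for i in range(20)], n=20)
        assert got["feature"].iloc[-1] == "F7"
        assert got["std_variance"].iloc[-1] == 0.0

    def test_returns_all_when_few_features(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, (8, 40))
        got = select_variable_features(x, [f"F{i}" for i in range(8)], n=500)
        assert len(got) == 8

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1, (30, 60))
        names = [f"F{i}" for i in range(30)]
        a = select_variable_features(x, names, n=10)
        b = select_variable_features(x[:, rng.permutation(60)], names, n=10)
        assert a["feature"].tolist() == b["feature"].tolist()

    def test_too_few_distinct_means_error(self):
        x = np.ones((2, 30))
        with pytest.raises(ValueError, match="distinct"):
            select_variable_features(x, ["a", "b"], n=2)


class TestPCA:
    def test_line_in_3d_captured_by_pc1(self):
        t = np.linspace(0, 1, 40)
        x = np.vstack([2 * t, -t, 3 * t])  # 3 features x 40 cells
        scores = embed_pca(x, np.arange(3), n_pcs=2)
        total = scores.var(axis=0).sum()
        assert scores[:, 0].var() / total > 0.999

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 5))  # features x cells
        scores = embed_pca(x, np.arange(4), n_pcs=3)
        d = x.T.copy()
        d -= d.mean(axis=0)
        sd = d.std(axis=0)
        sd[sd == 0] = 1
        d /= sd
        evals, evecs = np.linalg.eigh(np.cov(d.T))
        order = np.argsort(evals)[::-1][:3]
        oracle = d @ evecs[:, order]
        for j in range(3):
            agree = np.allclose(scores[:, j], oracle[:, j], atol=1e-8)
            flipped = np.allclose(scores[:, j], -oracle[:, j], atol=1e-8)
            assert agree or flipped

    def test_permuting_cells_permutes_scores(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 30))
        perm = rng.permutation(30)
        a = embed_pca(x, np.arange(6), n_pcs=3)
        b = embed_pca(x[:, perm], np.arange(6), n_pcs=3)
        np.testing.assert_allclose(a[perm], b, atol=1e-8)

    def test_rank_deficient_truncated_with_warning(self, caplog):
        x = np.ones((3, 10)) * np.arange(10)
        with caplog.at_level("WARNING"):
            scores = embed_pca(x, np.arange(3), n_pcs=5)
        assert scores.shape[1] < 5


class TestSNN:
    def test_identical_neighborhoods_weight_one(self):
        # two tight, well-separated blobs; within a blob all k-NN sets match
        rng = np.random.default_rng(6)
        blob = rng.normal(0, 1e-9, (5, 2))
        pts = np.vstack([blob, blob + 100])
        g = build_snn(pts, k=5, prune=0.0)
        for i in range(4):
            assert g[i, i + 1] == pytest.approx(1.0)
        assert g[0, 5] == 0.0

    def test_matches_bruteforce_jaccard(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(30, 3))
        k = 6
        g = build_snn(pts, k=k, prune=0.0).toarray()
        d = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        nbrs = [set(np.argsort(d[i], kind="stable")[:k]) for i in range(30)]
        for i in range(30):
            for j in range(30):
                if i == j:
                    assert g[i, j] == 0
                    continue
                jac = len(nbrs[i] & nbrs[j]) / len(nbrs[i] | nbrs[j])
                assert g[i, j] == pytest.approx(jac if jac > 0 else 0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(50, 4))
        g = build_snn(pts, k=10)
        assert (abs(g - g.T) > 1e-12).nnz == 0

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError, match="k="):
            build_snn(np.zeros((5, 2)), k=5)


class TestModularityClustering:
    @staticmethod
    def _graph(adj):
        return sp.csr_matrix(adj)

    def test_two_cliques(self):
        n = 10
        adj = np.zeros((2 * n, 2 * n))
        adj[:n, :n] = 1.0
        adj[n:, n:] = 1.0
        np.fill_diagonal(adj, 0)
        adj[0, n] = adj[n, 0] = 0.01
        labels = cluster_modularity(self._graph(adj), seed=0)
        assert len(set(labels[:n])) == 1
        assert len(set(labels[n:])) == 1
        assert labels[0] != labels[-1]

    def test_uniform_complete_graph_single_cluster(self):
        adj = np.ones((12, 12)) - np.eye(12)
        labels = cluster_modularity(self._graph(adj), resolution=0.8, seed=0)
        assert len(set(labels)) == 1

    def test_four_blob_embedding_recovered(self):
        rng = np.random.default_rng(9)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]])
        truth = np.repeat(np.arange(4), 50)
        pts = centers[truth] + rng.normal(0, 0.5, (200, 2))
        g = build_snn(pts, k=15)
        labels = cluster_modularity(g, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_modularity(sp.csr_matrix((0, 0)))

    def test_labels_ordered_by_size(self):
        adj = np.zeros((9, 9))
        adj[:6, :6] = 1
        adj[6:, 6:] = 1
        np.fill_diagonal(adj, 0)
        labels = cluster_modularity(self._graph(adj), seed=0)
        assert set(labels[:6]) == {0}
        assert set(labels[6:]) == {1}


class TestComposition:
    def test_two_donor_worked_example(self):
        ann = pd.DataFrame({
            "cell_type": ["T"] * 3 + ["B"] + ["T"] + ["B"] * 3,
            "donor": ["A"] * 4 + ["B"] * 4,
            "condition": ["baseline"] * 8,
        })
        props, cv = composition_stats(ann)
        pa = props.set_index(["donor", "cell_type"])["proportion"]
        assert pa[("A", "T")] == pytest.approx(0.75)
        assert pa[("B", "T")] == pytest.approx(0.25)
        cvt = cv.set_index("cell_type")["cv"]
        assert cvt["T"] == pytest.approx(np.sqrt(2) / 2, rel=1e-6)
        assert cvt["B"] == pytest.approx(cvt["T"], rel=1e-9)

    def test_single_type_degenerate(self):
        ann = pd.DataFrame({"cell_type": ["T"] * 4, "donor": ["A"] * 4,
                            "condition": ["baseline"] * 4})
        props, cv = composition_stats(ann)
        assert props["proportion"].tolist() == [1.0]
        assert cv["cv"].tolist() == [0.0]

    def test_proportions_sum_to_one(self, small_result):
        sums = (small_result.composition
                .groupby(["donor", "condition"])["proportion"].sum())
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
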