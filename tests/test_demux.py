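import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from citemux.config import PipelineConfig
from citemux.demux import (classify_droplets, filter_cells, fit_hto_mixture,
                           merge_demux_calls, normalize_hto)
from citemux.mixture import DegenerateFitError, fit_two_component

EPS = 1e-4


class TestNormalizeHTO:
    def test_matches_formula_oracle(self):
        """z-scored log2 proportions agree with a direct recomputation,
        including the worked droplet (100, 5, 3)."""
        rng = np.random.default_rng(0)
        h = rng.poisson(30, (3, 50)).astype(float)
        h[:, 0] = [100, 5, 3]
        norm = normalize_hto(h, pseudocount=EPS, min_total=1)
        totals = h.sum(axis=0)
        raw = np.log2(h / totals + EPS)
        expected = ((raw - raw.mean(axis=1, keepdims=True))
                    / raw.std(axis=1, keepdims=True))
        np.testing.assert_allclose(norm.values, expected, atol=1e-12)
        # frozen pre-scaling values of the worked droplet
        np.testing.assert_allclose(
            raw[:, 0], [-0.110876, -4.429847, -5.164741], atol=1e-4)

    def test_scaling_invariance_of_proportions(self):
        h = np.array([[100, 200], [5, 10], [3, 6]], dtype=float)
        norm = normalize_hto(h, min_total=1)
        np.testing.assert_allclose(norm.values[:, 0], norm.values[:, 1],
                                   atol=1e-12)

    def test_insufficient_totals_flagged(self):
        h = np.array([[0, 2, 100], [0, 1, 50], [0, 0, 30]], dtype=float)
        norm = normalize_hto(h, min_total=10)
        assert norm.insufficient.tolist() == [True, True, False]
        assert np.isnan(norm.values[:, :2]).all()


class TestMixtureFit:
    def test_recovers_separated_components(self):
        rng = np.random.default_rng(1)
        labels = rng.random(2000) < 0.4
        x = np.where(labels, rng.normal(5, 0.5, 2000),
                     rng.normal(0, 0.5, 2000))
        fit = fit_two_component(x, seed=0)
        assert abs(fit.means[0] - 0.0) < 0.2
        assert abs(fit.means[1] - 5.0) < 0.2
        acc = ((fit.posterior_positive > 0.5) == labels).mean()
        assert acc >= 0.99

    def test_constant_values_error(self):
        with pytest.raises(DegenerateFitError, match="constant"):
            fit_two_component(np.ones(100), seed=0)

    def test_too_few_observations_error(self):
        with pytest.raises(DegenerateFitError, match="at least"):
            fit_two_component(np.arange(10.0), seed=0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(6, 1, 300)])
        perm = rng.permutation(x.size)
        a = fit_two_component(x, seed=0)
        b = fit_two_component(x[perm], seed=0)
        np.testing.assert_allclose(a.means, b.means, atol=1e-8)
        np.testing.assert_allclose(a.posterior_positive[perm],
                                   b.posterior_positive, atol=1e-8)

    def test_nan_values_get_zero_posterior(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100),
                            [np.nan, np.nan]])
        fit = fit_hto_mixture(x, seed=0)
        assert fit.posterior_positive[-2:].tolist() == [0.0, 0.0]


class TestClassify:
    BARCODES = pd.Index(["b1", "b2", "b3"])

    def _classify(self, post):
        return classify_droplets(np.asarray(post, float).T,
                                 ["baseline", "LPS", "aCD3CD28"],
                                 self.BARCODES[: len(post)], threshold=0.5)

    def test_singlet_doublet_empty_examples(self):
        out = self._classify([[0.99, 0.01, 0.01],
                              [0.90, 0.80, 0.10],
                              [0.40, 0.30, 0.20]])
        assert out["kind"].tolist() == ["singlet", "doublet", "empty"]
        assert out["condition"].tolist() == ["baseline", "", ""]

    def test_tie_at_threshold_is_negative(self):
        out = self._classify([[0.5, 0.5, 0.5]])
        assert out["kind"].iloc[0] == "empty"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        post = rng.random((3, 200))
        bcs = pd.Index([f"d{i}" for i in range(200)])
        out = classify_droplets(post, ["a", "b", "c"], bcs, threshold=0.5)
        kinds = {0: "empty", 1: "singlet", 2: "doublet", 3: "triplet"}
        for j in range(200):
            pos = [t for t in range(3) if post[t, j] > 0.5]
            assert out["kind"].iloc[j] == kinds[len(pos)]
            if len(pos) == 1:
                assert out["condition"].iloc[j] == "abc"[pos[0]]

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_is_exhaustive_and_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 60)
        post = rng.random((3, n))
        bcs = pd.Index([f"d{i}" for i in range(n)])
        out = classify_droplets(post, ["a", "b", "c"], bcs)
        counts = out["kind"].value_counts()
        assert counts.sum() == n
        assert set(counts.index) <= {"empty", "singlet", "doublet",
                                     "triplet"}


class TestFilterAndMerge:
    def test_detected_gene_boundary(self):
        cfg = PipelineConfig()
        n_genes = 450
        rna = np.zeros((n_genes, 3), dtype=int)
        rna[:399, 0] = 1
        rna[:400, 1] = 1
        rna[:450, 2] = 1
        bcs = pd.Index(["low", "edge", "high"])
        detected = filter_cells(sp.csr_matrix(rna), bcs, 400)
        keep = detected >= cfg.min_genes_per_cell
        assert keep.tolist() == [False, True, True]
        assert (filter_cells(sp.csr_matrix(rna), bcs, 0) >= 0).all()

    def _merge(self, kinds, donors, detected, min_genes=400):
        n = len(kinds)
        bcs = pd.Index([f"d{i}" for i in range(n)])
        hto = pd.DataFrame({"barcode": bcs, "kind": kinds,
                            "condition": ["baseline"] * n,
                            "n_positive_tags": [1] * n})
        donor_tbl = pd.DataFrame({"barcode": bcs, "donor": donors})
        rna = np.zeros((max(detected) + 1, n), dtype=int)
        for j, d in enumerate(detected):
            rna[:d, j] = 1
        cfg = PipelineConfig(min_genes_per_cell=min_genes)
        return merge_demux_calls(hto, donor_tbl, sp.csr_matrix(rna), bcs,
                                 cfg)

    def test_retention_rules(self):
        merged, _ = self._merge(
            kinds=["singlet", "singlet", "singlet", "doublet"],
            donors=["D3", "ambiguous", "doublet", "D1"],
            detected=[900, 900, 900, 900])
        assert merged["retained"].tolist() == [True, False, False, False]

    def test_low_gene_singlet_discarded(self):
        merged, _ = self._merge(kinds=["singlet"], donors=["D1"],
                                detected=[399])
        assert not merged["retained"].any()

    def test_concordance_reported(self):
        merged, report = self._merge(
            kinds=["empty", "empty", "singlet"],
            donors=["ambiguous", "D2", "D1"],
            detected=[10, 10, 900])
        assert report["empty_ambiguous_concordance"] == pytest.approx(0.5)
        assert report["partition"]["empty"] == 2

    def test_barcode_mismatch_errors(self):
        bcs = pd.Index(["a", "b"])
        hto = pd.DataFrame({"barcode": bcs, "kind": ["singlet"] * 2,
                            "condition": ["x"] * 2,
                            "n_positive_tags": [1] * 2})
        donor_tbl = pd.DataFrame({"barcode": ["a", "z"],
                                  "donor": ["D1", "D2"]})
        rna = sp.csr_matrix(np.ones((5, 2), dtype=int))
        with pytest.raises(ValueError, match="only one table"):
            merge_demux_calls(hto, donor_tbl, rna, bcs, PipelineConfig())


class TestEndToEndDemux:
    def test_accuracy_on_simulated_truth(self, small_exp, pipe_config,
                                         small_result):
        """Singlet-vs-multiplet recovery on the shared 4k-droplet run."""
        gt = small_exp.ground_truth
        calls = small_result.droplet_calls
        truth = gt["true_kind"].to_numpy()
        called = calls["kind"].to_numpy()
        nonempty = truth != "empty"
        cm = np.isin(called, ["doublet", "triplet"])
        tm = np.isin(truth, ["doublet", "triplet"])
        assert (cm == tm)[nonempty].mean() >= 0.98

    def test_empty_ambiguous_concordance(self, small_result):
        """Called-empty droplets are overwhelmingly the donor-ambiguous ones:
        concordance is compatible with the generator's configured 85% overlap
        (3-sigma binomial band, small allowance for impurities) and far above
        the overall ambiguous rate."""
        report = small_result.demux_report
        conc = report["empty_ambiguous_concordance"]
        n_empty = report["partition"]["empty"]
        configured = 0.85
        noise = 3 * np.sqrt(configured * (1 - configured) / n_empty)
        assert conc >= configured - noise - 0.02
        overall_ambiguous = (small_result.droplet_calls["donor"]
                             == "ambiguous").mean()
        assert conc > 5 * overall_ambiguous

    def test_partition_counts_sum(self, small_exp, small_result):
        part = small_result.demux_report["partition"]
        assert sum(part.values()) == small_exp.counts.n_droplets
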