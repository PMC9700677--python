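"""Single-cell core: QC rules, normalization closed forms, HVG selection,
cell-cycle scoring, covariate regression, clustering and per-cluster
differential expression (with a brute-force rank-sum oracle)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stromadev import sc
from stromadev.containers import CountMatrix

from conftest import toy_count_matrix


def matrix_with_qc_profile(detected, mito_counts):
    """Cells with the requested number of detected genes and mitochondrial
    counts; gene 0 is mitochondrial."""
    n_genes = max(detected) + 1
    counts = np.zeros((n_genes, len(detected)), dtype=int)
    for j, (d, mt) in enumerate(zip(detected, mito_counts)):
        if mt > 0:
            counts[0, j] = mt
            d -= 1
        counts[1 : 1 + d, j] = 1
    genes = ["mt-nd1"] + [f"g{i}" for i in range(n_genes - 1)]
    return toy_count_matrix(counts, gene_names=genes)


class TestQcFilter:
    def test_hand_enumerated_toy(self):
        """Five cells with detected genes (1,2,4,5,3) and mito% (0,0,0,0,60);
        thresholds (2, 4, 50%) keep exactly the 2nd and 3rd cell."""
        m = matrix_with_qc_profile([1, 2, 4, 5, 3], [0, 0, 0, 0, 3])
        # cell 5: 3 of 5 counts mitochondrial -> 60% > 50%
        kept = sc.qc_filter(m, 2, 4, 50.0)
        assert list(kept.cell_names) == ["c1", "c2"]

    def test_wide_open_thresholds_are_identity(self, sc_small):
        m, _ = sc_small
        kept = sc.qc_filter(m, 0, np.inf, 100.0)
        assert np.array_equal(kept.counts, m.counts)

    def test_boundaries_inclusive(self):
        m = matrix_with_qc_profile([3, 3], [0, 0])
        assert sc.qc_filter(m, 3, 3.5, 100.0).n_cells == 2

    def test_idempotent(self, sc_small):
        m, _ = sc_small
        once = sc.qc_filter(m, 50, 400, 10.0)
        twice = sc.qc_filter(once, 50, 400, 10.0)
        assert np.array_equal(once.counts, twice.counts)

    def test_empty_result_is_empty_matrix_not_error(self):
        m = matrix_with_qc_profile([1, 1], [0, 0])
        out = sc.qc_filter(m, 5, 10, 100.0)
        assert out.n_cells == 0 and out.n_features == m.n_features

    def test_study_presets_encode_published_thresholds(self):
        assert sc.PRESETS["ontogeny"]["min_genes"] == 1000
        assert sc.PRESETS["ontogeny"]["max_genes"] == 4600
        assert sc.PRESETS["ontogeny"]["max_pct_mito"] == 4.5
        assert sc.PRESETS["gfspf"]["min_genes"] == 750
        assert sc.PRESETS["irf3"]["max_genes"] == 4500


class TestNormalizeLog:
    def test_closed_form_two_gene_cell(self):
        m = toy_count_matrix([[1], [1]])
        x = sc.normalize_log(m, scale=2)
        assert np.allclose(x, np.log1p(1.0))

    def test_zero_cell_warns_and_zeroes(self):
        m = toy_count_matrix([[0, 1], [0, 1]])
        with pytest.warns(UserWarning, match="zero total"):
            x = sc.normalize_log(m)
        assert np.all(x[:, 0] == 0)

    def test_expm1_column_sums_equal_scale(self, sc_small):
        m, _ = sc_small
        x = sc.normalize_log(m, scale=10_000)
        sums = np.expm1(x).sum(axis=0)
        assert np.allclose(sums, 10_000)


class TestSelectHvg:
    def test_constant_genes_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(20, 50))
        counts[3] = 0  # never-expressed gene: zero variance after normalization
        m = toy_count_matrix(counts)
        assert "g3" not in sc.select_hvg(m, 19)

    def test_n_equal_features_returns_all(self, sc_small):
        m, _ = sc_small
        assert set(sc.select_hvg(m, m.n_features)) == set(m.feature_names)

    def test_planted_markers_rank_highly(self, sc_small):
        m, truth = sc_small
        hvg = set(sc.select_hvg(m, 150))
        markers = {g for gs in truth.signature_genes.values() for g in gs}
        assert len(markers & hvg) / len(markers) > 0.8


class TestCellCycleScores:
    def test_all_zero_matrix_scores_zero(self):
        m = toy_count_matrix(np.zeros((30, 10), dtype=int))
        with pytest.warns(UserWarning):
            s = sc.score_cell_cycle(m, ["g0", "g1"], ["g2"], n_bins=3, seed=0)
        assert np.allclose(s.s_score, 0) and np.allclose(s.g2m_score, 0)

    def test_same_seed_same_controls(self, sc_small):
        m, truth = sc_small
        cc = truth.cell_cycle_genes
        a = sc.score_cell_cycle(m, cc["s"], cc["g2m"], seed=5)
        b = sc.score_cell_cycle(m, cc["s"], cc["g2m"], seed=5)
        assert np.array_equal(a.s_score, b.s_score)

    def test_random_gene_sets_score_near_zero(self, sc_small):
        """Sets drawn at random from the matrix (a label permutation of the
        planted program) have mean score ~ 0."""
        m, _ = sc_small
        rng = np.random.default_rng(3)
        means = []
        for _ in range(20):
            genes = list(rng.choice(m.feature_names, size=20, replace=False))
            s = sc.score_cell_cycle(m, genes, genes, n_bins=25, seed=0)
            means.append(s.s_score.mean())
        assert abs(np.mean(means)) < 3 * np.std(means) / np.sqrt(len(means)) + 0.03

    def test_planted_program_scores_progenitors_highest(self, sc_small):
        m, truth = sc_small
        cc = truth.cell_cycle_genes
        s = sc.score_cell_cycle(m, cc["s"], cc["g2m"], seed=0)
        is_root = (m.cell_meta["branch"] == "root").to_numpy()
        assert s.s_score[is_root].mean() > s.s_score[~is_root].mean() + 0.5

    def test_missing_genes_raise_with_names(self, sc_small):
        m, _ = sc_small
        with pytest.raises(ValueError, match="NotAGene"):
            sc.score_cell_cycle(m, ["NotAGene"], ["alsoNot"], seed=0)


class TestRegressCovariates:
    def test_orthogonal_covariate_only_centers(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 40))
        cov = rng.normal(size=40)
        cov -= cov.mean()
        x0 = x[0] - (x[0] @ cov) / (cov @ cov) * cov  # make gene 0 orthogonal
        x[0] = x0
        res = sc.regress_covariates(x, pd.DataFrame({"c": cov}))
        assert np.allclose(res[0], x0 - x0.mean(), atol=1e-10)

    def test_exact_linear_gene_residuals_vanish(self):
        cov = np.linspace(0, 1, 30)
        x = np.vstack([2.0 * cov + 1.0])
        res = sc.regress_covariates(x, pd.DataFrame({"c": cov}))
        assert np.allclose(res, 0, atol=1e-10)

    def test_residuals_uncorrelated_with_covariates(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 100))
        covs = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        res = sc.regress_covariates(x, covs)
        for c in covs.columns:
            v = covs[c] - covs[c].mean()
            r = res @ v / (np.linalg.norm(res, axis=1) * np.linalg.norm(v) + 1e-30)
            assert np.all(np.abs(r) < 1e-8)

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(3, 50))
        c1 = rng.normal(size=50)
        covs = pd.DataFrame({"a": c1, "b": 2 * c1})
        with pytest.warns(UserWarning, match="collinear"):
            res = sc.regress_covariates(x, covs)
        assert np.all(np.isfinite(res))


class TestCluster:
    def test_two_separated_blobs_found_exactly(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, (100, 5)), rng.normal(20, 1, (100, 5))]).T
        res = sc.cluster(x, dims=2, resolution=0.1, k_nn=15, seed=0)
        assert len(np.unique(res.labels)) == 2
        assert adjusted_rand_score([0] * 100 + [1] * 100, res.labels) == 1.0

    def test_resolution_limit_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 5)).T
        res = sc.cluster(x, dims=2, resolution=1e-9, k_nn=15, seed=0)
        assert len(np.unique(res.labels)) == 1

    def test_same_seed_reproduces_labels(self, sc_small):
        m, _ = sc_small
        x = sc.normalize_log(m)
        a = sc.cluster(x, dims=10, resolution=0.8, seed=4)
        b = sc.cluster(x, dims=10, resolution=0.8, seed=4)
        assert np.array_equal(a.labels, b.labels)

    def test_labels_contiguous_from_zero(self, sc_small):
        m, _ = sc_small
        res = sc.cluster(sc.normalize_log(m), dims=10, resolution=0.8, seed=0)
        assert set(res.labels) == set(range(res.labels.max() + 1))

    def test_small_n_reduces_knn_with_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="k_nn"):
            sc.cluster(rng.normal(size=(5, 10)), dims=3, k_nn=20, seed=0)


class TestGate:
    def _matrix(self, gate_expr_per_cluster):
        # 2 clusters x 10 cells; gene 'Pecam1' counts chosen so mean
        # normalized expression per cluster is controlled
        counts = np.ones((5, 20), dtype=int) * 10
        labels = np.repeat([0, 1], 10)
        for cl, e in enumerate(gate_expr_per_cluster):
            counts[0, labels == cl] = e
        m = toy_count_matrix(counts, gene_names=["Pecam1", "a", "b", "c", "d"])
        return m, labels

    def test_silent_cluster_retained(self):
        m, labels = self._matrix([0, 50])
        kept = sc.gate_non_endothelial(m, labels)
        assert kept.n_cells == 10

    def test_gate_is_strict_less_than(self):
        # max_expr set to the exact per-cluster mean: "strictly below" fails
        m, labels = self._matrix([0, 0])
        x = sc.normalize_log(m)
        target = float(x[1][labels == 0].mean())
        kept = sc.gate_non_endothelial(m, labels, gate_gene="a", max_expr=target)
        assert kept.n_cells == 0  # mean exactly at the gate -> dropped

    def test_all_high_yields_empty(self):
        m, labels = self._matrix([50, 50])
        assert sc.gate_non_endothelial(m, labels).n_cells == 0

    def test_missing_gate_gene_raises(self, sc_small):
        m, _ = sc_small
        with pytest.raises(ValueError, match="absent"):
            sc.gate_non_endothelial(m, np.zeros(m.n_cells, dtype=int), gate_gene="Nope")


def brute_force_ranksum_p(x, y):
    """Exact two-sided rank-sum p-value by enumerating every assignment of
    the pooled observations to the two groups."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n + m), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        u = sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(1 for xi in xs for yj in ys if xi == yj)
        if abs(u - n * m / 2) >= abs(u_obs - n * m / 2) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestClusterDegs:
    def test_null_clusters_yield_no_degs(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(100, 200))
        m = toy_count_matrix(counts)
        labels = np.repeat([0, 1], 100)
        degs = sc.cluster_degs(m, labels, min_log2fc=0.2, max_padj=0.05)
        assert len(degs) <= 2  # false positives only

    def test_planted_marker_detected(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(50, 100))
        counts[7, 50:] = rng.poisson(40, size=50)  # 8-fold up in cluster 1
        m = toy_count_matrix(counts)
        degs = sc.cluster_degs(m, np.repeat([0, 1], 50))
        up1 = degs[(degs["cluster"] == 1) & (degs["direction"] == "up")]
        assert "g7" in set(up1["gene"])

    def test_small_sample_p_matches_enumeration_oracle(self):
        """n = 3 vs 3 without ties: the reported p equals the exact
        permutation distribution of the rank-sum statistic."""
        x = np.array([1.3, 2.7, 0.4])
        y = np.array([3.1, 4.2, 2.9])
        counts = np.zeros((2, 6), dtype=int)
        m = toy_count_matrix(counts)
        xmat = np.vstack([np.concatenate([x, y]), np.zeros(6)])
        from scipy import stats as st

        res = st.mannwhitneyu(xmat[:, :3], xmat[:, 3:], axis=1, alternative="two-sided", method="exact")
        assert res.pvalue[0] == pytest.approx(brute_force_ranksum_p(x, y), abs=1e-12)

    def test_padj_at_least_p(self, sc_small):
        m, _ = sc_small
        labels = (m.cell_meta["branch"] == "branchA").to_numpy().astype(int)
        degs = sc.cluster_degs(m, labels, min_log2fc=0.0, max_padj=1.0)
        assert np.all(degs["padj"].to_numpy() >= degs["p"].to_numpy() - 1e-15)

    def test_singleton_cluster_skipped(self):
        counts = np.random.default_rng(0).poisson(5, size=(10, 5))
        m = toy_count_matrix(counts)
        with pytest.warns(UserWarning, match="singleton"):
            sc.cluster_degs(m, np.array([0, 0, 0, 0, 1]))


class TestComposition:
    def test_equal_groups_split_evenly(self):
        out = sc.composition_heatmap(np.zeros(20, dtype=int), np.repeat(["g1", "g2"], 10))
        assert np.allclose(out.to_numpy(), [[50.0, 50.0]])

    def test_exclusive_subset_takes_all(self):
        labels = np.array([0, 0, 1, 1, 1])
        groups = np.array(["a", "a", "b", "b", "b"])
        out = sc.composition_heatmap(labels, groups)
        assert out.loc[1, "b"] == 100.0 and out.loc[1, "a"] == 0.0

    def test_hand_toy_corrects_group_size(self):
        """10 of 100 cells in g1, 40 of 200 in g2: fractions 0.1 vs 0.2
        renormalize to (33.3, 66.7)."""
        labels = np.array([1] * 10 + [0] * 90 + [1] * 40 + [0] * 160)
        groups = np.array(["g1"] * 100 + ["g2"] * 200)
        out = sc.composition_heatmap(labels, groups)
        assert out.loc[1, "g1"] == pytest.approx(100 / 3, abs=1e-9)
        assert out.loc[1, "g2"] == pytest.approx(200 / 3, abs=1e-9)

    def test_rows_sum_to_100(self, sc_small):
        m, _ = sc_small
        out = sc.composition_heatmap(m.cell_meta["subset"].to_numpy(), m.cell_meta["timepoint"].to_numpy())
        assert np.allclose(out.sum(axis=1), 100.0, atol=1e-6)
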