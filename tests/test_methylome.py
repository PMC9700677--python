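"""DMR pipeline: coverage filter rules, smoothing against a per-point
weighted-least-squares oracle, t-statistic closed forms and the four-part
DMR criterion against brute-force run enumeration."""

import numpy as np
import pandas as pd
import pytest

from stromadev import methylome as me
from stromadev.containers import MethylomeTable
from stromadev.simulate import make_methylome


def table_from(pos, M, C, groups=("A", "A", "B", "B")):
    """Build a MethylomeTable from position vector and CpG x sample count
    arrays."""
    M, C = np.atleast_2d(M), np.atleast_2d(C)
    samples = [f"s{i}" for i in range(M.shape[1])]
    df = pd.DataFrame({"chrom": "chrS", "pos": pos})
    for j, s in enumerate(samples):
        df[f"M_{s}"] = M[:, j]
        df[f"C_{s}"] = C[:, j]
    return MethylomeTable(df, samples, dict(zip(samples, groups)))


class TestCoverageFilter:
    def test_one_condition_qualifying_keeps_cpg(self):
        t = table_from([10], [[3, 4, 0, 0]], [[5, 5, 0, 0]])
        kept = me.coverage_filter(t, min_cov=5, min_reps=2)
        assert kept.n_cpg == 1  # condition A has two replicates at 5x

    def test_uniform_low_coverage_dropped(self):
        t = table_from([10, 50], [[1] * 4] * 2, [[4] * 4] * 2)
        assert me.coverage_filter(t, 5, 2).n_cpg == 0

    def test_zero_threshold_is_identity(self, meth_small):
        t, _ = meth_small
        assert me.coverage_filter(t, 0, 1).n_cpg == t.n_cpg


class TestSmooth:
    def test_constant_levels_smooth_to_constant(self):
        pos = np.arange(20) * 50
        C = np.full((20, 4), 10)
        M = np.full((20, 4), 7)
        t = table_from(pos, M, C)
        sm = me.smooth(t, bandwidth=500, min_cpg_window=5)
        assert np.allclose(sm, 0.7)

    def test_single_cpg_chromosome_keeps_raw_ratio(self):
        t = table_from([100], [[3, 5, 2, 8]], [[10, 10, 10, 10]])
        sm = me.smooth(t)
        assert np.allclose(sm[0], [0.3, 0.5, 0.2, 0.8])

    def test_matches_weighted_least_squares_oracle(self, meth_small):
        """Independent per-point WLS fit (tricube x coverage weights over
        the same window) reproduces the smoothed value to 1e-8."""
        t, _ = meth_small
        bw, k = 500, 10
        sm = me.smooth(t, bandwidth=bw, min_cpg_window=k)
        pos = t.df["pos"].to_numpy().astype(float)
        lv = t.levels()
        cov = t.coverage().astype(float)
        rng = np.random.default_rng(0)
        for j in rng.choice(t.n_cpg, size=20, replace=False):
            d_all = np.abs(pos - pos[j])
            h = max(bw / 2.0, np.sort(d_all)[k])
            win = d_all <= h
            for s in range(len(t.samples)):
                w = (1 - (d_all[win] / (h * 1.0001)) ** 3) ** 3 * cov[win, s]
                y = np.nan_to_num(lv[win, s])
                X = np.column_stack([np.ones(win.sum()), pos[win] - pos[j]])
                sw = np.sqrt(w)
                beta = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)[0]
                expected = np.clip(beta[0], 0, 1)
                assert sm[j, s] == pytest.approx(expected, abs=1e-8)

    def test_few_cpg_chromosome_falls_back_to_weighted_mean(self):
        pos = [0, 100, 200]
        M = np.array([[2, 2, 2, 2], [4, 4, 4, 4], [6, 6, 6, 6]])
        C = np.full((3, 4), 10)
        t = table_from(pos, M, C)
        with pytest.warns(UserWarning, match="weighted mean"):
            sm = me.smooth(t, bandwidth=500, min_cpg_window=10)
        assert sm.shape == (3, 4)
        assert np.all((sm >= 0.2) & (sm <= 0.6))


class TestGroupTstat:
    def test_equal_means_give_zero(self):
        sm = np.tile([[0.5, 0.5, 0.5, 0.5]], (200, 1))
        t = table_from(np.arange(200) * 10, np.zeros((200, 4), int), np.full((200, 4), 10))
        ts = me.group_tstat(sm, t, "A", "B")
        assert np.allclose(ts, 0)

    def test_closed_form_hand_example(self):
        """Means (0.8, 0.3), pooled sd 0.1, n = 2 + 2: t = 0.5 / (0.1 * 1) = 5
        (the variance floor leaves a homogeneous-variance table unchanged)."""
        rng = np.random.default_rng(0)
        n = 400
        sm = np.empty((n, 4))
        sm[:, :2] = 0.8 + np.array([-0.1, 0.1]) * 1  # sample sd 0.1*sqrt(2) around 0.8?
        # construct exactly: group A values 0.8 +/- d, group B 0.3 +/- d with pooled sd 0.1
        d = 0.1  # each group sd = d*sqrt(2)... use direct: values (0.9, 0.7) sd = 0.1*sqrt(2)
        sm[:, 0], sm[:, 1] = 0.8 + d, 0.8 - d
        sm[:, 2], sm[:, 3] = 0.3 + d, 0.3 - d
        # pooled sd = sqrt((2*d^2 + 2*d^2)/2) = d*sqrt(2); make pooled sd 0.1 -> d = 0.1/sqrt(2)
        d = 0.1 / np.sqrt(2)
        sm[:, 0], sm[:, 1] = 0.8 + d, 0.8 - d
        sm[:, 2], sm[:, 3] = 0.3 + d, 0.3 - d
        t = table_from(np.arange(n) * 10, np.zeros((n, 4), int), np.full((n, 4), 10))
        ts = me.group_tstat(sm, t, "A", "B")
        assert np.allclose(ts, 0.5 / (0.1 * np.sqrt(1 / 2 + 1 / 2)))

    def test_antisymmetric_in_group_order(self, meth_small):
        t, _ = meth_small
        sm = me.smooth(t)
        assert np.allclose(me.group_tstat(sm, t, "A", "B"), -me.group_tstat(sm, t, "B", "A"))

    def test_single_sample_group_rejected(self):
        t = table_from([10], [[1, 1, 1]], [[5, 5, 5]], groups=("A", "A", "B"))
        with pytest.raises(ValueError, match="2 samples"):
            me.group_tstat(np.array([[0.5, 0.5, 0.5]]), t, "A", "B")


def synthetic_tstat_table(qualifying_positions, all_positions, t_hi=10.0, diff=0.5):
    """A table + t-stats + smoothed levels where exactly the chosen
    positions carry extreme positive t and a large group difference."""
    n = len(all_positions)
    t = table_from(all_positions, np.zeros((n, 4), int), np.full((n, 4), 10))
    rng = np.random.default_rng(0)
    tstats = rng.normal(0, 0.1, n)
    sm = np.full((n, 4), 0.5)
    qual = np.isin(all_positions, qualifying_positions)
    tstats[qual] = t_hi
    sm[qual, 0] = sm[qual, 1] = 0.5 + diff / 2
    sm[qual, 2] = sm[qual, 3] = 0.5 - diff / 2
    # pad with background CpGs so quantile estimation is allowed
    return t, tstats, sm


class TestFindDmrs:
    def test_toy_run_enumeration(self):
        """CpGs at 0,100,250,600,650,700 with qualifying t only at the first
        three (gaps <= 300): exactly one DMR spanning [0, 252) with 3 CpGs."""
        all_pos = np.concatenate([[0, 100, 250, 600, 650, 700], 1000 + np.arange(200) * 37])
        t, ts, sm = synthetic_tstat_table([0, 100, 250], all_pos)
        dmrs = me.find_dmrs(ts, t, sm, "A", "B")
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_cpg) == (0, 252, 3)
        assert d.direction == "hyper" and d.mean_diff == pytest.approx(0.5)

    def test_two_qualifying_cpgs_insufficient(self):
        all_pos = np.concatenate([[0, 100], 1000 + np.arange(200) * 37])
        t, ts, sm = synthetic_tstat_table([0, 100], all_pos)
        assert me.find_dmrs(ts, t, sm, "A", "B") == []

    def test_large_gap_splits_runs(self):
        all_pos = np.concatenate([[0, 100, 250, 600], 1000 + np.arange(400) * 37])
        t, ts, sm = synthetic_tstat_table([0, 100, 250, 600], all_pos)
        dmrs = me.find_dmrs(ts, t, sm, "A", "B")
        # 600 is 350 bp from 250: it cannot extend the run
        assert len(dmrs) == 1 and dmrs[0].end == 252

    def test_no_group_difference_yields_nothing(self):
        n = 300
        t = table_from(np.arange(n) * 11, np.full((n, 4), 5), np.full((n, 4), 10))
        sm = me.smooth(t)
        ts = me.group_tstat(sm, t, "A", "B")
        assert me.find_dmrs(ts, t, sm, "A", "B") == []

    def test_refuses_tiny_genome(self):
        t = table_from(np.arange(50) * 10, np.zeros((50, 4), int), np.full((50, 4), 10))
        with pytest.raises(ValueError, match="100 CpGs"):
            me.find_dmrs(np.zeros(50), t, np.full((50, 4), 0.5), "A", "B")

    def test_regions_satisfy_all_four_criteria(self, meth_small):
        t, _ = meth_small
        ft = me.coverage_filter(t, 5, 2)
        sm = me.smooth(ft)
        ts = me.group_tstat(sm, ft, "A", "B")
        lo, hi = np.quantile(ts, [0.01, 0.99])
        pos = ft.df["pos"].to_numpy()
        dmrs = me.find_dmrs(ts, ft, sm, "A", "B")
        assert dmrs
        for d in dmrs:
            inside = (pos >= d.start) & (pos < d.end)
            member_t = ts[inside]
            assert d.n_cpg >= 3
            assert np.max(np.diff(pos[inside])) <= 300
            assert abs(d.mean_diff) >= 0.25
            assert np.all((member_t < lo) | (member_t > hi))

    def test_group_swap_flips_direction_same_intervals(self, meth_small):
        t, _ = meth_small
        ft = me.coverage_filter(t, 5, 2)
        sm = me.smooth(ft)
        ts = me.group_tstat(sm, ft, "A", "B")
        fwd = me.find_dmrs(ts, ft, sm, "A", "B")
        rev = me.find_dmrs(-ts, ft, sm, "B", "A")
        assert [(d.start, d.end) for d in fwd] == [(d.start, d.end) for d in rev]
        assert all(a.direction != b.direction for a, b in zip(fwd, rev))

    def test_planted_recovery(self, meth_small):
        t, truth = meth_small
        ft = me.coverage_filter(t, 5, 2)
        sm = me.smooth(ft)
        ts = me.group_tstat(sm, ft, "A", "B")
        dmrs = me.find_dmrs(ts, ft, sm, "A", "B")
        planted = [(s, e) for _, s, e, _ in truth.dmr_intervals]
        hits = sum(any(d.start < e and d.end > s for s, e in planted) for d in dmrs)
        recall = sum(any(d.start < e and d.end > s for d in dmrs) for s, e in planted) / len(planted)
        assert hits / len(dmrs) >= 0.9 and recall >= 0.9


class TestPairwiseAndAnnotation:
    def _dmr(self, start, end, contrast="x"):
        return me.DMR("chrS", start, end, 3, 0.3, "hyper", 10.0, contrast)

    def test_union_merges_overlaps_with_tags(self, monkeypatch):
        t, _ = make_methylome(n_cpg=300, n_dmr=2, delta=0.4, seed=0)
        calls = iter(
            [
                [self._dmr(0, 100, "A_vs_B"), self._dmr(500, 700, "A_vs_B")],
                [self._dmr(50, 120, "A_vs_C"), self._dmr(900, 950, "A_vs_C")],
            ]
        )
        monkeypatch.setattr(me, "find_dmrs", lambda *a, **k: next(calls))
        monkeypatch.setattr(me, "group_tstat", lambda *a, **k: np.zeros(t.n_cpg))
        out = me.pairwise_dmr_sets(t, [("A", "B"), ("A", "C")])
        assert len(out) == 3
        merged = out.loc[(out["start"] == 0) & (out["end"] == 120)].iloc[0]
        assert sorted(merged["contrasts"]) == ["A_vs_B", "A_vs_C"]
        # non-overlap invariant
        for chrom, sub in out.groupby("chrom"):
            s = sub.sort_values("start")
            assert np.all(s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1])

    def test_promoter_annotation_nearest_tss_within_window(self):
        genes = pd.DataFrame({"gene": ["x", "y"], "chrom": ["chrS", "chrS"], "tss": [100, 5000]})
        on_tss = self._dmr(50, 150)
        beyond = self._dmr(8000, 8010)  # midpoint 8005: >2000 bp from both TSSs
        out = me.annotate_promoter([on_tss, beyond], genes, window=2000)
        assert out[0].annotated_gene == "x"
        mid = (beyond.start + beyond.end) // 2
        assert min(abs(mid - 100), abs(mid - 5000)) > 2000
        assert out[1].annotated_gene is None

    def test_annotation_matches_brute_force_scan(self, meth_small):
        rng = np.random.default_rng(1)
        genes = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(30)], "chrom": "chrS", "tss": np.sort(rng.integers(0, 10**6, 30))}
        )
        dmrs = [self._dmr(int(s), int(s) + 120) for s in rng.integers(0, 10**6, 40)]
        out = me.annotate_promoter(dmrs, genes, window=2000)
        for d in out:
            mid = (d.start + d.end) // 2
            dist = np.abs(genes["tss"] - mid)
            expected = genes["gene"].iloc[dist.idxmin()] if dist.min() <= 2000 else None
            assert d.annotated_gene == expected
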