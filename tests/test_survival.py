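"""Kaplan-Meier, log-rank, group comparisons, chi-square."""
import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from metimm.survival import chisq_independence, compare_groups, kaplan_meier, logrank_test


class TestKaplanMeier:
    def test_all_censored_survival_one(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.survival_at(10.0) == 1.0
        assert len(curve.times) == 0

    def test_single_event_one_step(self):
        curve = kaplan_meier([3.0, 5.0, 6.0, 7.0, 9.0], [1, 0, 0, 0, 0])
        assert curve.survival_at(3.0) == pytest.approx(4 / 5, abs=1e-12)
        assert curve.survival_at(2.9) == 1.0

    def test_classic_interleaved_toy_hand_computed(self):
        # events at 1, 3, 5; censored at 2, 4; event at 6
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 0, 1, 0, 1, 1]
        curve = kaplan_meier(times, events)
        # S(1)=5/6; S(3)=5/6*3/4; S(5)=5/6*3/4*1/2; S(6)=0
        np.testing.assert_allclose(
            curve.survival,
            [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 1 / 2, 0.0],
            atol=1e-12,
        )

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        times = rng.exponential(10, 40)
        curve = kaplan_meier(times, np.ones(40, dtype=int))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 60)
        events = (rng.random(60) < 0.7).astype(int)
        curve = kaplan_meier(times, events)
        fitter = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(fitter.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier([], [])


def _logrank_oracle(times, events, groups):
    """Two-group log-rank sums coded directly from the O/E/V definitions."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    o = e = v = 0.0
    for et in sorted(set(times[events == 1])):
        n = (times >= et).sum()
        d = ((times == et) & (events == 1)).sum()
        n1 = ((times >= et) & (groups == labels[0])).sum()
        d1 = ((times == et) & (events == 1) & (groups == labels[0])).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o - e) ** 2 / v
    return chi2, stats.chi2.sf(chi2, 1)


class TestLogRank:
    def test_identical_groups_null(self):
        times = [1.0, 2.0, 3.0, 4.0] * 2
        events = [1, 1, 0, 1] * 2
        groups = ["a"] * 4 + ["b"] * 4
        res = logrank_test(times, events, groups)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_p_consistent_with_chi_square_tail(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(5, 30)
        events = (rng.random(30) < 0.8).astype(int)
        groups = rng.choice(["a", "b", "c"], 30)
        res = logrank_test(times, events, groups)
        assert res.df == 2
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, res.df), abs=1e-15)

    def test_two_group_toy_matches_direct_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        groups = ["a", "b", "a", "b", "a", "b", "a", "b"]
        res = logrank_test(times, events, groups)
        chi2, p = _logrank_oracle(times, events, groups)
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_lifelines_multigroup(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(5, 90)
        events = (rng.random(90) < 0.8).astype(int)
        groups = rng.choice(["a", "b", "c"], 90)
        res = logrank_test(times, events, groups)
        reference = multivariate_logrank_test(times, groups, events)
        assert res.chi2 == pytest.approx(reference.test_statistic, rel=1e-8)
        assert res.p == pytest.approx(reference.p_value, rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestCompareGroups:
    def test_identical_groups_t_zero_and_u_half(self):
        values = [1.0, 2.0, 3.0] * 2
        groups = ["a"] * 3 + ["b"] * 3
        res_t = compare_groups(values, groups, "t")
        assert res_t["statistic"] == pytest.approx(0.0, abs=1e-12)
        res_u = compare_groups(values, groups, "mann-whitney")
        assert res_u["statistic"] == pytest.approx(9 / 2, abs=1e-12)

    def test_equal_group_means_anova_f_zero(self):
        values = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_groups(values, groups, "anova-tukey")
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["pairwise"] is not None and len(res["pairwise"]) == 3

    def test_t_matches_pooled_variance_hand_formula(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 7.0]
        res = compare_groups(a + b, ["a"] * 3 + ["b"] * 3, "t")
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * stats.t.sf(abs(t), 4)
        assert res["statistic"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-10)

    def test_t_with_three_groups_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            compare_groups([1.0] * 6, ["a", "a", "b", "b", "c", "c"], "t")

    def test_kruskal_dunn_pairwise_adjusted(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10),
                                 rng.normal(0.2, 1, 10)])
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = compare_groups(values, groups, "kruskal-dunn")
        pw = res["pairwise"]
        assert len(pw) == 3
        assert (pw["p_adj"] >= pw["p_raw"] - 1e-15).all()
        worst = pw.sort_values("p_adj").iloc[-1]
        assert {worst["group_a"], worst["group_b"]} == {"a", "c"}


class TestChiSquare:
    def test_proportional_rows_zero(self):
        chi2, df, p = chisq_independence([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_known_two_by_two(self):
        chi2, df, p = chisq_independence([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(100 / 15, abs=1e-10)
        assert df == 1

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            chisq_independence([[0, 0], [5, 5]])

    def test_permutation_invariance(self):
        table = np.array([[5, 9, 2], [7, 1, 6]])
        chi2, _, _ = chisq_independence(table)
        chi2_perm, _, _ = chisq_independence(table[::-1, ::-1])
        assert chi2 == pytest.approx(chi2_perm, abs=1e-12)
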