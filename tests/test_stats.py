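"""Proportion CIs, chi-square, t and rank-sum tests against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from rxaudit.stats import (
    proportion_ci,
    t_test_means,
    two_proportion_test,
    wilcoxon_rank_sum,
)


def moment_matched_series(mean: float, sd: float, n: int = 11) -> np.ndarray:
    """A series with exactly the requested sample mean and SD (ddof=1)."""
    base = np.arange(n, dtype=float)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


class TestProportionCI:
    # count/n pairs typical of a two-period prescription audit, with the
    # Wald interval each should produce at 2 decimals on the percent scale
    @pytest.mark.parametrize(
        "count,n,expected",
        [
            (5617, 31300, (17.95, 17.52, 18.37)),
            (6650, 41014, (16.21, 15.86, 16.57)),
            (12267, 72314, (16.96, 16.69, 17.24)),
            (30353, 72314, (41.97, 41.61, 42.33)),
            (29694, 72314, (41.06, 40.70, 41.42)),
            (12163, 31300, (38.86, 38.32, 39.40)),
            (18190, 41014, (44.35, 43.87, 44.83)),
        ],
    )
    def test_wald_intervals_to_two_decimals(self, count, n, expected):
        est = proportion_ci(count, n)
        assert est.rounded() == expected

    def test_wald_agrees_with_direct_formula(self):
        count, n = 123, 457
        est = proportion_ci(count, n)
        p = count / n
        z = sps.norm.ppf(0.975)
        half = z * np.sqrt(p * (1 - p) / n)
        assert est.percent == pytest.approx(100 * p, rel=1e-12)
        assert est.ci_low == pytest.approx(100 * (p - half), rel=1e-9)
        assert est.ci_high == pytest.approx(100 * (p + half), rel=1e-9)

    def test_degenerate_zero_count_collapses_under_wald(self):
        est = proportion_ci(0, 10)
        assert (est.percent, est.ci_low, est.ci_high) == (0.0, 0.0, 0.0)

    def test_wilson_option_does_not_collapse(self):
        est = proportion_ci(0, 10, method="wilson")
        assert est.ci_high > 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_ci(5, 4)

    def test_invariant_ordering(self):
        est = proportion_ci(3, 7)
        assert 0 <= est.ci_low <= est.percent <= est.ci_high <= 100


class TestTwoProportionTest:
    def test_large_audit_counts_are_significant(self):
        res = two_proportion_test(5617, 31300, 6650, 41014)
        assert res.p_value < 0.001
        assert res.statistic > 0

    def test_identical_proportions(self):
        res = two_proportion_test(50, 100, 50, 100)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        a = two_proportion_test(30, 120, 45, 150)
        b = two_proportion_test(45, 150, 30, 120)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_statistic_equals_squared_z(self):
        """Pearson chi-square on a 2x2 table is the squared pooled z-statistic."""
        c1, n1, c2, n2 = 37, 210, 52, 190
        p1, p2, pooled = c1 / n1, c2 / n2, (c1 + c2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        res = two_proportion_test(c1, n1, c2, n2)
        assert res.statistic == pytest.approx(z**2, rel=1e-10)

    def test_small_table_near_exact_reference(self):
        """At 3/10 vs 7/10 the chi-square p sits within the documented
        distance of the exact conditional (Fisher) reference."""
        res = two_proportion_test(3, 10, 7, 10)
        fisher = sps.fisher_exact([[3, 7], [7, 3]])
        assert res.statistic >= 0
        assert abs(res.p_value - fisher.pvalue) < 0.15
        assert res.p_value < fisher.pvalue  # uncorrected chi-square is anticonservative here

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 10, 0, 10)
        with pytest.raises(ValueError):
            two_proportion_test(12, 10, 3, 10)


class TestTTestMeans:
    def test_identical_series(self):
        a = [4.0, 5.0, 6.0]
        res = t_test_means(a, a)
        assert res.p_value == pytest.approx(1.0)

    def test_borderline_monthly_volumes(self):
        """Monthly volumes differing by ~0.8 pooled SDs over 11 months sit
        right at the conventional significance boundary."""
        a = moment_matched_series(4284.64, 200.68)
        b = moment_matched_series(4121.00, 180.74)
        res = t_test_means(a, b)
        assert res.test_name == "t_welch"
        assert 0.05 < res.p_value < 0.07

    def test_large_shift_is_significant(self):
        a = moment_matched_series(4000.0, 200.0)
        res = t_test_means(a, a + 1000.0)
        assert res.p_value < 0.001

    def test_pooled_option(self):
        a = moment_matched_series(10.0, 2.0, n=8)
        b = moment_matched_series(12.0, 2.0, n=8)
        welch = t_test_means(a, b, welch=True)
        pooled = t_test_means(a, b, welch=False)
        # equal variances and n: identical statistic, pooled df larger
        assert welch.statistic == pytest.approx(pooled.statistic, rel=1e-12)
        assert pooled.df >= welch.df

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            t_test_means([1.0], [1.0, 2.0])


def exact_rank_sum_p(x, y) -> float:
    """Brute-force two-sided permutation p for the rank-sum statistic."""
    combined = np.asarray(list(x) + list(y), dtype=float)
    ranks = sps.rankdata(combined)
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in itertools.combinations(range(len(combined)), n1)]
    )
    p_le = np.mean(sums <= observed + 1e-12)
    p_ge = np.mean(sums >= observed - 1e-12)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxonRankSum:
    def test_identical_distributions(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_all_tied_degenerate_case_warns(self):
        with pytest.warns(UserWarning, match="tied"):
            res = wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert res.p_value == 1.0

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 1, 1, 2, 2], [1, 1, 2, 2, 2]),  # heavily tied counts
            ([1, 2, 2, 3, 5], [2, 3, 3, 4, 4]),
            ([1, 1, 2], [2, 3, 3, 4]),
        ],
    )
    def test_exact_route_matches_enumeration_oracle(self, x, y):
        res = wilcoxon_rank_sum(x, y, exact=True)
        assert res.p_value == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_dominated_arm_is_significant(self):
        rng = np.random.default_rng(7)
        a = rng.integers(1, 4, size=50).astype(float)
        res = wilcoxon_rank_sum(a, a + 10.0)
        assert res.p_value < 0.01

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
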