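"""Statistical layer: proportions with Wald CIs, chi-square, t and rank-sum tests.

Proportion intervals default to the Wald (normal-approximation) form
p +/- z*sqrt(p(1-p)/n); Wilson is available behind a flag.  Two-proportion
comparisons use the Pearson chi-square on the 2x2 table without continuity
correction, whose statistic equals the squared two-proportion z-statistic.
Monthly volumes are compared with a two-sample t test (Welch by default)
and per-patient-per-month counts with a rank-sum test using the
tie-corrected normal approximation, since those counts are heavily tied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ProportionEstimate",
    "TestResult",
    "proportion_ci",
    "two_proportion_test",
    "chi_square_table",
    "t_test_means",
    "wilcoxon_rank_sum",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used for display percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion on the percent (0-100) scale with its CI."""

    count: int
    n: int
    percent: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.percent, ndigits),
            round_half_up(self.ci_low, ndigits),
            round_half_up(self.ci_high, ndigits),
        )

    def __str__(self) -> str:
        p, lo, hi = self.rounded()
        return f"{self.count}/{self.n}, {p:.2f}% (95% CI {lo:.2f}-{hi:.2f})"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def proportion_ci(
    count: int, n: int, level: float = 0.95, method: str = "wald"
) -> ProportionEstimate:
    """Binomial proportion with a confidence interval on the percent scale.

    ``method="wald"`` (default) gives p +/- z*sqrt(p(1-p)/n), clipped to
    [0, 100].  At count 0 or n the Wald interval degenerates to zero
    width — a documented limitation of the method, kept because it is the
    interval form the audit reports.  ``method="wilson"`` is available
    for sensitivity analysis.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in [0, n], got {count}/{n}")
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(count, n, alpha=1.0 - level, method=sm_method)
    lo, hi = max(lo, 0.0), min(hi, 1.0)
    return ProportionEstimate(
        count=count,
        n=n,
        percent=100.0 * count / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        ci_level=level,
    )


def two_proportion_test(
    count1: int, n1: int, count2: int, n2: int, correction: bool = False
) -> TestResult:
    """Pearson chi-square comparison of two binomial proportions.

    Without continuity correction (the default), the statistic equals the
    squared two-proportion z-statistic; Yates correction is available but
    immaterial at audit-scale counts.
    """
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts may not exceed their totals")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square is undefined with an empty margin")
    res = sps.chi2_contingency(table, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="chi2_2x2",
        df=1.0,
    )


def chi_square_table(table: Sequence[Sequence[int]], correction: bool = False) -> TestResult:
    """Pearson chi-square on an arbitrary contingency table (omnibus use)."""
    arr = np.asarray(table, dtype=float)
    res = sps.chi2_contingency(arr, correction=correction)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"chi2_{arr.shape[0]}x{arr.shape[1]}",
        df=float(res.dof),
    )


def t_test_means(
    series1: Sequence[float], series2: Sequence[float], welch: bool = True
) -> TestResult:
    """Two-sample t test on monthly prescription counts (Welch by default)."""
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t test needs at least two observations per series")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and np.mean(a) == np.mean(b):
        # identical constant series: no evidence of a difference
        return TestResult(statistic=0.0, p_value=1.0, test_name="t_welch" if welch else "t_pooled")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="t_welch" if welch else "t_pooled",
        df=float(res.df),
    )


def wilcoxon_rank_sum(
    series1: Sequence[float], series2: Sequence[float], exact: bool = False
) -> TestResult:
    """Two-sample rank-sum test with tie correction.

    Per-patient-per-month counts are heavily tied, so the default route is
    the tie-corrected normal approximation (Mann-Whitney U, two-sided).
    ``exact=True`` switches to full permutation enumeration of the
    rank-sum statistic — feasible only for small samples, used as the
    reference in validation.  A fully tied input carries no ordering
    information: p = 1 with a warning.
    """
    a = np.asarray(series1, dtype=float)
    b = np.asarray(series2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank-sum test needs nonempty series")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all observations tied; rank-sum test is degenerate", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, test_name="wilcoxon_rank_sum")
    if exact:
        def rank_sum_stat(x, y):
            ranks = sps.rankdata(np.concatenate([x, y]))
            return ranks[: len(x)].sum()

        res = sps.permutation_test(
            (a, b),
            rank_sum_stat,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            test_name="wilcoxon_rank_sum_exact",
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="wilcoxon_rank_sum",
    )
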