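"""Two-group contingency and rank statistics for the cohort comparison.

Continuous variables use the Wilcoxon rank-sum test (normal
approximation with tie correction and continuity correction).
Categorical 2×2 tables use Fisher's exact test when any expected cell is
below 5 and the continuity-corrected chi-square otherwise; k×2 tables
use the chi-square test.  Risk differences come with Wald 95% CIs and
the median length-of-stay difference with a seeded percentile-bootstrap
CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RiskDifference",
    "risk_difference",
    "median_difference",
    "two_group_test",
]


@dataclass(frozen=True)
class RiskDifference:
    """Absolute risk difference between two proportions, in percentage points."""

    p1_pct: float           # group-1 rate, rounded to one decimal (as printed)
    p2_pct: float
    diff_rounded_pct: float  # difference of the rounded rates
    diff_pct: float          # difference of the unrounded rates
    ci_low: float            # Wald 95% CI on the unrounded difference
    ci_high: float


def risk_difference(x1: int, n1: int, x2: int, n2: int) -> RiskDifference:
    """Absolute risk difference with a Wald 95% confidence interval.

    Rates are reported (and differenced) after rounding to one decimal
    percentage point, mirroring how such tables are printed; the
    unrounded difference and its Wald CI are carried alongside.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("event counts must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    p1_pct, p2_pct = round(100 * p1, 1), round(100 * p2, 1)
    d = 100 * (p1 - p2)
    se = 100 * math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return RiskDifference(
        p1_pct=p1_pct,
        p2_pct=p2_pct,
        diff_rounded_pct=round(p1_pct - p2_pct, 1),
        diff_pct=d,
        ci_low=d - 1.96 * se,
        ci_high=d + 1.96 * se,
    )


def median_difference(
    sample1, sample2, n_boot: int = 2000, seed: int | None = 0
) -> tuple[float, tuple[float, float]]:
    """Difference of medians with a seeded percentile-bootstrap 95% CI.

    Resampling is within-group with ``n_boot`` replicates (default
    2000).  Returns ``(difference, (ci_low, ci_high))``.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    diff = float(np.median(a) - np.median(b))
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boots = np.median(a[idx_a], axis=1) - np.median(b[idx_b], axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return diff, (float(lo), float(hi))


def two_group_test(
    kind: str, group1, group2=None
) -> tuple[float, float, str]:
    """Dispatch the comparison test for one variable.

    ``kind='continuous'``: ``group1``/``group2`` are samples; Wilcoxon
    rank-sum via the normal approximation with tie correction.
    ``kind='categorical'``: ``group1`` is a k×2 contingency table
    (rows = outcome levels, columns = groups); Fisher's exact test for
    2×2 tables with any expected cell < 5, chi-square otherwise.

    Returns ``(statistic, p_value, test_name)``; degenerate tables (a
    zero margin) return ``(nan, nan, 'not-applicable')``.
    """
    if kind == "continuous":
        a, b = np.asarray(group1, float), np.asarray(group2, float)
        if a.size == 0 or b.size == 0:
            return (float("nan"), float("nan"), "not-applicable")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return (float(res.statistic), float(res.pvalue), "wilcoxon-rank-sum")
    if kind != "categorical":
        raise ValueError(f"unknown kind {kind!r}")

    table = np.asarray(group1, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("contingency table must be k x 2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (float("nan"), float("nan"), "not-applicable")
    if table.shape[0] == 2:
        expected = sps.contingency.expected_freq(table)
        if (expected < 5).any():
            stat, p = sps.fisher_exact(table, alternative="two-sided")
            return (float(stat), float(p), "fisher-exact")
        chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        return (float(chi2), float(p), "chi-square")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return (float(chi2), float(p), "chi-square")
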