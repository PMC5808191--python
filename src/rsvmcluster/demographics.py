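"""Group-comparison statistics for cohort demographic tables.

Gender composition is compared with a Pearson chi-square test on the
2x2 male/female count table (no Yates continuity correction), and age
with a pooled-variance two-sample t-test computed from per-group
summary statistics.  Welch's unequal-variance t is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def gender_chisq(counts) -> tuple[float, float]:
    """Pearson chi-square (df=1, uncorrected) on a 2x2 count table.

    Returns ``(statistic, two_sided_p)``.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def age_ttest(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test from group summary statistics.

    Pooled-variance by default (df = n1 + n2 - 2); pass ``welch=True``
    for the unequal-variance form.  Returns ``(statistic, two_sided_p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 subjects")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(t), float(p)


@dataclass
class DemographicsSummary:
    """Per-group demographics and the two between-group tests."""

    gender_counts: np.ndarray  # 2x2: rows = groups, cols = (M, F)
    age_mean: tuple[float, float]
    age_sd: tuple[float, float]
    n: tuple[int, int]
    chisq_statistic: float
    chisq_p: float
    t_statistic: float
    t_p: float


def compare_groups(
    gender_counts,
    age_mean: tuple[float, float],
    age_sd: tuple[float, float],
    n: tuple[int, int],
    welch: bool = False,
) -> DemographicsSummary:
    """Run both demographic comparisons and bundle the results."""
    chi2, p_chi = gender_chisq(gender_counts)
    t, p_t = age_ttest(
        age_mean[0], age_sd[0], n[0], age_mean[1], age_sd[1], n[1], welch=welch
    )
    return DemographicsSummary(
        gender_counts=np.asarray(gender_counts),
        age_mean=age_mean,
        age_sd=age_sd,
        n=n,
        chisq_statistic=chi2,
        chisq_p=p_chi,
        t_statistic=t,
        t_p=p_t,
    )
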