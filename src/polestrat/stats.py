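"""Nonparametric group comparisons used throughout the cohort analysis.

Thin, opinionated wrappers over scipy/statsmodels: Mann-Whitney U with an
explicit exact-vs-approximate policy and a refusal rule for tiny samples,
Benjamini-Hochberg FDR adjustment, Spearman rank correlation, and the
midpoint-convention median-with-range used in the group tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import fdrcorrection

__all__ = [
    "ComparisonResult",
    "ComparisonRefused",
    "mann_whitney",
    "bh_fdr",
    "spearman",
    "median_range",
    "significance_stars",
]

MIN_N = 3  # comparisons with <= 2 datapoints in either arm are refused
EXACT_CUTOFF = 20  # exact permutation p only when both n <= this and no ties


class ComparisonRefused(Exception):
    """A comparison was declined (too few datapoints), with a reason."""


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    adjusted_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p below raw p")

    @property
    def stars(self) -> str:
        return significance_stars(self.adjusted_p if self.adjusted_p is not None else self.p_value)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
    label_a: str = "A",
    label_b: str = "B",
    exact_cutoff: int = EXACT_CUTOFF,
) -> ComparisonResult:
    """Mann-Whitney U comparison of two samples.

    U uses midranks for ties. The exact permutation null is used when both
    samples have at most ``exact_cutoff`` observations and there are no
    ties; otherwise a tie-corrected normal approximation with continuity
    correction. Samples with <= 2 datapoints are refused outright
    (:class:`ComparisonRefused`), never silently reported as p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < MIN_N or len(b) < MIN_N:
        raise ComparisonRefused(
            f"{label_a} (n={len(a)}) vs {label_b} (n={len(b)}): "
            "comparison refused with <=2 datapoints in an arm"
        )
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) <= exact_cutoff and len(b) <= exact_cutoff and not has_ties)
    res = sps.mannwhitneyu(
        a, b, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return ComparisonResult(
        group_a=label_a, group_b=label_b, n_a=len(a), n_b=len(b),
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        method="exact" if exact else "normal_approx",
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj = fdrcorrection(p, alpha=0.05, method="indep")
    return [float(x) for x in adj]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) with the midpoint convention for even n.

    The even-n median is the mean of the two central order statistics
    (no interpolation beyond the midpoint), matching values like 264.5
    reported for group TMB tables.
    """
    v = sorted(float(x) for x in values)
    if not v:
        raise ValueError("median of empty list")
    n = len(v)
    mid = n // 2
    med = v[mid] if n % 2 else (v[mid - 1] + v[mid]) / 2.0
    return med, v[0], v[-1]
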