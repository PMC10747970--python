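"""Normality-gated two-tailed paired comparison of the two systems.

Per parameter the per-subject differences d_i = reference_i - test_i are
screened with the Shapiro-Wilk test; if they look Gaussian (p >= alpha)
a paired Student t-test compares the system means, otherwise a Wilcoxon
signed-rank test compares the distributions.  Both tests are two-tailed.
Normality is assessed on the differences — the quantity whose
distribution the paired tests actually assume — rather than on each
system's arm separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError
from .types import AnalysisConfig, PairedSeries

__all__ = ["NormalityResult", "PairedTestResult", "shapiro_wilk", "paired_compare"]

_EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk test outcome on a sample."""

    statistic: float  # W, in (0, 1]
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of the gated paired comparison.

    ``method`` records which branch the normality gate selected;
    ``flags`` carries degenerate-input annotations (e.g. all differences
    zero), in which case ``normality`` is None.
    """

    method: str  # "t_student" | "wilcoxon"
    statistic: float
    p_value: float
    significant: bool
    normality: Optional[NormalityResult]
    flags: tuple[str, ...] = ()


def shapiro_wilk(values) -> NormalityResult:
    """Shapiro-Wilk normality test.

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 3 <= n <= 5000:
        raise DegenerateInputError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={n}"
        )
    if np.ptp(values) == 0:
        raise DegenerateInputError("Shapiro-Wilk undefined for constant input")
    res = stats.shapiro(values)
    return NormalityResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), n=n
    )


def _wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank with classic zero handling.

    Zero differences are discarded; the exact null distribution is used
    for n_nonzero <= 25 with no tied absolute differences, otherwise the
    normal approximation with continuity correction and tie-corrected
    variance (midranks).
    """
    nonzero = d[d != 0]
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= _EXACT_WILCOXON_MAX_N and not ties
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue)


def paired_compare(
    series: PairedSeries, config: AnalysisConfig | None = None
) -> PairedTestResult:
    """Run the normality-gated paired test on one parameter's series.

    Degenerate cases: if every difference is zero the no-difference
    convention applies (statistic 0, p = 1, flagged); constant nonzero
    differences bypass the gate (Shapiro-Wilk is undefined) and go to the
    Wilcoxon branch, flagged.
    """
    config = config or AnalysisConfig()
    if series.n < 3:
        raise DegenerateInputError(f"paired test requires n >= 3, got {series.n}")
    d = series.differences()

    if np.all(d == 0):
        return PairedTestResult(
            method="wilcoxon",
            statistic=0.0,
            p_value=1.0,
            significant=False,
            normality=None,
            flags=("all_differences_zero",),
        )
    if np.ptp(d) == 0:  # constant nonzero offset
        statistic, p = _wilcoxon(d)
        return PairedTestResult(
            method="wilcoxon",
            statistic=statistic,
            p_value=p,
            significant=p < config.alpha,
            normality=None,
            flags=("constant_differences",),
        )

    normality = shapiro_wilk(d)
    if normality.p_value >= config.alpha:
        res = stats.ttest_rel(series.ref_values, series.test_values)
        statistic, p, method = float(res.statistic), float(res.pvalue), "t_student"
    else:
        statistic, p = _wilcoxon(d)
        method = "wilcoxon"
    return PairedTestResult(
        method=method,
        statistic=statistic,
        p_value=p,
        significant=p < config.alpha,
        normality=normality,
    )
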