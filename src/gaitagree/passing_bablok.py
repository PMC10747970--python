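"""Passing-Bablok non-parametric regression of test on reference values.

The structural line ``test = q + m * reference`` is estimated from the
median of all pairwise slopes, shifted to correct for the method's
negative-slope bias, with distribution-free confidence bounds read off
the ranked slopes.  Unlike ordinary least squares the estimator tolerates
measurement error in both variables and is insensitive to outliers, which
is why it is the standard regression in method-comparison studies: a
slope confidence interval excluding 1 signals a proportional systematic
error, an intercept interval excluding 0 a constant one.

The estimator follows the original procedure for method comparison over
the natural measuring range: pairwise slopes S_ij = (y_j - y_i) /
(x_j - x_i) for i < j, slopes of exactly -1 discarded, the estimate being
the median of the ranked slopes offset by K = #{S_ij < -1}, and the
1 - alpha confidence bounds the order statistics at ranks M1 + K and
M2 + K with M1 = round((N - C)/2), M2 = N - M1 + 1,
C = z_{1-alpha/2} * sqrt(n (n - 1) (2 n + 5) / 18).

A cusum-of-residual-signs statistic checks the linearity precondition:
walking the points in order of increasing reference value, the running
sum of residual signs should stay small if the relation is linear; its
maximum absolute excursion, scaled by sqrt(number of nonzero residuals),
is compared against the Kolmogorov-Smirnov critical value (1.36 at the
5% level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from ._numeric import round_half_away
from .exceptions import CIUndefinedError, DegenerateFitError
from .types import AnalysisConfig, PairedSeries

__all__ = [
    "LinearityResult",
    "PBResult",
    "pairwise_slopes",
    "pb_fit",
    "cusum_linearity",
]


@dataclass(frozen=True)
class LinearityResult:
    """Cusum linearity check attached to a Passing-Bablok fit."""

    statistic: float  # H >= 0
    critical_value: float
    linear: bool  # H <= critical_value
    n_scores: int  # nonzero residuals entering the cusum


@dataclass(frozen=True)
class PBResult:
    """Passing-Bablok slope/intercept estimates with rank-based CIs.

    ``n_slopes`` is N, the number of valid pairwise slopes (infinities
    included, exact -1 slopes and 0/0 pairs excluded); ``k_offset`` is K,
    the count of slopes below -1 used to shift the median.
    """

    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    n: int
    n_slopes: int
    k_offset: int
    linearity: Optional[LinearityResult] = None

    @property
    def m(self) -> float:
        return self.slope

    @property
    def q(self) -> float:
        return self.intercept


def pairwise_slopes(series: PairedSeries) -> tuple[np.ndarray, int]:
    """All pairwise slopes S_ij, sorted ascending, plus the offset K.

    Pairs with identical (reference, test) coordinates contribute nothing;
    vertical pairs (equal reference, different test) contribute signed
    infinity, ordered at the extremes; slopes exactly equal to -1 are
    excluded.  K counts slopes below -1 (including -inf).
    """
    x = series.ref_values
    y = series.test_values
    n = series.n
    if n < 3:
        raise DegenerateFitError(f"Passing-Bablok requires n >= 3, got {n}")
    if np.unique(x).size < 2:
        raise DegenerateFitError("need at least 2 distinct reference values")
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    slopes = np.empty(dx.size)
    vertical = dx == 0
    with np.errstate(invalid="ignore"):
        slopes[~vertical] = dy[~vertical] / dx[~vertical]
        slopes[vertical] = np.sign(dy[vertical]) * np.inf  # 0/0 -> nan
    keep = ~(vertical & (dy == 0)) & (slopes != -1.0)
    slopes = np.sort(slopes[keep])
    if np.sum(np.isfinite(slopes)) < 3:
        raise DegenerateFitError(
            f"only {int(np.sum(np.isfinite(slopes)))} finite pairwise slopes"
        )
    k_offset = int(np.sum(slopes < -1.0))
    return slopes, k_offset


def _shifted_median(slopes: np.ndarray, k: int) -> float:
    """Median of the ranked slopes shifted by K (1-indexed ranks)."""
    n_slopes = slopes.size
    if n_slopes % 2 == 1:
        value = slopes[(n_slopes + 1) // 2 + k - 1]
    else:
        lo = slopes[n_slopes // 2 + k - 1]
        hi = slopes[n_slopes // 2 + k]
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise DegenerateFitError(
                "central order statistic is infinite; slope undefined"
            )
        value = 0.5 * (lo + hi)
    if not np.isfinite(value):
        raise DegenerateFitError(
            "central order statistic is infinite; slope undefined"
        )
    return float(value)


def pb_fit(
    series: PairedSeries,
    config: AnalysisConfig | None = None,
    linearity: bool = True,
) -> PBResult:
    """Fit the Passing-Bablok structural line with rank-based CIs.

    Raises
    ------
    CIUndefinedError
        When n is too small for confidence bounds at the requested level;
        the exception's ``partial`` attribute carries the point estimates
        with NaN bounds.
    """
    config = config or AnalysisConfig()
    x = series.ref_values
    y = series.test_values
    n = series.n
    slopes, k = pairwise_slopes(series)
    n_slopes = slopes.size

    slope = _shifted_median(slopes, k)
    intercept = float(np.median(y - slope * x))

    z = stats.norm.ppf(1.0 - config.alpha / 2.0)
    c = z * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round_half_away((n_slopes - c) / 2.0, 0))
    m2 = n_slopes - m1 + 1

    result = PBResult(
        slope=slope,
        slope_ci=(np.nan, np.nan),
        intercept=intercept,
        intercept_ci=(np.nan, np.nan),
        n=n,
        n_slopes=n_slopes,
        k_offset=k,
    )
    if m1 + k < 1 or m2 + k > n_slopes:
        if linearity:
            result = replace(
                result, linearity=cusum_linearity(series, slope, intercept,
                                                  alpha=config.alpha)
            )
        raise CIUndefinedError(
            f"n={n} too small for {1 - config.alpha:.0%} slope bounds "
            f"(ranks {m1 + k}..{m2 + k} outside 1..{n_slopes})",
            partial=result,
        )
    slope_lb = float(slopes[m1 + k - 1])
    slope_ub = float(slopes[m2 + k - 1])
    # intercept bounds pair with the opposite slope bound
    intercept_lb = float(np.median(y - slope_ub * x))
    intercept_ub = float(np.median(y - slope_lb * x))
    result = replace(
        result,
        slope_ci=(slope_lb, slope_ub),
        intercept_ci=(intercept_lb, intercept_ub),
    )
    if linearity:
        result = replace(
            result,
            linearity=cusum_linearity(series, slope, intercept,
                                      alpha=config.alpha),
        )
    return result


def cusum_linearity(
    series: PairedSeries,
    slope: float,
    intercept: float,
    alpha: float = 0.05,
) -> LinearityResult:
    """Cusum test of the linearity precondition.

    Residual signs are accumulated in order of increasing reference value
    (ties broken by test value); zero residuals are dropped.  The
    statistic is the maximum absolute partial sum divided by sqrt(L),
    compared against the Kolmogorov-Smirnov critical value (1.36 at
    alpha = 0.05).  A perfect fit (no nonzero residuals) is linear by
    convention with H = 0.
    """
    x = series.ref_values
    y = series.test_values
    residuals = y - (intercept + slope * x)
    # relative tolerance guards against sign noise on an exact line
    tol = 1e-12 * max(1.0, float(np.max(np.abs(y)))) if y.size else 0.0
    scores = np.where(residuals > tol, 1.0, np.where(residuals < -tol, -1.0, 0.0))
    order = np.lexsort((y, x))
    scores = scores[order]
    scores = scores[scores != 0]
    critical = float(stats.kstwobign.isf(alpha))
    if scores.size == 0:
        return LinearityResult(0.0, critical, True, 0)
    h = float(np.max(np.abs(np.cumsum(scores))) / np.sqrt(scores.size))
    return LinearityResult(h, critical, h <= critical, int(scores.size))
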