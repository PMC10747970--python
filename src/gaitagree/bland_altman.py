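"""Bland-Altman agreement analysis.

For each subject the difference d_i = reference_i - test_i is paired with
the mean (reference_i + test_i) / 2.  The *bias* is the mean difference,
the *limits of agreement* are bias +/- 1.96 * SD(d) (the range expected
to contain ~95% of differences under normality), and a t-based interval
expresses the uncertainty of the bias itself.  Two regression diagnostics
flag pathologies a practitioner would otherwise read off the plot: a
linear trend of d on the pair means (proportional error) and a rank
correlation of |d - bias| with the pair means (heteroscedasticity, the
"fan shape").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError
from .types import AnalysisConfig, PairedSeries

__all__ = ["BATrend", "BAResult", "ba_fit", "ba_trend"]


@dataclass(frozen=True)
class BATrend:
    """Trend diagnostics of the difference-vs-mean scatter."""

    slope_of_diff_on_mean: float
    trend_p: float
    proportional_trend: bool
    hetero_p: float
    heteroscedastic: bool


@dataclass(frozen=True)
class BAResult:
    """Bias, its confidence interval, and the limits of agreement.

    Invariants: ``loa`` midpoint equals ``bias`` and its half-width equals
    ``loa_multiplier * sd_diff`` exactly.
    """

    bias: float
    sd_diff: float
    bias_ci: tuple[float, float]
    loa: tuple[float, float]
    loa_multiplier: float
    n: int
    trend: Optional[BATrend] = None
    flags: tuple[str, ...] = ()


def ba_trend(
    d: np.ndarray, means: np.ndarray, config: AnalysisConfig | None = None
) -> BATrend:
    """Fit the two trend diagnostics on (difference, pair-mean) points.

    Proportional trend: two-sided p of the OLS slope of d on means.
    Heteroscedasticity: two-sided p of the Spearman correlation between
    |d - mean(d)| and the pair means.
    """
    config = config or AnalysisConfig()
    d = np.asarray(d, dtype=float)
    means = np.asarray(means, dtype=float)
    if d.size < 4:
        raise DegenerateInputError(f"trend tests require n >= 4, got {d.size}")
    if np.ptp(means) == 0:
        raise DegenerateInputError("trend undefined: constant pair means")
    ols = stats.linregress(means, d)
    rho = stats.spearmanr(np.abs(d - d.mean()), means)
    hetero_p = float(rho.pvalue) if np.isfinite(rho.pvalue) else 1.0
    return BATrend(
        slope_of_diff_on_mean=float(ols.slope),
        trend_p=float(ols.pvalue),
        proportional_trend=float(ols.pvalue) < config.alpha,
        hetero_p=hetero_p,
        heteroscedastic=hetero_p < config.alpha,
    )


def ba_fit(
    series: PairedSeries, config: AnalysisConfig | None = None
) -> BAResult:
    """Bland-Altman analysis of one parameter's paired series.

    The SD of differences uses the n-1 denominator; the bias CI is
    ``bias +/- t_{1-alpha/2, n-1} * sd / sqrt(n)``.  With zero SD the
    limits collapse onto the bias and the trend diagnostics are skipped
    (flagged).
    """
    config = config or AnalysisConfig()
    n = series.n
    if n < 3:
        raise DegenerateInputError(f"Bland-Altman requires n >= 3, got {n}")
    d = series.differences()
    means = series.pair_means()
    bias = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    half = config.loa_multiplier * sd_diff
    t_crit = float(stats.t.ppf(1.0 - config.alpha / 2.0, n - 1))
    se = sd_diff / np.sqrt(n)

    flags: tuple[str, ...] = ()
    trend = None
    if sd_diff == 0:
        flags += ("zero_variance_differences", "trend_undefined")
    elif n < 4 or np.ptp(means) == 0:
        flags += ("trend_undefined",)
    else:
        trend = ba_trend(d, means, config)
    return BAResult(
        bias=bias,
        sd_diff=sd_diff,
        bias_ci=(bias - t_crit * se, bias + t_crit * se),
        loa=(bias - half, bias + half),
        loa_multiplier=config.loa_multiplier,
        n=n,
        trend=trend,
        flags=flags,
    )
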