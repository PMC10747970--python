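"""Monte-Carlo calibration of the analysis stages.

Three simulation studies verify that the pipeline behaves as a
statistician would demand before trusting it on real data:

* ``null_type_one_error`` — under interchangeable systems the gated
  paired test should reject at about the nominal level alpha;
* ``slope_recovery`` — the Passing-Bablok slope should recover a known
  generative proportional factor with negligible bias;
* ``slope_ci_coverage`` — the rank-based slope CI should contain the
  generative slope in about 95% of replicates;

plus ``verdict_rates``, an end-to-end check that injected error
structures produce the expected dominant verdict.  Per-replicate seeds
derive from a single master seed, so every summary is reproducible.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .exceptions import GaitAgreeError
from .io import average_trials
from .model import MethodComparison
from .paired_tests import paired_compare
from .passing_bablok import pb_fit
from .synthetic import SyntheticConfig, generate, simulate_pairs
from .types import AnalysisConfig

__all__ = [
    "null_type_one_error",
    "slope_recovery",
    "slope_ci_coverage",
    "verdict_rates",
]


def _replicate_rngs(master_seed: int, n_reps: int):
    """One independent generator per replicate, derived from a master seed."""
    for child in np.random.SeedSequence(master_seed).spawn(n_reps):
        yield np.random.default_rng(child)


def null_type_one_error(
    n_reps: int = 5000,
    n: int = 15,
    truth_mean: float = 91.72,
    truth_sd: float = 14.23,
    sigma: float | None = None,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the gated paired test under the null.

    Both systems observe a common Gaussian truth with independent
    Gaussian noise (defaults: the cadence population, noise SD 2% of the
    truth mean).  Returns the rejection fraction and its Monte-Carlo
    standard error.
    """
    if n_reps < 100:
        raise GaitAgreeError(f"need n_reps >= 100, got {n_reps}")
    config = config or AnalysisConfig()
    sigma = 0.02 * truth_mean if sigma is None else sigma
    rejections = 0
    for rng in _replicate_rngs(seed, n_reps):
        series = simulate_pairs(
            rng, n, truth_mean, truth_sd,
            slope=1.0, intercept=0.0, sigma_ref=sigma, sigma_test=sigma,
        )
        if paired_compare(series, config).significant:
            rejections += 1
    rate = rejections / n_reps
    return {
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / n_reps)),
        "n_reps": n_reps,
        "n": n,
        "alpha": config.alpha,
    }


def slope_recovery(
    n_reps: int = 1000,
    n: int = 15,
    truth_mean: float = 0.41,
    truth_sd: float = 0.10,
    slope: float = 2.10,
    intercept: float = -0.06,
    sigma: float = 0.02,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the Passing-Bablok slope.

    Defaults reproduce a stride-length-like generative model: truth
    ~ Normal(0.41, 0.10^2) metres, measurement noise SD 0.02 on both
    axes, test = -0.06 + 2.10 * truth.
    """
    if n_reps < 100:
        raise GaitAgreeError(f"need n_reps >= 100, got {n_reps}")
    config = config or AnalysisConfig()
    slopes = np.empty(n_reps)
    intercepts = np.empty(n_reps)
    for r, rng in enumerate(_replicate_rngs(seed, n_reps)):
        series = simulate_pairs(
            rng, n, truth_mean, truth_sd,
            slope=slope, intercept=intercept,
            sigma_ref=sigma, sigma_test=sigma,
        )
        fit = pb_fit(series, config, linearity=False)
        slopes[r] = fit.slope
        intercepts[r] = fit.intercept
    return {
        "mean_slope": float(np.mean(slopes)),
        "slope_bias": float(np.mean(slopes) - slope),
        "slope_rmse": float(np.sqrt(np.mean((slopes - slope) ** 2))),
        "mean_intercept": float(np.mean(intercepts)),
        "mc_se": float(np.std(slopes, ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
        "n": n,
        "generative_slope": slope,
        "generative_intercept": intercept,
    }


def slope_ci_coverage(
    n_reps: int = 1000,
    n: int = 50,
    truth_mean: float = 10.0,
    truth_sd: float = 2.0,
    slope: float = 1.0,
    intercept: float = 0.0,
    sigma: float = 0.3,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict:
    """Empirical coverage (in %) of the Passing-Bablok slope CI."""
    if n_reps < 100:
        raise GaitAgreeError(f"need n_reps >= 100, got {n_reps}")
    config = config or AnalysisConfig()
    covered = 0
    for rng in _replicate_rngs(seed, n_reps):
        series = simulate_pairs(
            rng, n, truth_mean, truth_sd,
            slope=slope, intercept=intercept,
            sigma_ref=sigma, sigma_test=sigma,
        )
        lb, ub = pb_fit(series, config, linearity=False).slope_ci
        if lb <= slope <= ub:
            covered += 1
    frac = covered / n_reps
    return {
        "coverage_percent": 100.0 * frac,
        "mc_se_percent": 100.0 * float(np.sqrt(frac * (1 - frac) / n_reps)),
        "n_reps": n_reps,
        "n": n,
        "nominal_percent": 100.0 * (1 - config.alpha),
    }


def verdict_rates(
    base_config: SyntheticConfig,
    n_reps: int = 50,
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> dict[str, Counter]:
    """End-to-end verdict frequencies over replicated synthetic studies.

    Each replicate regenerates the study from ``base_config`` with a
    fresh derived seed and runs the full pipeline
    (generate -> average -> fit -> classify).  Returns per-parameter
    counters of verdict levels.
    """
    config = config or AnalysisConfig()
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    counts: dict[str, Counter] = {}
    for rep_seed in seeds:
        cfg = base_config.model_copy(deep=True)
        cfg.seed = int(rep_seed)
        for series in average_trials(generate(cfg)):
            res = MethodComparison.from_series(series, config).fit()
            counts.setdefault(series.parameter.name, Counter())[
                res.verdict.level.value
            ] += 1
    return counts
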