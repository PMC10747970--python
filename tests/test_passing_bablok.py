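"""Passing-Bablok regression against a brute-force oracle, plus cusum."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitagree.exceptions import CIUndefinedError, DegenerateFitError
from gaitagree.passing_bablok import cusum_linearity, pairwise_slopes, pb_fit
from gaitagree.types import AnalysisConfig

from conftest import make_series


def oracle_slopes(x, y):
    """Independent double-loop implementation of the pairwise slopes."""
    slopes = []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = math.copysign(math.inf, dy) if dx == 0 else dy / dx
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    k = sum(1 for s in slopes if s < -1.0)
    return slopes, k


def oracle_estimate(x, y):
    slopes, k = oracle_slopes(x, y)
    n_slopes = len(slopes)
    if n_slopes % 2 == 1:
        slope = slopes[(n_slopes + 1) // 2 + k - 1]
    else:
        slope = 0.5 * (slopes[n_slopes // 2 + k - 1] + slopes[n_slopes // 2 + k])
    intercept = statistics.median(yi - slope * xi for xi, yi in zip(x, y))
    return slope, intercept


class TestPairwiseSlopes:
    def test_identity_line(self):
        slopes, k = pairwise_slopes(make_series([1, 2, 3], [1, 2, 3]))
        np.testing.assert_array_equal(slopes, [1.0, 1.0, 1.0])
        assert k == 0

    def test_affine_line(self):
        # y = 2x + 1 over x = 0, 1, 2
        slopes, k = pairwise_slopes(
            make_series([0.5, 1, 2], [2.0, 3, 5.0], parameter="custom")
        )
        np.testing.assert_array_equal(slopes, [2.0, 2.0, 2.0])
        assert k == 0

    def test_duplicate_points_excluded(self):
        series = make_series([1, 1, 2, 3], [1, 1, 2, 3])
        slopes, _ = pairwise_slopes(series)
        # pair (0,1) is 0/0 and drops; remaining 5 pairs all slope 1
        assert slopes.size == 5
        np.testing.assert_array_equal(slopes, np.ones(5))

    def test_vertical_pair_is_signed_infinity(self):
        series = make_series([1, 1, 2, 3], [1, 2, 3, 4], parameter="custom")
        slopes, _ = pairwise_slopes(series)
        assert slopes[-1] == math.inf
        assert np.isfinite(slopes[:-1]).all()

    def test_minus_one_slopes_excluded_and_k_counts(self):
        series = make_series([1, 2, 3, 4], [8, 7, 5, 2], parameter="custom")
        expected, k_expected = oracle_slopes([1, 2, 3, 4], [8, 7, 5, 2])
        slopes, k = pairwise_slopes(series)
        np.testing.assert_allclose(slopes, expected)
        assert k == k_expected
        assert -1.0 not in slopes
        assert k == sum(s < -1 for s in expected)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [4, 6, 8, 11, 12])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, n)
        y = rng.uniform(0, 10, n)
        slopes, k = pairwise_slopes(make_series(x, y, parameter="custom"))
        expected, k_expected = oracle_slopes(list(x), list(y))
        np.testing.assert_allclose(slopes, expected, rtol=1e-14)
        assert k == k_expected


class TestPBFit:
    def test_noiseless_affine_line_exact(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        y = [2.10 * xi - 0.06 for xi in x]
        fit = pb_fit(make_series(x, y, parameter="stride_length"))
        assert fit.slope == pytest.approx(2.10, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.06, abs=1e-12)
        assert fit.slope_ci[0] == pytest.approx(2.10, abs=1e-9)
        assert fit.slope_ci[1] == pytest.approx(2.10, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_estimates_match_oracle_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 13)
        x = rng.uniform(1, 10, n)
        y = 1.5 * x + rng.normal(0, 1, n)
        fit = pb_fit(make_series(x, y, parameter="custom"))
        slope, intercept = oracle_estimate(list(x), list(y))
        assert fit.slope == pytest.approx(slope, rel=1e-14)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_swapped_axes_slope_is_reciprocal(self):
        # exact scale symmetry needs an odd slope count (n=11 -> N=55) and
        # all-positive pairwise slopes so the K offset is zero on both axes
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.linspace(1, 10, 11)
            y = 2.0 * x + rng.normal(0, 0.3, 11)
            forward = pb_fit(make_series(x, y, parameter="custom"),
                             linearity=False)
            backward = pb_fit(make_series(y, x, parameter="custom"),
                              linearity=False)
            assert forward.k_offset == backward.k_offset == 0
            assert backward.slope == pytest.approx(1 / forward.slope,
                                                   rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-5.0, 5.0),
    )
    def test_affine_equivariance_in_test_values(self, scale, offset):
        rng = np.random.default_rng(7)
        x = np.linspace(1, 10, 10)
        y = 2.0 * x + rng.normal(0, 0.1, 10)  # all pairwise slopes positive,
        # so rescaling by a positive factor cannot change the K offset
        base = pb_fit(make_series(x, y, parameter="custom"), linearity=False)
        mapped = pb_fit(
            make_series(x, offset + scale * y, parameter="custom"),
            linearity=False,
        )
        assert mapped.slope == pytest.approx(scale * base.slope, rel=1e-9)
        assert mapped.intercept == pytest.approx(
            offset + scale * base.intercept, rel=1e-9, abs=1e-9
        )

    def test_ci_brackets_estimate(self, rng):
        x = rng.uniform(1, 10, 15)
        y = 1.2 * x + rng.normal(0, 0.8, 15)
        fit = pb_fit(make_series(x, y, parameter="custom"))
        assert fit.slope_ci[0] <= fit.slope <= fit.slope_ci[1]
        assert fit.intercept_ci[0] <= fit.intercept <= fit.intercept_ci[1]
        assert fit.n_slopes <= 15 * 14 // 2

    def test_tiny_n_ci_undefined_carries_estimates(self):
        x = [1.0, 2.0, 3.0]
        y = [2.10 * xi - 0.06 for xi in x]
        with pytest.raises(CIUndefinedError) as exc:
            pb_fit(make_series(x, y, parameter="custom"))
        partial = exc.value.partial
        assert partial.slope == pytest.approx(2.10)
        assert partial.intercept == pytest.approx(-0.06)
        assert np.isnan(partial.slope_ci).all()

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateFitError):
            pb_fit(make_series([2.0, 2.0, 2.0], [1.0, 2.0, 3.0],
                               parameter="custom"))

    def test_alpha_widens_interval(self, rng):
        x = rng.uniform(1, 10, 20)
        y = x + rng.normal(0, 0.5, 20)
        series = make_series(x, y, parameter="custom")
        narrow = pb_fit(series, AnalysisConfig(alpha=0.10), linearity=False)
        wide = pb_fit(series, AnalysisConfig(alpha=0.01), linearity=False)
        assert wide.slope_ci[0] <= narrow.slope_ci[0]
        assert wide.slope_ci[1] >= narrow.slope_ci[1]


class TestCusumLinearity:
    def test_perfect_line_is_linear_with_zero_statistic(self):
        series = make_series([1, 2, 3, 4, 5], [2, 4, 6, 8, 10],
                             parameter="custom")
        fit = pb_fit(series)
        assert fit.linearity.statistic == 0.0
        assert fit.linearity.linear

    def test_quadratic_relation_fails_linearity(self):
        # residual signs of a parabola form three long runs; the cusum
        # excursion grows like sqrt(n) and crosses the critical value here
        x = np.arange(1.0, 41.0)
        series = make_series(x, x**2, parameter="custom")
        fit = pb_fit(series)
        assert fit.linearity.statistic > fit.linearity.critical_value
        assert not fit.linearity.linear

    def test_alternating_residuals_small_statistic(self):
        x = np.arange(1.0, 21.0)
        y = 2 * x + np.where(np.arange(20) % 2 == 0, 0.1, -0.1)
        series = make_series(x, y, parameter="custom")
        result = cusum_linearity(series, slope=2.0, intercept=0.0)
        # alternating signs keep every partial sum in {-1, 0, 1}
        assert result.statistic == pytest.approx(1 / np.sqrt(20))
        assert result.linear

    def test_statistic_matches_direct_computation(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 1.3 * x + rng.normal(0, 1, 15)
        slope, intercept = oracle_estimate(list(x), list(y))
        result = cusum_linearity(make_series(x, y, parameter="custom"),
                                 slope, intercept)
        order = np.lexsort((y, x))
        r = (y - intercept - slope * x)[order]
        scores = np.sign(r[np.abs(r) > 1e-12 * max(1, np.abs(y).max())])
        expected = np.max(np.abs(np.cumsum(scores))) / np.sqrt(len(scores))
        assert result.statistic == pytest.approx(expected, rel=1e-12)
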