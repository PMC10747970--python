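"""Model/results objects tying the analysis stages together.

``MethodComparison`` is the model: one parameter's per-subject paired
measurements from a reference and a test system.  Its :meth:`fit` runs
the full agreement analysis — normality-gated paired test,
Passing-Bablok regression with linearity check, Bland-Altman analysis,
and the systematic-error classification — and returns a
:class:`MethodComparisonResults` carrying every stage's estimates plus a
``summary()`` table and plot-data export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .agreement import AgreementVerdict, classify
from .bland_altman import BAResult, ba_fit
from .exceptions import CIUndefinedError
from .paired_tests import PairedTestResult, paired_compare
from .passing_bablok import PBResult, pb_fit
from .types import AnalysisConfig, PairedSeries, parameter_spec

__all__ = ["MethodComparison", "MethodComparisonResults"]


class MethodComparison:
    """Agreement model for one parameter measured by two systems.

    Parameters
    ----------
    ref, test : array-like
        Per-subject values (post trial averaging) from the reference and
        test systems, aligned by position.
    parameter : str
        Parameter name (used for units lookup and reporting).
    subject_ids : sequence of str, optional
        Defaults to S01, S02, ...
    config : AnalysisConfig, optional

    Examples
    --------
    >>> model = MethodComparison([1.0, 1.2, 1.4, 1.6, 1.8],
    ...                          [1.1, 1.3, 1.5, 1.7, 1.9],
    ...                          parameter="cycle_duration")
    >>> results = model.fit()
    >>> results.verdict.level.value
    'very_close_agreement'
    """

    def __init__(self, ref, test, parameter="parameter",
                 subject_ids=None, config: AnalysisConfig | None = None):
        ref = np.asarray(ref, dtype=float)
        if subject_ids is None:
            subject_ids = tuple(f"S{i + 1:02d}" for i in range(ref.size))
        self.series = PairedSeries(
            parameter=parameter_spec(parameter),
            subject_ids=tuple(subject_ids),
            ref_values=ref,
            test_values=np.asarray(test, dtype=float),
        )
        self.config = config or AnalysisConfig()

    @classmethod
    def from_series(cls, series: PairedSeries,
                    config: AnalysisConfig | None = None) -> "MethodComparison":
        model = cls.__new__(cls)
        model.series = series
        model.config = config or AnalysisConfig()
        return model

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        parameter: str,
        config: AnalysisConfig | None = None,
        subject_col: str = "subject",
        system_col: str = "system",
        value_col: str = "value",
        parameter_col: str = "parameter",
    ) -> "MethodComparison":
        """Build from a tidy long DataFrame (one row per measurement).

        Multiple trials per (subject, system) are averaged; subjects
        missing either system are dropped.
        """
        sub = df
        if parameter_col in df.columns:
            sub = df[df[parameter_col] == parameter]
        wide = (
            sub.groupby([subject_col, system_col])[value_col]
            .mean()
            .unstack(system_col)
            .dropna(subset=["reference", "test"])
            .sort_index()
        )
        return cls(
            ref=wide["reference"].to_numpy(),
            test=wide["test"].to_numpy(),
            parameter=parameter,
            subject_ids=tuple(str(s) for s in wide.index),
            config=config,
        )

    def fit(self, linearity: bool = True) -> "MethodComparisonResults":
        """Run every analysis stage and classify the agreement."""
        paired = paired_compare(self.series, self.config)
        try:
            pb = pb_fit(self.series, self.config, linearity=linearity)
        except CIUndefinedError as err:
            raise CIUndefinedError(
                f"{self.series.parameter.name}: {err}", partial=err.partial
            ) from err
        ba = ba_fit(self.series, self.config)
        verdict = classify(
            pb.slope_ci,
            pb.intercept_ci,
            ba.bias_ci,
            parameter=self.series.parameter.name,
            context={"paired_test_p": round(paired.p_value, 6)},
        )
        return MethodComparisonResults(
            series=self.series,
            config=self.config,
            paired_test=paired,
            pb=pb,
            ba=ba,
            verdict=verdict,
        )


@dataclass
class MethodComparisonResults:
    """Fitted agreement analysis for one parameter."""

    series: PairedSeries
    config: AnalysisConfig
    paired_test: PairedTestResult
    pb: PBResult
    ba: BAResult
    verdict: AgreementVerdict

    # -- summaries ---------------------------------------------------------

    @property
    def system_summary(self) -> dict:
        """Per-system mean and SD (n-1 denominator)."""
        ref, test = self.series.ref_values, self.series.test_values
        return {
            "ref_mean": float(np.mean(ref)),
            "ref_sd": float(np.std(ref, ddof=1)),
            "test_mean": float(np.mean(test)),
            "test_sd": float(np.std(test, ddof=1)),
        }

    def to_dict(self) -> dict:
        """JSON-ready nested dict of every stage's outputs."""
        norm = self.paired_test.normality
        lin = self.pb.linearity
        trend = self.ba.trend
        return {
            "parameter": self.series.parameter.name,
            "units": self.series.parameter.units,
            "n": self.series.n,
            "summary": self.system_summary,
            "paired_test": {
                "method": self.paired_test.method,
                "statistic": self.paired_test.statistic,
                "p_value": self.paired_test.p_value,
                "significant": self.paired_test.significant,
                "normality": None if norm is None else {
                    "statistic": norm.statistic,
                    "p_value": norm.p_value,
                    "n": norm.n,
                },
                "flags": list(self.paired_test.flags),
            },
            "passing_bablok": {
                "slope": self.pb.slope,
                "slope_ci": list(self.pb.slope_ci),
                "intercept": self.pb.intercept,
                "intercept_ci": list(self.pb.intercept_ci),
                "n_slopes": self.pb.n_slopes,
                "k_offset": self.pb.k_offset,
                "linearity": None if lin is None else {
                    "statistic": lin.statistic,
                    "critical_value": lin.critical_value,
                    "linear": lin.linear,
                },
            },
            "bland_altman": {
                "bias": self.ba.bias,
                "sd_diff": self.ba.sd_diff,
                "bias_ci": list(self.ba.bias_ci),
                "loa": list(self.ba.loa),
                "loa_multiplier": self.ba.loa_multiplier,
                "trend": None if trend is None else {
                    "slope_of_diff_on_mean": trend.slope_of_diff_on_mean,
                    "trend_p": trend.trend_p,
                    "proportional_trend": trend.proportional_trend,
                    "hetero_p": trend.hetero_p,
                    "heteroscedastic": trend.heteroscedastic,
                },
                "flags": list(self.ba.flags),
            },
            "verdict": {
                "level": self.verdict.level.value,
                "proportional_error": self.verdict.proportional_error,
                "constant_error": self.verdict.constant_error,
                "error_types": list(self.verdict.error_types),
                "rationale": list(self.verdict.rationale),
            },
        }

    def summary(self) -> str:
        """Human-readable summary table (one parameter)."""
        p = self.series.parameter
        s = self.system_summary
        lines = [
            f"Method comparison: {p.name} ({p.units})    n = {self.series.n}",
            "=" * 62,
            f"reference mean +/- SD   {s['ref_mean']:.4g} +/- {s['ref_sd']:.4g}",
            f"test mean +/- SD        {s['test_mean']:.4g} +/- {s['test_sd']:.4g}",
            (
                f"paired test             {self.paired_test.method}"
                f"  p = {self.paired_test.p_value:.4g}"
                + (
                    f"  (Shapiro-Wilk p = {self.paired_test.normality.p_value:.3g})"
                    if self.paired_test.normality
                    else "  (normality gate skipped)"
                )
            ),
            (
                f"PB slope                {self.pb.slope:.4g}"
                f"  CI ({self.pb.slope_ci[0]:.4g}, {self.pb.slope_ci[1]:.4g})"
            ),
            (
                f"PB intercept            {self.pb.intercept:.4g}"
                f"  CI ({self.pb.intercept_ci[0]:.4g}, "
                f"{self.pb.intercept_ci[1]:.4g})"
            ),
        ]
        if self.pb.linearity is not None:
            lin = self.pb.linearity
            lines.append(
                f"linearity (cusum)       H = {lin.statistic:.3g}"
                f"  {'linear' if lin.linear else 'NOT linear'}"
                f" (crit {lin.critical_value:.3g})"
            )
        lines += [
            (
                f"BA bias                 {self.ba.bias:.4g}"
                f"  CI ({self.ba.bias_ci[0]:.4g}, {self.ba.bias_ci[1]:.4g})"
            ),
            (
                f"limits of agreement     ({self.ba.loa[0]:.4g}, "
                f"{self.ba.loa[1]:.4g})  [bias +/- "
                f"{self.ba.loa_multiplier:g} x SD]"
            ),
            "-" * 62,
            (
                f"verdict: {self.verdict.level.value.replace('_', ' ')}"
                + (
                    f"  ({' + '.join(self.verdict.error_types)}"
                    " systematic error)"
                    if self.verdict.error_types
                    else "  (no systematic error)"
                )
            ),
        ]
        return "\n".join(lines)

    def plot_data(self) -> dict:
        """Data needed to redraw the two standard panels externally.

        Returns scatter points, the fitted Passing-Bablok line and the
        identity line for the regression panel, and the (mean, difference)
        points with bias and limits-of-agreement levels for the
        Bland-Altman panel.  Drawing is deliberately left to the caller.
        """
        x = self.series.ref_values
        order = np.argsort(x, kind="stable")
        xs = x[order]
        return {
            "passing_bablok": {
                "ref": xs.tolist(),
                "test": self.series.test_values[order].tolist(),
                "fit_line": {
                    "x": [float(xs[0]), float(xs[-1])],
                    "y": [
                        float(self.pb.intercept + self.pb.slope * xs[0]),
                        float(self.pb.intercept + self.pb.slope * xs[-1]),
                    ],
                },
                "identity_line": {
                    "x": [float(xs[0]), float(xs[-1])],
                    "y": [float(xs[0]), float(xs[-1])],
                },
            },
            "bland_altman": {
                "mean": self.series.pair_means().tolist(),
                "difference": self.series.differences().tolist(),
                "bias": self.ba.bias,
                "loa": list(self.ba.loa),
            },
        }
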