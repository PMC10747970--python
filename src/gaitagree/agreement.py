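"""Deterministic agreement classification from confidence intervals.

Three intervals decide the verdict for a parameter:

* the Passing-Bablok slope CI — excluding 1 flags a *proportional*
  systematic error;
* the Passing-Bablok intercept CI and the Bland-Altman bias CI — either
  excluding 0 flags a *constant* systematic error (the disjunction is
  needed because a wide intercept interval can hide an offset the bias
  interval still resolves, and vice versa);

and the level follows mechanically: no flags -> *agreement*; a constant
error only -> *very close agreement* (interchangeable after zeroing the
bias); any proportional error -> *no agreement*.  Interval endpoints
exactly at 1 or 0 count as containing.  Paired-test p-values never enter
the verdict; they are context only.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = ["AgreementLevel", "AgreementVerdict", "classify"]


class AgreementLevel(str, enum.Enum):
    AGREEMENT = "agreement"
    VERY_CLOSE = "very_close_agreement"
    NO_AGREEMENT = "no_agreement"


@dataclass(frozen=True)
class AgreementVerdict:
    """Classification of one parameter's agreement between systems."""

    parameter: str
    proportional_error: bool
    constant_error: bool
    level: AgreementLevel
    rationale: tuple[str, ...]

    @property
    def error_types(self) -> tuple[str, ...]:
        out = []
        if self.constant_error:
            out.append("constant")
        if self.proportional_error:
            out.append("proportional")
        return tuple(out)


def _check_interval(name: str, ci) -> tuple[float, float]:
    lo, hi = float(ci[0]), float(ci[1])
    if not (math.isfinite(lo) and math.isfinite(hi)):
        raise ValueError(f"{name} interval must be finite, got ({lo}, {hi})")
    if lo > hi:
        raise ValueError(f"{name} interval inverted: ({lo}, {hi})")
    return lo, hi


def _contains(ci: tuple[float, float], value: float) -> bool:
    return ci[0] <= value <= ci[1]


def classify(
    slope_ci,
    intercept_ci,
    bias_ci,
    parameter: str = "",
    context: dict | None = None,
) -> AgreementVerdict:
    """Classify agreement from the three decision intervals.

    Parameters
    ----------
    slope_ci, intercept_ci
        Passing-Bablok slope and intercept confidence intervals.
    bias_ci
        Bland-Altman bias confidence interval.
    context
        Optional extra facts (e.g. paired-test p-value) recorded in the
        rationale but never affecting the verdict.
    """
    slope_ci = _check_interval("slope", slope_ci)
    intercept_ci = _check_interval("intercept", intercept_ci)
    bias_ci = _check_interval("bias", bias_ci)

    rationale: list[str] = []

    proportional = not _contains(slope_ci, 1.0)
    rationale.append(
        f"slope CI ({slope_ci[0]:g}, {slope_ci[1]:g}) "
        + ("excludes 1 -> proportional systematic error"
           if proportional else "contains 1")
    )

    intercept_off = not _contains(intercept_ci, 0.0)
    rationale.append(
        f"intercept CI ({intercept_ci[0]:g}, {intercept_ci[1]:g}) "
        + ("excludes 0 -> constant systematic error"
           if intercept_off else "contains 0")
    )
    bias_off = not _contains(bias_ci, 0.0)
    rationale.append(
        f"bias CI ({bias_ci[0]:g}, {bias_ci[1]:g}) "
        + ("excludes 0 -> constant systematic error"
           if bias_off else "contains 0")
    )
    constant = intercept_off or bias_off

    if proportional:
        level = AgreementLevel.NO_AGREEMENT
    elif constant:
        level = AgreementLevel.VERY_CLOSE
    else:
        level = AgreementLevel.AGREEMENT

    for key, value in (context or {}).items():
        rationale.append(f"context: {key} = {value}")

    return AgreementVerdict(
        parameter=parameter,
        proportional_error=proportional,
        constant_error=constant,
        level=level,
        rationale=tuple(rationale),
    )
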