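"""Domain types for two-system gait agreement studies.

A study compares a *reference* system (optoelectronic motion capture,
the field's gold standard) against a *test* system (wearable inertial
sensors) on per-subject spatiotemporal gait parameters.  Raw input is a
tidy long table of single-trial measurements; after trial/side averaging
each parameter is held as a :class:`PairedSeries` of per-subject
(reference, test) value pairs, which is the unit every downstream stage
consumes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

__all__ = [
    "Side",
    "System",
    "ParameterSpec",
    "RawRecord",
    "PairedSeries",
    "AnalysisConfig",
    "DEFAULT_PARAMETERS",
    "PERCENT_PARAMETERS",
    "POSITIVE_PARAMETERS",
    "check_value",
]


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NA = "na"


class System(str, enum.Enum):
    REFERENCE = "reference"
    TEST = "test"


@dataclass(frozen=True)
class ParameterSpec:
    """A measured gait parameter and its physical units."""

    name: str
    units: str

    def __post_init__(self):
        if not self.name:
            raise ValueError("parameter name must be nonempty")
        if not self.units:
            raise ValueError("parameter units must be nonempty")


#: The six spatiotemporal parameters of a standard gait report.
DEFAULT_PARAMETERS: dict[str, ParameterSpec] = {
    "cadence": ParameterSpec("cadence", "steps/min"),
    "cycle_duration": ParameterSpec("cycle_duration", "s"),
    "speed": ParameterSpec("speed", "m/s"),
    "stance_phase": ParameterSpec("stance_phase", "% gait cycle time"),
    "swing_phase": ParameterSpec("swing_phase", "% gait cycle time"),
    "stride_length": ParameterSpec("stride_length", "m"),
}

#: Parameters expressed as a percentage of the gait cycle: open range (0, 100).
PERCENT_PARAMETERS = frozenset({"stance_phase", "swing_phase"})

#: Strictly positive physical quantities.
POSITIVE_PARAMETERS = frozenset(
    {"cadence", "cycle_duration", "speed", "stride_length"}
)


def parameter_spec(name: str) -> ParameterSpec:
    """Look up a known parameter, or build a unit-less spec for a custom one."""
    return DEFAULT_PARAMETERS.get(name, ParameterSpec(name, "a.u."))


def physical_range(name: str) -> tuple[float, float]:
    """Open physical range (lo, hi) of a parameter's values."""
    if name in PERCENT_PARAMETERS:
        return (0.0, 100.0)
    if name in POSITIVE_PARAMETERS:
        return (0.0, math.inf)
    return (-math.inf, math.inf)


def check_value(parameter: str, value: float) -> None:
    """Validate a single measurement against its parameter's physical range."""
    if not math.isfinite(value):
        raise ValueError(f"{parameter}: value must be finite, got {value!r}")
    lo, hi = physical_range(parameter)
    if not (lo < value < hi):
        raise ValueError(
            f"{parameter}: value {value} outside open range ({lo}, {hi})"
        )


@dataclass(frozen=True)
class RawRecord:
    """One single-trial measurement of one parameter by one system."""

    subject_id: str
    parameter: str
    trial: int
    side: Side
    system: System
    value: float

    def __post_init__(self):
        if self.trial < 1:
            raise ValueError(f"trial index must be >= 1, got {self.trial}")
        check_value(self.parameter, self.value)


@dataclass
class PairedSeries:
    """Per-subject (reference, test) value pairs for one parameter.

    Values are post trial/side averaging: one pair per subject, aligned by
    position with ``subject_ids``.  All downstream fits (paired test,
    Passing-Bablok, Bland-Altman) operate on this container.
    """

    parameter: ParameterSpec
    subject_ids: tuple[str, ...]
    ref_values: np.ndarray
    test_values: np.ndarray

    def __post_init__(self):
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.ref_values = np.asarray(self.ref_values, dtype=float)
        self.test_values = np.asarray(self.test_values, dtype=float)
        if not (
            len(self.subject_ids)
            == self.ref_values.size
            == self.test_values.size
        ):
            raise ValueError("subject_ids, ref_values, test_values must align")
        if not (
            np.all(np.isfinite(self.ref_values))
            and np.all(np.isfinite(self.test_values))
        ):
            raise ValueError("paired series must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def differences(self) -> np.ndarray:
        """Per-subject differences d_i = reference_i - test_i."""
        return self.ref_values - self.test_values

    def pair_means(self) -> np.ndarray:
        """Per-subject means (reference_i + test_i) / 2."""
        return (self.ref_values + self.test_values) / 2.0


class AnalysisConfig(BaseModel):
    """Study-wide analysis settings.

    ``difference_convention`` is fixed: differences are always computed as
    reference minus test, so a positive Bland-Altman bias means the test
    system under-reads relative to the reference.
    """

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    loa_multiplier: float = Field(default=1.96, gt=0.0)
    difference_convention: Literal["reference_minus_test"] = (
        "reference_minus_test"
    )
    seed: Optional[int] = None
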