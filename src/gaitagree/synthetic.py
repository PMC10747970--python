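"""Synthetic two-system gait datasets with known error structure.

The generator emulates a typical validation cohort: per subject a latent
"true" value of each spatiotemporal parameter is drawn from a Gaussian
population (truncated to the parameter's physical range), the reference
system observes that truth with additive Gaussian measurement noise, and
the test system observes a linearly distorted version

    test = q + m * truth + noise

where ``m`` is a proportional error factor and ``q`` a constant offset —
exactly the two systematic errors the downstream Passing-Bablok and
Bland-Altman stages are built to detect.  With ``m = 1`` and ``q = 0``
the two systems are interchangeable and the dataset is a null dataset.

Default population moments match a published cohort of fifteen people
with progressive supranuclear palsy walking at self-selected speed
(reference-system column): cadence 91.72 +/- 14.23 steps/min, cycle
duration 1.36 +/- 0.33 s, speed 0.61 +/- 0.20 m/s, stance 63.96 +/- 2.92
and swing 36.83 +/- 3.92 % of the gait cycle, stride length 0.41 +/-
0.10 m.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .exceptions import GenerationError
from .types import PairedSeries, RawRecord, Side, System, parameter_spec, physical_range

__all__ = [
    "ParameterErrorModel",
    "SyntheticConfig",
    "generate",
    "generate_null",
    "simulate_pairs",
]

#: Reference-system population moments of the default cohort.
DEFAULT_TRUTH_MOMENTS: dict[str, tuple[float, float]] = {
    "cadence": (91.72, 14.23),
    "cycle_duration": (1.36, 0.33),
    "speed": (0.61, 0.20),
    "stance_phase": (63.96, 2.92),
    "swing_phase": (36.83, 3.92),
    "stride_length": (0.41, 0.10),
}

#: Fraction of the truth mean used as default measurement-noise SD.
DEFAULT_NOISE_FRACTION = 0.02

_TRUNCATION_SD = 6.0
_MAX_RETRIES = 100
_EDGE = 1e-9


class ParameterErrorModel(BaseModel):
    """Generative model of one parameter: population truth + system errors."""

    truth_mean: float
    truth_sd: float = Field(ge=0.0)
    m: float = 1.0  # proportional error factor of the test system
    q: float = 0.0  # constant offset of the test system
    sigma_ref: Optional[float] = Field(default=None, ge=0.0)
    sigma_test: Optional[float] = Field(default=None, ge=0.0)

    def resolved_sigma(self) -> tuple[float, float]:
        default = DEFAULT_NOISE_FRACTION * abs(self.truth_mean)
        return (
            default if self.sigma_ref is None else self.sigma_ref,
            default if self.sigma_test is None else self.sigma_test,
        )


def _default_parameters() -> dict[str, ParameterErrorModel]:
    return {
        name: ParameterErrorModel(truth_mean=mean, truth_sd=sd)
        for name, (mean, sd) in DEFAULT_TRUTH_MOMENTS.items()
    }


class SyntheticConfig(BaseModel):
    """Full generative configuration for one synthetic study."""

    n_subjects: int = Field(default=15, ge=3)
    n_trials: int = Field(default=4, ge=1)
    parameters: dict[str, ParameterErrorModel] = Field(
        default_factory=_default_parameters
    )
    heteroscedastic: bool = False
    consistent_kinematics: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check_positive_means(self):
        for name, p in self.parameters.items():
            lo, _ = physical_range(name)
            if lo >= 0 and p.truth_mean <= 0:
                raise ValueError(
                    f"{name}: truth_mean must be positive, got {p.truth_mean}"
                )
        return self


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sample Normal(mean, sd^2) restricted to the open (lo, hi)."""
    lo = max(lo, mean - _TRUNCATION_SD * sd)
    hi = min(hi, mean + _TRUNCATION_SD * sd)
    if sd == 0:
        if not (lo <= mean <= hi):
            raise GenerationError(f"degenerate truth {mean} outside ({lo}, {hi})")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    bad = ~((out > lo) & (out < hi))
    for _ in range(_MAX_RETRIES):
        k = int(bad.sum())
        if k == 0:
            return out
        out[bad] = rng.normal(mean, sd, size=k)
        bad = ~((out > lo) & (out < hi))
    raise GenerationError(
        f"truncation failed after {_MAX_RETRIES} retries "
        f"(mean={mean}, sd={sd}, range=({lo}, {hi}))"
    )


def _draw_truths(rng, config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-subject latent truths, optionally with kinematic consistency.

    In consistent mode only cadence, stance and stride are free draws; the
    remaining parameters are derived on the truth layer before any noise:
    swing = 100 - stance, cycle = 120 / cadence (two steps per stride),
    speed = stride / cycle.
    """
    n = config.n_subjects
    truths: dict[str, np.ndarray] = {}
    derived = (
        {"swing_phase", "cycle_duration", "speed"}
        if config.consistent_kinematics
        else set()
    )
    for name in config.parameters:  # insertion order keeps draws reproducible
        if name in derived:
            continue
        p = config.parameters[name]
        lo, hi = physical_range(name)
        truths[name] = _truncated_normal(rng, p.truth_mean, p.truth_sd, lo, hi, n)
    if config.consistent_kinematics:
        if "swing_phase" in config.parameters and "stance_phase" in truths:
            truths["swing_phase"] = 100.0 - truths["stance_phase"]
        if "cycle_duration" in config.parameters and "cadence" in truths:
            truths["cycle_duration"] = 120.0 / truths["cadence"]
        if (
            "speed" in config.parameters
            and "stride_length" in truths
            and "cycle_duration" in truths
        ):
            truths["speed"] = truths["stride_length"] / truths["cycle_duration"]
    return truths


def _clip_physical(name: str, values: np.ndarray) -> np.ndarray:
    lo, hi = physical_range(name)
    lo = lo + _EDGE if math.isfinite(lo) else lo
    hi = hi - _EDGE if math.isfinite(hi) else hi
    return np.clip(values, lo, hi)


def generate(config: SyntheticConfig) -> list[RawRecord]:
    """Generate a tidy collection of single-trial records.

    Per subject ``s`` and parameter ``p``: truth ~ truncated
    Normal(truth_mean, truth_sd^2); per trial the reference system records
    ``truth + N(0, sigma_ref^2)`` and the test system
    ``q + m * truth + N(0, sigma_test^2)``.  With ``heteroscedastic`` the
    noise SD scales linearly with the subject's truth.  Observations are
    clipped into the parameter's physical range.  A fixed seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    truths = _draw_truths(rng, config)
    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    records: list[RawRecord] = []
    for name in config.parameters:
        p = config.parameters[name]
        truth = truths[name]
        sigma_ref, sigma_test = p.resolved_sigma()
        if config.heteroscedastic:
            scale = truth / p.truth_mean
        else:
            scale = np.ones_like(truth)
        for trial in range(1, config.n_trials + 1):
            ref = truth + rng.normal(0.0, 1.0, config.n_subjects) * sigma_ref * scale
            test = (
                p.q
                + p.m * truth
                + rng.normal(0.0, 1.0, config.n_subjects) * sigma_test * scale
            )
            ref = _clip_physical(name, ref)
            test = _clip_physical(name, test)
            for i, subject in enumerate(subjects):
                records.append(
                    RawRecord(subject, name, trial, Side.NA, System.REFERENCE,
                              float(ref[i]))
                )
                records.append(
                    RawRecord(subject, name, trial, Side.NA, System.TEST,
                              float(test[i]))
                )
    return records


def generate_null(config: SyntheticConfig) -> list[RawRecord]:
    """Generate under the null of interchangeable systems.

    Forces ``m = 1`` and ``q = 0`` for every parameter; both systems then
    observe the same truth with independent noise, so the expected
    difference is zero for every parameter.
    """
    null = config.model_copy(deep=True)
    for p in null.parameters.values():
        p.m = 1.0
        p.q = 0.0
    return generate(null)


def simulate_pairs(
    rng: np.random.Generator,
    n: int,
    truth_mean: float,
    truth_sd: float,
    slope: float = 1.0,
    intercept: float = 0.0,
    sigma_ref: float = 0.0,
    sigma_test: float = 0.0,
    parameter: str = "simulated",
) -> PairedSeries:
    """Directly simulate one already-averaged paired series.

    Lightweight path used by calibration simulations: truths are plain
    Gaussian draws (no truncation, no trial structure), reference and test
    add independent Gaussian noise around ``truth`` and
    ``intercept + slope * truth`` respectively.
    """
    truth = rng.normal(truth_mean, truth_sd, n)
    ref = truth + rng.normal(0.0, 1.0, n) * sigma_ref
    test = intercept + slope * truth + rng.normal(0.0, 1.0, n) * sigma_test
    return PairedSeries(
        parameter=parameter_spec(parameter),
        subject_ids=tuple(f"S{i + 1:02d}" for i in range(n)),
        ref_values=ref,
        test_values=test,
    )
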