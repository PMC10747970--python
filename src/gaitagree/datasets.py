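"""Published summary tables of a two-system gait validation cohort.

These are the printed per-parameter summary statistics of a study that
compared an optoelectronic motion-capture system (reference) against a
wearable inertial system (test) on six spatiotemporal gait parameters in
fifteen people with progressive supranuclear palsy walking at
self-selected speed.  The per-subject raw data of that cohort are not
public, so the tables serve two roles here: they parameterize the
synthetic generator's default population, and they feed the
classification-only pipeline (the interval bounds alone determine the
agreement verdicts, which the study also printed and which the rule
engine reproduces).

All numbers are stored exactly as printed (two decimals).
"""

from __future__ import annotations

import pandas as pd

from .agreement import AgreementLevel

__all__ = [
    "PARAMETER_ORDER",
    "system_summary",
    "pb_table",
    "ba_table",
    "interval_table",
    "reported_agreement",
]

PARAMETER_ORDER = [
    "cadence",
    "cycle_duration",
    "speed",
    "stance_phase",
    "swing_phase",
    "stride_length",
]

#: parameter -> (ref_mean, ref_sd, test_mean, test_sd, p_printed, test_type)
_SYSTEM_SUMMARY = {
    "cadence": (91.72, 14.23, 99.14, 14.28, "0.002", "wilcoxon"),
    "cycle_duration": (1.36, 0.33, 1.21, 0.30, "0.003", "wilcoxon"),
    "speed": (0.61, 0.20, 0.65, 0.19, "0.192", "wilcoxon"),
    "stance_phase": (63.96, 2.92, 62.12, 2.11, "0.037", "wilcoxon"),
    "swing_phase": (36.83, 3.92, 36.88, 2.11, "0.159", "wilcoxon"),
    "stride_length": (0.41, 0.10, 0.78, 0.20, "<0.001", "t_student"),
}

#: parameter -> (m, LB_m, UB_m, q, LB_q, UB_q)
_PB_TABLE = {
    "cadence": (1.09, 0.74, 1.81, -3.02, -67.89, 30.17),
    "cycle_duration": (1.03, 0.63, 1.74, -0.10, -1.04, 0.40),
    "speed": (1.02, 0.71, 1.45, 0.05, -0.17, 0.22),
    "stance_phase": (0.63, 0.46, 0.85, 23.09, 8.78, 33.34),
    "swing_phase": (0.58, 0.32, 0.74, 15.96, 10.13, 25.68),
    "stride_length": (2.10, 1.64, 2.69, -0.06, -0.28, 0.13),
}

#: parameter -> (bias, LB_b, UB_b, LB_LA, UB_LA); bias is reference - test
_BA_TABLE = {
    "cadence": (-7.43, -11.36, -3.50, -28.95, 14.10),
    "cycle_duration": (0.15, 0.05, 0.25, -0.40, 0.70),
    "speed": (-0.03, -0.08, 0.02, -0.31, 0.25),
    "stance_phase": (0.84, 0.11, 1.57, -3.17, 4.84),
    "swing_phase": (-0.05, -1.37, 1.27, -7.30, 7.20),
    "stride_length": (-0.37, -0.42, -0.32, -0.63, -0.11),
}

#: parameter -> (level, error types) as the study reported them
_REPORTED_AGREEMENT = {
    "cadence": (AgreementLevel.VERY_CLOSE, ("constant",)),
    "cycle_duration": (AgreementLevel.VERY_CLOSE, ("constant",)),
    "speed": (AgreementLevel.AGREEMENT, ()),
    "stance_phase": (AgreementLevel.NO_AGREEMENT, ("constant", "proportional")),
    "swing_phase": (AgreementLevel.NO_AGREEMENT, ("constant", "proportional")),
    "stride_length": (AgreementLevel.NO_AGREEMENT, ("constant", "proportional")),
}

#: Cohort size of the published study.
N_SUBJECTS = 15


def system_summary() -> pd.DataFrame:
    """Per-system means and SDs with the reported paired-test outcome."""
    return pd.DataFrame(
        [(p, *_SYSTEM_SUMMARY[p]) for p in PARAMETER_ORDER],
        columns=["parameter", "ref_mean", "ref_sd", "test_mean", "test_sd",
                 "p_printed", "test_type"],
    )


def pb_table() -> pd.DataFrame:
    """Reported Passing-Bablok slope/intercept estimates and 95% CIs."""
    return pd.DataFrame(
        [(p, *_PB_TABLE[p]) for p in PARAMETER_ORDER],
        columns=["parameter", "m", "LB_m", "UB_m", "q", "LB_q", "UB_q"],
    )


def ba_table() -> pd.DataFrame:
    """Reported Bland-Altman bias, bias CI and limits of agreement."""
    return pd.DataFrame(
        [(p, *_BA_TABLE[p]) for p in PARAMETER_ORDER],
        columns=["parameter", "bias", "LB_b", "UB_b", "LB_LA", "UB_LA"],
    )


def interval_table() -> pd.DataFrame:
    """The six decision intervals per parameter, classification-ready.

    Joins the Passing-Bablok CIs with the bias CI in the layout
    :func:`gaitagree.pipeline.classify_intervals` expects.
    """
    pb = pb_table()[["parameter", "LB_m", "UB_m", "LB_q", "UB_q"]]
    ba = ba_table()[["parameter", "LB_b", "UB_b"]]
    return pb.merge(ba, on="parameter")


def reported_agreement() -> pd.DataFrame:
    """The agreement verdicts as the study reported them."""
    return pd.DataFrame(
        [
            (p, level.value, "+".join(errors) or "/")
            for p, (level, errors) in (
                (q, _REPORTED_AGREEMENT[q]) for q in PARAMETER_ORDER
            )
        ],
        columns=["parameter", "level", "error_types"],
    )
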