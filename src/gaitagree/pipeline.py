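"""Study-level orchestration: read -> average -> fit -> classify.

``analyze_records`` runs the full agreement analysis for every parameter
in a record collection and collects the per-parameter results into a
:class:`StudyReport`.  Stages are isolated: a parameter that fails a
stage (too few pairs, degenerate fit, sample too small for rank CIs) is
recorded as a failure and the remaining parameters proceed.

A classification-only entry point (:func:`classify_intervals`) accepts
precomputed Passing-Bablok and bias intervals — e.g. the printed tables
of a published study whose raw data are unavailable — and runs just the
rule engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from typing import Iterable

import pandas as pd

from .agreement import AgreementVerdict, classify
from .exceptions import GaitAgreeError
from .io import average_trials, read_paired_csv
from .model import MethodComparison, MethodComparisonResults
from .types import AnalysisConfig, RawRecord

__all__ = ["StudyReport", "analyze_records", "analyze_csv", "classify_intervals"]

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("gaitagree")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class StudyReport:
    """All per-parameter results of one study run, plus provenance."""

    parameters: dict[str, MethodComparisonResults]
    failures: dict[str, str]
    config: AnalysisConfig
    version: str = field(default_factory=_package_version)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config.model_dump(),
            "parameters": {
                name: res.to_dict() for name, res in self.parameters.items()
            },
            "failures": dict(self.failures),
        }

    def summary(self) -> str:
        blocks = [res.summary() for res in self.parameters.values()]
        for name, msg in self.failures.items():
            blocks.append(f"{name}: FAILED - {msg}")
        return "\n\n".join(blocks)


def analyze_records(
    records: Iterable[RawRecord], config: AnalysisConfig | None = None
) -> StudyReport:
    """Run the full pipeline on a tidy record collection.

    Raises
    ------
    GaitAgreeError
        If no parameter could be analyzed at all.
    """
    config = config or AnalysisConfig()
    results: dict[str, MethodComparisonResults] = {}
    failures: dict[str, str] = {}
    records = list(records)
    by_parameter: dict[str, list[RawRecord]] = {}
    for record in records:
        by_parameter.setdefault(record.parameter, []).append(record)
    series_list = []
    for name in sorted(by_parameter):
        try:
            series_list.extend(average_trials(by_parameter[name]))
        except GaitAgreeError as err:
            logger.warning("%s: averaging failed: %s", name, err)
            failures[name] = str(err)
    for series in series_list:
        name = series.parameter.name
        logger.info("analyzing %s (n=%d)", name, series.n)
        try:
            results[name] = MethodComparison.from_series(series, config).fit()
            logger.info(
                "%s: verdict=%s", name, results[name].verdict.level.value
            )
        except GaitAgreeError as err:
            logger.warning("%s: stage failed: %s", name, err)
            failures[name] = str(err)
    if not results:
        raise GaitAgreeError(
            "no analyzable parameter "
            + (f"(failures: {failures})" if failures else "(empty input)")
        )
    return StudyReport(parameters=results, failures=failures, config=config)


def analyze_csv(path, config: AnalysisConfig | None = None,
                schema=None) -> StudyReport:
    """Read a tidy CSV and run :func:`analyze_records`."""
    return analyze_records(read_paired_csv(path, schema=schema), config)


INTERVAL_COLUMNS = ("LB_m", "UB_m", "LB_q", "UB_q", "LB_b", "UB_b")


def classify_intervals(table: pd.DataFrame) -> list[AgreementVerdict]:
    """Classification-only mode: verdicts from precomputed intervals.

    ``table`` needs a ``parameter`` column plus the six interval bounds
    ``LB_m, UB_m`` (slope), ``LB_q, UB_q`` (intercept), ``LB_b, UB_b``
    (bias).
    """
    missing = [c for c in ("parameter",) + INTERVAL_COLUMNS
               if c not in table.columns]
    if missing:
        raise GaitAgreeError(f"intervals table missing columns {missing}")
    verdicts = []
    for _, row in table.iterrows():
        verdicts.append(
            classify(
                slope_ci=(row["LB_m"], row["UB_m"]),
                intercept_ci=(row["LB_q"], row["UB_q"]),
                bias_ci=(row["LB_b"], row["UB_b"]),
                parameter=str(row["parameter"]),
            )
        )
    return verdicts
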