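"""Tidy-CSV reading, trial/side averaging, and report writing.

Canonical input is a long table with one row per single-trial measurement:

    subject,parameter,trial,side,system,value
    S01,cadence,1,na,reference,90.1

``trial`` and ``side`` are optional (defaulting to 1 and ``na``); column
names can be remapped through a schema dictionary, so wide exports from
acquisition software only need a reshaping step, not a custom reader.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._numeric import round_half_away
from .exceptions import DegenerateSeriesError, ParseError, SchemaError
from .types import PairedSeries, RawRecord, Side, System, parameter_spec

__all__ = [
    "read_paired_csv",
    "read_wide_csv",
    "average_trials",
    "records_to_dataframe",
    "write_records_csv",
    "write_report",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "parameter", "system", "value")
OPTIONAL_COLUMNS = ("trial", "side")


def _resolve_schema(columns: Sequence[str], schema: Mapping[str, str] | None):
    """Map canonical column names to actual file columns; validate presence."""
    schema = dict(schema or {})
    mapping = {}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        actual = schema.get(canonical, canonical)
        if actual in columns:
            mapping[canonical] = actual
        elif canonical in REQUIRED_COLUMNS:
            raise SchemaError(
                f"required column {canonical!r} (mapped to {actual!r}) "
                f"not found; file has columns {list(columns)}"
            )
    return mapping


def read_paired_csv(
    path, schema: Mapping[str, str] | None = None
) -> list[RawRecord]:
    """Read a tidy long CSV of single-trial measurements.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names
        (``subject, parameter, trial, side, system, value``) to the
        file's actual column names.

    Returns
    -------
    list of RawRecord, in file row order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = _resolve_schema(df.columns, schema)

    records: list[RawRecord] = []
    for pos, (_, row) in enumerate(df.iterrows()):
        file_row = pos + 2  # 1-based, header is row 1
        raw_value = row[mapping["value"]]
        try:
            value = float(raw_value)
        except (TypeError, ValueError):
            raise ParseError(
                f"row {file_row}: cannot parse value {raw_value!r} as a number",
                row=file_row,
            ) from None
        system_label = str(row[mapping["system"]]).strip().lower()
        try:
            system = System(system_label)
        except ValueError:
            raise ValueError(
                f"row {file_row}: unknown system label {system_label!r}; "
                f"expected 'reference' or 'test'"
            ) from None
        if "trial" in mapping:
            try:
                trial = int(row[mapping["trial"]])
            except (TypeError, ValueError):
                raise ParseError(
                    f"row {file_row}: cannot parse trial index "
                    f"{row[mapping['trial']]!r}",
                    row=file_row,
                ) from None
        else:
            trial = 1
        side = (
            Side(str(row[mapping["side"]]).strip().lower())
            if "side" in mapping
            else Side.NA
        )
        records.append(
            RawRecord(
                subject_id=str(row[mapping["subject"]]),
                parameter=str(row[mapping["parameter"]]),
                trial=trial,
                side=side,
                system=system,
                value=value,
            )
        )
    return records


def read_wide_csv(
    path,
    parameter: str,
    reference_col: str,
    test_col: str,
    subject_col: str = "subject",
) -> list[RawRecord]:
    """Read a wide per-subject CSV (one reference and one test column)."""
    df = pd.read_csv(path)
    for col in (subject_col, reference_col, test_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found")
    records = []
    for _, row in df.iterrows():
        for system, col in (
            (System.REFERENCE, reference_col),
            (System.TEST, test_col),
        ):
            records.append(
                RawRecord(
                    subject_id=str(row[subject_col]),
                    parameter=parameter,
                    trial=1,
                    side=Side.NA,
                    system=system,
                    value=float(row[col]),
                )
            )
    return records


def records_to_dataframe(records: Iterable[RawRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of a record collection."""
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "parameter": [r.parameter for r in records],
            "trial": [r.trial for r in records],
            "side": [r.side.value for r in records],
            "system": [r.system.value for r in records],
            "value": [r.value for r in records],
        }
    )


def write_records_csv(records: Iterable[RawRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def average_trials(
    records: Iterable[RawRecord],
    min_pairs: int = 3,
    errors: str = "raise",
) -> list[PairedSeries]:
    """Average trials and sides per (subject, parameter, system).

    Each subject contributes one value per system per parameter: the
    arithmetic mean over all of that subject's trials and sides.  Subjects
    measured by only one system for a parameter are dropped from that
    parameter's series with a warning (listwise deletion; no imputation).

    Returns one :class:`PairedSeries` per parameter, subjects sorted by id.

    Raises
    ------
    DegenerateSeriesError
        If a parameter ends up with fewer than ``min_pairs`` complete pairs
        (with ``errors="collect"`` the degenerate parameter is skipped with
        a warning instead, so the remaining parameters still average).
    """
    if errors not in ("raise", "collect"):
        raise ValueError(f"errors must be 'raise' or 'collect', got {errors!r}")
    df = records_to_dataframe(records)
    if df.empty:
        return []
    out: list[PairedSeries] = []
    for parameter, group in df.groupby("parameter", sort=True):
        per_subject = (
            group.groupby(["subject", "system"])["value"].mean().unstack("system")
        )
        for col in ("reference", "test"):
            if col not in per_subject.columns:
                per_subject[col] = np.nan
        complete = per_subject.dropna(subset=["reference", "test"])
        dropped = sorted(set(per_subject.index) - set(complete.index))
        if dropped:
            msg = (
                f"{parameter}: dropping subjects {dropped} "
                f"(measured by only one system)"
            )
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        if len(complete) < min_pairs:
            err = DegenerateSeriesError(
                f"{parameter}: only {len(complete)} complete pairs "
                f"(need >= {min_pairs})"
            )
            if errors == "raise":
                raise err
            logger.warning(str(err))
            warnings.warn(str(err), UserWarning, stacklevel=2)
            continue
        complete = complete.sort_index()
        out.append(
            PairedSeries(
                parameter=parameter_spec(str(parameter)),
                subject_ids=tuple(str(s) for s in complete.index),
                ref_values=complete["reference"].to_numpy(),
                test_values=complete["test"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

#: Column layouts of the four summary tables, mirroring a standard
#: agreement-study report.
TABLE_COLUMNS = {
    "system_summary": [
        "parameter", "ref_mean", "ref_sd", "test_mean", "test_sd",
        "p_value", "test_type",
    ],
    "passing_bablok": ["parameter", "m", "LB_m", "UB_m", "q", "LB_q", "UB_q"],
    "bland_altman": ["parameter", "bias", "LB_b", "UB_b", "LB_LA", "UB_LA"],
    "agreement": ["parameter", "level", "error_types"],
}


def _rounded(x, ndigits=2):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    return round_half_away(float(x), ndigits)


def write_report(report, json_path, tables_dir=None) -> None:
    """Serialize a study report to JSON plus four per-table CSVs.

    The JSON carries all values at full precision and round-trips
    losslessly; the CSV tables round to two decimals (half away from
    zero), matching how such studies print their tables.

    Raises
    ------
    ValueError
        If the report contains no analyzed parameter.
    """
    payload = report.to_dict()
    if not payload.get("parameters"):
        raise ValueError("empty report: no analyzed parameter to write")
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    if tables_dir is None:
        return
    tables_dir = Path(tables_dir)
    tables_dir.mkdir(parents=True, exist_ok=True)
    rows = {name: [] for name in TABLE_COLUMNS}
    for name, entry in payload["parameters"].items():
        s = entry["summary"]
        t = entry["paired_test"]
        rows["system_summary"].append(
            [name, _rounded(s["ref_mean"]), _rounded(s["ref_sd"]),
             _rounded(s["test_mean"]), _rounded(s["test_sd"]),
             _rounded(t["p_value"], 3), t["method"]]
        )
        pb = entry["passing_bablok"]
        rows["passing_bablok"].append(
            [name, _rounded(pb["slope"]), _rounded(pb["slope_ci"][0]),
             _rounded(pb["slope_ci"][1]), _rounded(pb["intercept"]),
             _rounded(pb["intercept_ci"][0]), _rounded(pb["intercept_ci"][1])]
        )
        ba = entry["bland_altman"]
        rows["bland_altman"].append(
            [name, _rounded(ba["bias"]), _rounded(ba["bias_ci"][0]),
             _rounded(ba["bias_ci"][1]), _rounded(ba["loa"][0]),
             _rounded(ba["loa"][1])]
        )
        v = entry["verdict"]
        rows["agreement"].append(
            [name, v["level"], "+".join(v["error_types"]) or "/"]
        )
    for name, columns in TABLE_COLUMNS.items():
        pd.DataFrame(rows[name], columns=columns).to_csv(
            tables_dir / f"{name}.csv", index=False
        )
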