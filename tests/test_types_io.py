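"""Domain types, CSV reading, trial/side averaging, report writing."""

import json

import numpy as np
import pytest

from gaitagree._numeric import round_half_away
from gaitagree.exceptions import (
    DegenerateSeriesError,
    ParseError,
    SchemaError,
)
from gaitagree.io import (
    average_trials,
    read_paired_csv,
    records_to_dataframe,
    write_records_csv,
    write_report,
)
from gaitagree.model import MethodComparison
from gaitagree.pipeline import StudyReport, analyze_records
from gaitagree.synthetic import SyntheticConfig, generate
from gaitagree.types import AnalysisConfig, RawRecord, Side, System


def _write_csv(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


TIDY_6_ROWS = """subject,parameter,trial,side,system,value
A,cadence,1,na,reference,90
A,cadence,2,na,reference,92
A,cadence,3,na,reference,94
A,cadence,1,na,test,95
A,cadence,2,na,test,96
A,cadence,3,na,test,97
"""


class TestReadPairedCsv:
    def test_row_count_and_order(self, tmp_path):
        records = read_paired_csv(_write_csv(tmp_path, TIDY_6_ROWS))
        assert len(records) == 6
        assert [r.value for r in records] == [90, 92, 94, 95, 96, 97]
        assert records[0].system is System.REFERENCE
        assert records[3].system is System.TEST

    def test_header_only_gives_empty_collection(self, tmp_path):
        path = _write_csv(tmp_path, "subject,parameter,system,value\n")
        assert read_paired_csv(path) == []

    def test_non_numeric_value_cites_row(self, tmp_path):
        text = (
            "subject,parameter,system,value\n"
            "A,cadence,reference,90\n"
            "A,cadence,reference,91\n"
            "A,cadence,test,abc\n"
        )
        with pytest.raises(ParseError, match="row 4") as exc:
            read_paired_csv(_write_csv(tmp_path, text))
        assert exc.value.row == 4

    def test_missing_column_named_in_error(self, tmp_path):
        path = _write_csv(tmp_path, "subject,parameter,value\nA,cadence,90\n")
        with pytest.raises(SchemaError, match="system"):
            read_paired_csv(path)

    def test_unknown_system_label(self, tmp_path):
        path = _write_csv(
            tmp_path, "subject,parameter,system,value\nA,cadence,gold,90\n"
        )
        with pytest.raises(ValueError, match="gold"):
            read_paired_csv(path)

    def test_schema_mapping_renames_columns(self, tmp_path):
        text = "pid,var,device,reading\nA,cadence,reference,90\n"
        records = read_paired_csv(
            _write_csv(tmp_path, text),
            schema={"subject": "pid", "parameter": "var",
                    "system": "device", "value": "reading"},
        )
        assert len(records) == 1
        assert records[0].subject_id == "A"
        assert records[0].trial == 1 and records[0].side is Side.NA

    def test_read_write_read_round_trip(self, tmp_path):
        config = SyntheticConfig(n_subjects=4, n_trials=2, seed=3)
        records = generate(config)
        path = tmp_path / "roundtrip.csv"
        write_records_csv(records, path)
        back = read_paired_csv(path)
        assert back == records


class TestAverageTrials:
    def _rec(self, subject, value, system=System.REFERENCE, trial=1,
             parameter="cadence", side=Side.NA):
        return RawRecord(subject, parameter, trial, side, system, value)

    def test_mean_of_three_trials(self):
        records = [self._rec("A", v, trial=t + 1)
                   for t, v in enumerate([90, 92, 94])]
        records += [self._rec(s, 90 + i, system=sys)
                    for i, s in enumerate("BCD") for sys in System]
        records += [self._rec("A", 93, system=System.TEST)]
        series = average_trials(records)[0]
        assert series.ref_values[list(series.subject_ids).index("A")] == 92.0

    def test_sides_averaged_with_trials(self):
        records = [
            self._rec("A", 90, side=Side.LEFT),
            self._rec("A", 94, side=Side.RIGHT),
        ]
        records += [self._rec("A", 91, system=System.TEST)]
        records += [self._rec(s, 90, system=sys) for s in "BC" for sys in System]
        series = average_trials(records)[0]
        assert series.ref_values[0] == 92.0

    def test_single_system_subject_dropped_with_warning(self):
        records = [self._rec(s, 90 + i, system=sys)
                   for i, s in enumerate("ABC") for sys in System]
        records.append(self._rec("D", 99))  # reference only
        with pytest.warns(UserWarning, match="D"):
            series = average_trials(records)[0]
        assert "D" not in series.subject_ids
        assert series.n == 3

    def test_fully_crossed_synthetic_study(self):
        records = generate(SyntheticConfig(n_subjects=15, seed=0))
        series = average_trials(records)
        assert len(series) == 6
        assert all(s.n == 15 for s in series)

    def test_too_few_pairs_raises(self):
        records = [self._rec(s, 90, system=sys) for s in "AB" for sys in System]
        with pytest.raises(DegenerateSeriesError, match="cadence"):
            average_trials(records)

    def test_idempotent_on_averaged_records(self):
        records = generate(SyntheticConfig(n_subjects=5, n_trials=3, seed=8))
        first = average_trials(records)
        averaged_records = [
            RawRecord(sid, s.parameter.name, 1, Side.NA, system, float(v))
            for s in first
            for system, values in (
                (System.REFERENCE, s.ref_values),
                (System.TEST, s.test_values),
            )
            for sid, v in zip(s.subject_ids, values)
        ]
        second = average_trials(averaged_records)
        for a, b in zip(first, second):
            assert a.parameter == b.parameter
            np.testing.assert_allclose(a.ref_values, b.ref_values)
            np.testing.assert_allclose(a.test_values, b.test_values)

    def test_permutation_invariant_over_row_order(self, rng):
        records = generate(SyntheticConfig(n_subjects=5, n_trials=4, seed=2))
        shuffled = list(records)
        rng.shuffle(shuffled)
        # means agree up to float summation order
        for a, b in zip(average_trials(records), average_trials(shuffled)):
            np.testing.assert_allclose(a.ref_values, b.ref_values, rtol=1e-12)
            np.testing.assert_allclose(a.test_values, b.test_values, rtol=1e-12)


class TestRawRecordValidation:
    def test_rejects_out_of_range_percentages(self):
        with pytest.raises(ValueError):
            RawRecord("A", "stance_phase", 1, Side.NA, System.TEST, 101.0)

    def test_rejects_nonpositive_physical_values(self):
        with pytest.raises(ValueError):
            RawRecord("A", "speed", 1, Side.NA, System.TEST, 0.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            RawRecord("A", "speed", 1, Side.NA, System.TEST, float("nan"))


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.005, 0.01), (-0.005, -0.01), (2.675, 2.68), (-7.425, -7.43),
         (0.835, 0.84), (1.844, 1.84)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestWriteReport:
    def _report(self):
        records = generate(SyntheticConfig(n_subjects=10, seed=5))
        return analyze_records(records)

    def test_json_and_four_tables_written(self, tmp_path):
        report = self._report()
        write_report(report, tmp_path / "report.json", tmp_path / "tables")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert len(payload["parameters"]) == 6
        names = {p.name for p in (tmp_path / "tables").iterdir()}
        assert names == {"system_summary.csv", "passing_bablok.csv",
                         "bland_altman.csv", "agreement.csv"}

    def test_json_round_trips_losslessly(self, tmp_path):
        report = self._report()
        write_report(report, tmp_path / "report.json")
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload == json.loads(json.dumps(report.to_dict()))
        slope = report.parameters["speed"].pb.slope
        assert payload["parameters"]["speed"]["passing_bablok"]["slope"] == slope

    def test_empty_report_refused(self, tmp_path):
        empty = StudyReport(parameters={}, failures={}, config=AnalysisConfig())
        with pytest.raises(ValueError, match="empty"):
            write_report(empty, tmp_path / "report.json")
        assert not (tmp_path / "report.json").exists()
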