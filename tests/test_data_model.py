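import datetime as dt

import pytest
from pydantic import ValidationError

from pftmine.data_model import (
    ClinicalNote,
    CohortConfig,
    Obstruction,
    ProcedureRecord,
    RecordError,
    SchemaError,
    Severity,
    Source,
    SpirometryClassification,
    read_classifications,
    read_notes,
    read_procedures,
    write_classifications,
)

NOTE_HEADER = "note_id,patient_id,facility_id,note_date,text\n"


class TestReadNotes:
    def test_csv_round_trip_preserves_order(self, tmp_path):
        path = tmp_path / "notes.csv"
        path.write_text(
            NOTE_HEADER
            + 'n3,p1,F1,2020-01-01,"FEV1: 2.1 L"\n'
            + "n1,p2,F1,2020-02-01,\n"
            + 'n2,p1,F2,2020-03-01,"multi\nline"\n'
        )
        notes = read_notes(path, "csv")
        assert [n.note_id for n in notes] == ["n3", "n1", "n2"]
        assert notes[0].note_date == dt.date(2020, 1, 1)
        assert notes[1].text == ""
        assert notes[2].text == "multi\nline"

    def test_jsonl_matches_csv(self, tmp_path):
        row = {
            "note_id": "n1", "patient_id": "p1", "facility_id": "F1",
            "note_date": "2020-01-01", "text": "FEV1 ok",
        }
        import json

        jp = tmp_path / "notes.jsonl"
        jp.write_text(json.dumps(row) + "\n")
        (tmp_path / "notes.csv").write_text(
            NOTE_HEADER + "n1,p1,F1,2020-01-01,FEV1 ok\n"
        )
        assert read_notes(jp, "jsonl") == read_notes(tmp_path / "notes.csv", "csv")

    def test_header_only_yields_empty(self, tmp_path):
        path = tmp_path / "notes.csv"
        path.write_text(NOTE_HEADER)
        assert read_notes(path) == []

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "notes.csv"
        path.write_text("note_id,patient_id,facility_id,text\nn1,p1,F1,x\n")
        with pytest.raises(SchemaError, match="note_date"):
            read_notes(path)

    def test_bad_date_is_record_error_listing_note_id(self, tmp_path):
        path = tmp_path / "notes.csv"
        path.write_text(
            NOTE_HEADER
            + "n1,p1,F1,2018-01-01,ok\n"
            + "n2,p1,F1,2018-13-01,bad month\n"
        )
        with pytest.raises(RecordError, match="n2") as exc:
            read_notes(path)
        assert exc.value.record_ids == ["n2"]


class TestProcedures:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "procs.csv"
        path.write_text(
            "study_id,patient_id,facility_id,procedure_date,cpt_code,has_structured_fev1\n"
            "s1,p1,F1,2020-01-01,94010,false\n"
            "s2,p1,F1,2020-01-02,94729,true\n"
        )
        recs = read_procedures(path)
        assert [r.study_id for r in recs] == ["s1", "s2"]
        assert recs[0].has_structured_fev1 is False
        assert recs[1].has_structured_fev1 is True

    def test_cpt_code_must_be_five_digits(self):
        with pytest.raises(ValidationError):
            ProcedureRecord(
                study_id="s", patient_id="p", facility_id="F",
                procedure_date=dt.date(2020, 1, 1), cpt_code="941",
            )


class TestCohortConfig:
    def test_defaults(self):
        cfg = CohortConfig()
        assert cfg.cpt_codes == frozenset(
            {"94010", "94375", "94060", "94726", "94727", "94729", "94150"}
        )
        assert cfg.window_days == (-1, 21)
        assert cfg.top_n_facilities == 36
        assert cfg.min_fev1_note_proportion == 0.80
        assert cfg.exclude_structured is True

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_days": (5, -5)},
            {"cpt_codes": frozenset()},
            {"top_n_facilities": 0},
            {"min_fev1_note_proportion": 1.2},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CohortConfig(**kwargs)


def _full_classification(study_id="s1"):
    return SpirometryClassification(
        study_id=study_id,
        obstruction=Obstruction.OBSTRUCTED,
        severity=Severity.SEVERE,
        ratio_value=0.55,
        fev1_pct_pred=42.0,
        obstruction_source=Source.QUANTITATIVE,
        severity_source=Source.QUANTITATIVE,
    )


class TestClassificationTable:
    def test_write_read_identity(self, tmp_path):
        records = [
            _full_classification("s1"),
            SpirometryClassification(
                study_id="s2",
                obstruction=Obstruction.NOT_OBSTRUCTED,
                severity=Severity.MISSING,
                ratio_value=0.81,
                obstruction_source=Source.QUANTITATIVE,
                severity_source=Source.NONE,
            ),
            SpirometryClassification(
                study_id="s3",
                obstruction=Obstruction.MISSING,
                severity=Severity.NORMAL,
                fev1_pct_pred=95.0,
                obstruction_source=Source.NONE,
                severity_source=Source.QUALITATIVE,
            ),
            SpirometryClassification(
                study_id="s4",
                obstruction=Obstruction.MISSING,
                severity=Severity.MISSING,
                obstruction_source=Source.NONE,
                severity_source=Source.NONE,
            ),
            SpirometryClassification(
                study_id="s5",
                obstruction=Obstruction.OBSTRUCTED,
                severity=Severity.MILD,
                obstruction_source=Source.QUALITATIVE,
                severity_source=Source.QUALITATIVE,
            ),
        ]
        path = tmp_path / "out.csv"
        write_classifications(records, path)
        assert read_classifications(path) == records

    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_classifications([], path)
        lines = path.read_text().splitlines()
        assert lines == [
            "study_id,obstruction,severity,ratio_value,fev1_pct_pred,"
            "obstruction_source,severity_source"
        ]

    def test_absent_values_are_empty_cells(self, tmp_path):
        rec = SpirometryClassification(
            study_id="s1",
            obstruction=Obstruction.MISSING,
            severity=Severity.MISSING,
            obstruction_source=Source.NONE,
            severity_source=Source.NONE,
        )
        path = tmp_path / "out.csv"
        write_classifications([rec], path)
        assert path.read_text().splitlines()[1] == "s1,missing,missing,,,none,none"

    @pytest.mark.parametrize(
        "kwargs",
        [
            # missing status but a non-none source
            dict(obstruction=Obstruction.MISSING, obstruction_source=Source.QUANTITATIVE,
                 ratio_value=0.5, severity=Severity.MISSING, severity_source=Source.NONE),
            # quantitative obstruction without a ratio
            dict(obstruction=Obstruction.OBSTRUCTED, obstruction_source=Source.QUANTITATIVE,
                 severity=Severity.MISSING, severity_source=Source.NONE),
            # severity present but source none
            dict(obstruction=Obstruction.MISSING, obstruction_source=Source.NONE,
                 severity=Severity.MILD, severity_source=Source.NONE),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SpirometryClassification(study_id="s", **kwargs)

    def test_ratio_range_enforced(self):
        with pytest.raises(ValidationError):
            SpirometryClassification(
                study_id="s",
                obstruction=Obstruction.OBSTRUCTED,
                severity=Severity.MISSING,
                ratio_value=2.0,
                obstruction_source=Source.QUANTITATIVE,
                severity_source=Source.NONE,
            )
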