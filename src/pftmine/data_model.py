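"""Domain types and file I/O for the spirometry extraction pipeline.

The pipeline consumes two record-oriented inputs — clinical notes and
procedure (PFT) records — and emits one :class:`SpirometryClassification`
per pulmonary function study.  Files are CSV (RFC-4180 quoting) or
JSON-lines; dates are ISO-8601 calendar dates with no time-of-day, because
the note-linkage window is defined in whole days.

Missing values in the classification output are written as empty cells so
downstream consumers never have to guess a sentinel string.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
import math
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "ClinicalNote",
    "ProcedureRecord",
    "CohortConfig",
    "Obstruction",
    "Severity",
    "Source",
    "SpirometryClassification",
    "SchemaError",
    "RecordError",
    "read_notes",
    "read_procedures",
    "write_classifications",
    "read_classifications",
]

_CPT_RE = re.compile(r"^\d{5}$")

NOTE_COLUMNS = ["note_id", "patient_id", "facility_id", "note_date", "text"]
PROCEDURE_COLUMNS = [
    "study_id",
    "patient_id",
    "facility_id",
    "procedure_date",
    "cpt_code",
    "has_structured_fev1",
]


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class RecordError(ValueError):
    """One or more individual records failed validation.

    Carries the offending record identifiers in :attr:`record_ids`.
    """

    def __init__(self, message: str, record_ids: Sequence[str]):
        super().__init__(message)
        self.record_ids = list(record_ids)


class ClinicalNote(BaseModel):
    """A single inpatient or outpatient clinical note."""

    model_config = ConfigDict(frozen=True)

    note_id: str
    patient_id: str
    facility_id: str
    note_date: dt.date
    text: str  # may be empty, never absent


class ProcedureRecord(BaseModel):
    """A pulmonary function test procedure identified by CPT code.

    ``has_structured_fev1`` marks studies whose FEV1 already exists as a
    structured result; such studies are excluded from text mining.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    patient_id: str
    facility_id: str
    procedure_date: dt.date
    cpt_code: str
    has_structured_fev1: bool = False

    @field_validator("cpt_code")
    @classmethod
    def _check_cpt(cls, v: str) -> str:
        if not _CPT_RE.match(v):
            raise ValueError(f"cpt_code {v!r} is not a 5-digit CPT code")
        return v


#: Spirometry CPT codes: routine spirometry, flow-volume loop, pre/post
#: bronchodilator spirometry, plethysmography / gas-dilution lung volumes,
#: airway resistance, and vital capacity.
DEFAULT_CPT_CODES = frozenset(
    {"94010", "94375", "94060", "94726", "94727", "94729", "94150"}
)


class CohortConfig(BaseModel):
    """Thresholds for cohort construction and facility screening."""

    model_config = ConfigDict(frozen=True)

    cpt_codes: frozenset[str] = DEFAULT_CPT_CODES
    window_days: tuple[int, int] = (-1, 21)
    top_n_facilities: int = 36
    min_fev1_note_proportion: float = 0.80
    #: comparator for the coverage threshold: ">=" (default) or ">"
    proportion_comparator: str = ">="
    exclude_structured: bool = True

    @field_validator("cpt_codes")
    @classmethod
    def _check_codes(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("cpt_codes must be non-empty")
        for code in v:
            if not _CPT_RE.match(code):
                raise ValueError(f"cpt code {code!r} is not a 5-digit code")
        return v

    @field_validator("window_days")
    @classmethod
    def _check_window(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo > hi:
            raise ValueError(f"window lower bound {lo} exceeds upper bound {hi}")
        return v

    @field_validator("top_n_facilities")
    @classmethod
    def _check_top_n(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("top_n_facilities must be positive")
        return v

    @field_validator("min_fev1_note_proportion")
    @classmethod
    def _check_prop(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("min_fev1_note_proportion must lie in [0, 1]")
        return v

    @field_validator("proportion_comparator")
    @classmethod
    def _check_cmp(cls, v: str) -> str:
        if v not in (">=", ">"):
            raise ValueError("proportion_comparator must be '>=' or '>'")
        return v


class Obstruction(str, enum.Enum):
    OBSTRUCTED = "obstructed"
    NOT_OBSTRUCTED = "not_obstructed"
    MISSING = "missing"


class Severity(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"
    VERY_SEVERE = "very_severe"
    MISSING = "missing"


class Source(str, enum.Enum):
    QUANTITATIVE = "quantitative"
    QUALITATIVE = "qualitative"
    NONE = "none"


class SpirometryClassification(BaseModel):
    """Final per-study interpretation with provenance.

    Invariants: a status/band is ``missing`` exactly when its source is
    ``none``, and a quantitative obstruction call always carries the ratio
    it was made from.
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    obstruction: Obstruction
    severity: Severity
    ratio_value: Optional[float] = None
    fev1_pct_pred: Optional[float] = None
    obstruction_source: Source
    severity_source: Source

    @field_validator("ratio_value")
    @classmethod
    def _check_ratio(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 <= v <= 1.5:
            raise ValueError(f"ratio_value {v} outside [0, 1.5]")
        return v

    @field_validator("fev1_pct_pred")
    @classmethod
    def _check_pct(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 < v < 300.0:
            raise ValueError(f"fev1_pct_pred {v} outside (0, 300)")
        return v

    @model_validator(mode="after")
    def _check_coherence(self) -> "SpirometryClassification":
        if (self.obstruction is Obstruction.MISSING) != (
            self.obstruction_source is Source.NONE
        ):
            raise ValueError(
                "obstruction is 'missing' iff obstruction_source is 'none'"
            )
        if (self.severity is Severity.MISSING) != (
            self.severity_source is Source.NONE
        ):
            raise ValueError("severity is 'missing' iff severity_source is 'none'")
        if self.obstruction_source is Source.QUANTITATIVE and self.ratio_value is None:
            raise ValueError(
                "quantitative obstruction call requires ratio_value to be present"
            )
        return self


CLASSIFICATION_COLUMNS = [
    "study_id",
    "obstruction",
    "severity",
    "ratio_value",
    "fev1_pct_pred",
    "obstruction_source",
    "severity_source",
]


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def _load_frame(path: Path, fmt: str, required: Sequence[str]) -> pd.DataFrame:
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    rows.append(json.loads(line))
        frame = pd.DataFrame(rows, columns=None if rows else required)
        frame = frame.astype(object)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'jsonl'")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return frame


def read_notes(path: str | Path, format: str = "csv") -> list[ClinicalNote]:
    """Read clinical notes from a CSV or JSON-lines file.

    Order is preserved.  Raises :class:`SchemaError` for missing columns and
    :class:`RecordError` (listing note ids) for unparseable dates.
    """
    frame = _load_frame(Path(path), format, NOTE_COLUMNS)
    notes: list[ClinicalNote] = []
    bad: list[str] = []
    for row in frame.itertuples(index=False):
        try:
            notes.append(
                ClinicalNote(
                    note_id=str(row.note_id),
                    patient_id=str(row.patient_id),
                    facility_id=str(row.facility_id),
                    note_date=_parse_date(row.note_date),
                    text="" if row.text is None else str(row.text),
                )
            )
        except (ValueError, TypeError):
            bad.append(str(row.note_id))
    if bad:
        raise RecordError(
            f"{path}: unparseable record(s) for note_id(s): {', '.join(bad)}", bad
        )
    return notes


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def read_procedures(path: str | Path, format: str = "csv") -> list[ProcedureRecord]:
    """Read PFT procedure records from a CSV or JSON-lines file."""
    frame = _load_frame(Path(path), format, PROCEDURE_COLUMNS)
    records: list[ProcedureRecord] = []
    bad: list[str] = []
    for row in frame.itertuples(index=False):
        try:
            records.append(
                ProcedureRecord(
                    study_id=str(row.study_id),
                    patient_id=str(row.patient_id),
                    facility_id=str(row.facility_id),
                    procedure_date=_parse_date(row.procedure_date),
                    cpt_code=str(row.cpt_code),
                    has_structured_fev1=_parse_bool(row.has_structured_fev1),
                )
            )
        except (ValueError, TypeError):
            bad.append(str(row.study_id))
    if bad:
        raise RecordError(
            f"{path}: unparseable record(s) for study_id(s): {', '.join(bad)}", bad
        )
    return records


def _fmt_number(value: Optional[float]) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return ""
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def write_classifications(
    records: Iterable[SpirometryClassification], path: str | Path
) -> None:
    """Write classification records as CSV with a stable column order.

    Absent numeric values become empty cells.  Records are re-validated so a
    table that violates the source/value invariants is never written.
    """
    rows = []
    for rec in records:
        # re-validate defensively: callers may have constructed via model_construct
        rec = SpirometryClassification.model_validate(rec.model_dump())
        rows.append(
            {
                "study_id": rec.study_id,
                "obstruction": rec.obstruction.value,
                "severity": rec.severity.value,
                "ratio_value": _fmt_number(rec.ratio_value),
                "fev1_pct_pred": _fmt_number(rec.fev1_pct_pred),
                "obstruction_source": rec.obstruction_source.value,
                "severity_source": rec.severity_source.value,
            }
        )
    frame = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    frame.to_csv(path, index=False)


def read_classifications(path: str | Path) -> list[SpirometryClassification]:
    """Read a classification table written by :func:`write_classifications`."""
    frame = _load_frame(Path(path), "csv", CLASSIFICATION_COLUMNS)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SpirometryClassification(
                study_id=str(row.study_id),
                obstruction=Obstruction(row.obstruction),
                severity=Severity(row.severity),
                ratio_value=float(row.ratio_value) if row.ratio_value != "" else None,
                fev1_pct_pred=(
                    float(row.fev1_pct_pred) if row.fev1_pct_pred != "" else None
                ),
                obstruction_source=Source(row.obstruction_source),
                severity_source=Source(row.severity_source),
            )
        )
    return out
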