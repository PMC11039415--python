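import datetime as dt

import pytest

from pftmine.data_model import (
    Obstruction,
    Severity,
    Source,
    SpirometryClassification,
)
from pftmine.template_registry import FacilityTemplate

# Published cross-tabulation of FEV1 impairment band x ratio status:
# rows normal..very_severe,missing; columns (>=0.7, <0.7, missing).
TABLE1_CELLS = {
    "normal": (3693, 826, 16),
    "mild": (974, 2418, 5),
    "moderate": (758, 2897, 8),
    "moderately_severe": (427, 2837, 6),
    "severe": (288, 5241, 18),
    "very_severe": (61, 3247, 9),
    "missing": (1044, 149, 0),
}

#: a representative percent-predicted value inside each band
BAND_REPRESENTATIVE_PCT = {
    "normal": 90.0,
    "mild": 75.0,
    "moderate": 65.0,
    "moderately_severe": 55.0,
    "severe": 40.0,
    "very_severe": 25.0,
}


def classification_for_cell(
    severity: str, ratio_col: int, study_id: str
) -> SpirometryClassification:
    """A classification record that falls in the given cross-tab cell."""
    if ratio_col == 0:  # ratio >= 0.7
        obstruction, ratio, obs_src = Obstruction.NOT_OBSTRUCTED, 0.75, Source.QUANTITATIVE
    elif ratio_col == 1:  # ratio < 0.7
        obstruction, ratio, obs_src = Obstruction.OBSTRUCTED, 0.55, Source.QUANTITATIVE
    else:
        obstruction, ratio, obs_src = Obstruction.MISSING, None, Source.NONE
    if severity == "missing":
        sev, pct, sev_src = Severity.MISSING, None, Source.NONE
    else:
        sev = Severity(severity)
        pct = BAND_REPRESENTATIVE_PCT[severity]
        sev_src = Source.QUANTITATIVE
    return SpirometryClassification(
        study_id=study_id,
        obstruction=obstruction,
        severity=sev,
        ratio_value=ratio,
        fev1_pct_pred=pct,
        obstruction_source=obs_src,
        severity_source=sev_src,
    )


@pytest.fixture(scope="session")
def table1_records() -> list[SpirometryClassification]:
    """The published table's 21 cells replayed as individual records."""
    records = []
    i = 0
    for severity, counts in TABLE1_CELLS.items():
        for col, count in enumerate(counts):
            for _ in range(count):
                i += 1
                records.append(classification_for_cell(severity, col, f"T{i:06d}"))
    return records


@pytest.fixture
def simple_template() -> FacilityTemplate:
    """A compact test dialect covering all four slots."""
    return FacilityTemplate(
        facility_id="FTEST",
        anchor_pattern=r"SPIROMETRY\s+RESULTS",
        before_chars=150,
        after_chars=1000,
        dialect_patterns={
            "fev1_liters": r"FEV[\s-]?1\s+(\d+(?:[.,]\d+)*)\s*L\b",
            "fev1_pct_pred": r"\(\s*(\d+(?:[.,]\d+)*)\s*%?\s*predicted\s*\)",
            "ratio": r"FEV[\s-]?1\s*[/:]\s*FVC:?\s*(\d+(?:[.,]\d+)*)\s*%?",
        },
    )


def make_note(note_id, patient_id, facility_id, date, text=""):
    from pftmine.data_model import ClinicalNote

    return ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        facility_id=facility_id,
        note_date=date if isinstance(date, dt.date) else dt.date.fromisoformat(date),
        text=text,
    )


def make_procedure(study_id, patient_id, facility_id, date, cpt="94010",
                   structured=False):
    from pftmine.data_model import ProcedureRecord

    return ProcedureRecord(
        study_id=study_id,
        patient_id=patient_id,
        facility_id=facility_id,
        procedure_date=date if isinstance(date, dt.date) else dt.date.fromisoformat(date),
        cpt_code=cpt,
        has_structured_fev1=structured,
    )
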