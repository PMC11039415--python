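"""Cohort construction: CPT filtering, note linkage, facility screening.

Reproduces the study funnel: select pulmonary function tests by CPT code,
drop studies whose FEV1 already exists as a structured result, link each
study to candidate notes dated within a fixed day window around the
procedure, and screen facilities by volume and FEV1-note coverage.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import pandas as pd

from .data_model import ClinicalNote, CohortConfig, ProcedureRecord

__all__ = [
    "filter_procedures",
    "link_notes",
    "screen_facilities",
    "DEFAULT_FEV1_PATTERN",
]

logger = logging.getLogger(__name__)

#: Tolerant token pattern for "FEV1" (also matches "FEV-1", "FEV 1").
DEFAULT_FEV1_PATTERN = r"FEV[\s-]?1"


def filter_procedures(
    procedures: Sequence[ProcedureRecord], config: CohortConfig
) -> list[ProcedureRecord]:
    """Keep procedures whose CPT code is in scope.

    When ``config.exclude_structured`` is set, studies already carrying a
    structured FEV1 result are dropped — their values need no text mining.
    Input order is preserved; the operation is idempotent.
    """
    kept = []
    for rec in procedures:
        if rec.cpt_code not in config.cpt_codes:
            continue
        if config.exclude_structured and rec.has_structured_fev1:
            continue
        kept.append(rec)
    return kept


def link_notes(
    procedures: Sequence[ProcedureRecord],
    notes: Sequence[ClinicalNote],
    config: CohortConfig,
) -> list[tuple[str, str]]:
    """Pair each study with same-patient notes inside the day window.

    A pair ``(study_id, note_id)`` is emitted iff the patient matches and
    ``note_date - procedure_date`` lies in ``config.window_days``, both
    endpoints inclusive.  Output is sorted by (study_id, note_date, note_id)
    so shuffling either input cannot change the result.
    """
    lo, hi = config.window_days
    by_patient: dict[str, list[ClinicalNote]] = {}
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)

    pairs: list[tuple[str, object, str]] = []
    for proc in procedures:
        for note in by_patient.get(proc.patient_id, ()):
            offset = (note.note_date - proc.procedure_date).days
            if lo <= offset <= hi:
                pairs.append((proc.study_id, note.note_date, note.note_id))
    pairs.sort()
    return [(s, n) for s, _, n in pairs]


def screen_facilities(
    procedures: Sequence[ProcedureRecord],
    notes: Sequence[ClinicalNote],
    config: CohortConfig,
    fev1_token: str = DEFAULT_FEV1_PATTERN,
) -> pd.DataFrame:
    """Per-facility screen: PFT volume and FEV1-note coverage.

    Restricts to the ``top_n_facilities`` facilities by PFT count (ties
    broken by facility id).  A study counts as "FEV1-containing" if any
    linked note's text matches ``fev1_token`` case-insensitively.  A
    facility is eligible when its coverage proportion clears
    ``min_fev1_note_proportion`` under the configured comparator.

    Returns a DataFrame indexed by facility_id with columns
    ``pft_count``, ``fev1_note_count``, ``proportion``, ``eligible``.
    """
    token_re = re.compile(fev1_token, re.IGNORECASE)
    pairs = link_notes(procedures, notes, config)
    note_text = {n.note_id: n.text for n in notes}

    fev1_studies: set[str] = set()
    for study_id, note_id in pairs:
        if study_id in fev1_studies:
            continue
        if token_re.search(note_text[note_id]):
            fev1_studies.add(study_id)

    counts: dict[str, list[int]] = {}
    for proc in procedures:
        row = counts.setdefault(proc.facility_id, [0, 0])
        row[0] += 1
        if proc.study_id in fev1_studies:
            row[1] += 1

    if len(counts) < config.top_n_facilities:
        logger.warning(
            "only %d facilities present; top_n_facilities=%d — using all",
            len(counts),
            config.top_n_facilities,
        )

    # rank by volume descending, facility_id ascending for ties
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1][0], kv[0]))
    ranked = ranked[: config.top_n_facilities]

    rows = []
    for facility_id, (pft_count, fev1_count) in ranked:
        proportion = fev1_count / pft_count if pft_count else 0.0
        if config.proportion_comparator == ">":
            eligible = proportion > config.min_fev1_note_proportion
        else:
            eligible = proportion >= config.min_fev1_note_proportion
        rows.append(
            {
                "facility_id": facility_id,
                "pft_count": pft_count,
                "fev1_note_count": fev1_count,
                "proportion": proportion,
                "eligible": eligible,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["facility_id", "pft_count", "fev1_note_count", "proportion", "eligible"],
    )
    return frame.set_index("facility_id")
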