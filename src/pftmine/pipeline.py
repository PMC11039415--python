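"""End-to-end orchestration: procedures + notes + registry -> classifications.

One classification is produced per in-scope study.  A study whose linked
notes contain no anchor match (or whose facility has no registered
template) is classified as fully missing rather than dropped, so funnel
counts remain auditable downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classifier import ClassificationCriteria, DEFAULT_CRITERIA, resolve
from .cohort_linker import filter_procedures, link_notes
from .data_model import (
    ClinicalNote,
    CohortConfig,
    Obstruction,
    ProcedureRecord,
    Severity,
    Source,
    SpirometryClassification,
)
from .snippet_extractor import Snippet, extract_snippet, find_anchor, normalize_text
from .template_registry import FacilityTemplate, template_for
from .value_extractor import LexiconEntry, SpirometryExtraction, extract_all

__all__ = ["PipelineResult", "run_pipeline", "snippets_for_studies"]

logger = logging.getLogger(__name__)


def _missing_classification(study_id: str) -> SpirometryClassification:
    return SpirometryClassification(
        study_id=study_id,
        obstruction=Obstruction.MISSING,
        severity=Severity.MISSING,
        obstruction_source=Source.NONE,
        severity_source=Source.NONE,
    )


@dataclass
class PipelineResult:
    classifications: list[SpirometryClassification]
    snippets: list[Snippet]
    extractions: list[SpirometryExtraction]
    n_studies: int = 0
    n_linked: int = 0
    n_snippets: int = 0
    n_no_template: int = 0
    funnel: dict = field(default_factory=dict)


def snippets_for_studies(
    procedures: Sequence[ProcedureRecord],
    notes: Sequence[ClinicalNote],
    registry: dict[str, FacilityTemplate],
    config: CohortConfig,
) -> tuple[list[Snippet], dict]:
    """Cut at most one snippet per study.

    Linked notes are visited in (note_date, note_id) order; the first note
    whose facility template's anchor matches supplies the snippet.
    Facilities without a template are skipped and counted, never guessed.
    """
    pairs = link_notes(procedures, notes, config)
    note_by_id = {n.note_id: n for n in notes}
    linked: dict[str, list[str]] = {}
    for study_id, note_id in pairs:
        linked.setdefault(study_id, []).append(note_id)

    snippets: list[Snippet] = []
    n_no_template = 0
    for proc in procedures:
        template = template_for(proc.facility_id, registry)
        if template is None:
            if proc.study_id in linked:
                n_no_template += 1
            continue
        for note_id in linked.get(proc.study_id, ()):
            note = note_by_id[note_id]
            text = normalize_text(note.text)
            span = find_anchor(text, template)
            if span is None:
                continue
            snippets.append(
                extract_snippet(
                    text, span, template, study_id=proc.study_id, note_id=note_id
                )
            )
            break  # one snippet per study
    stats = {"n_pairs": len(pairs), "n_linked_studies": len(linked),
             "n_no_template": n_no_template}
    return snippets, stats


def run_pipeline(
    procedures: Sequence[ProcedureRecord],
    notes: Sequence[ClinicalNote],
    registry: dict[str, FacilityTemplate],
    config: Optional[CohortConfig] = None,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    lexicon: Optional[Sequence[LexiconEntry]] = None,
) -> PipelineResult:
    """Filter, link, snip, extract and classify; one record per study."""
    config = config or CohortConfig()
    in_scope = filter_procedures(procedures, config)
    snippets, stats = snippets_for_studies(in_scope, notes, registry, config)

    extraction_by_id: dict[str, SpirometryExtraction] = {}
    for snip in snippets:
        template = registry[snip.facility_id]
        extraction_by_id[snip.study_id] = extract_all(
            snip.text,
            template,
            study_id=snip.study_id,
            lexicon=lexicon,
            anchor_offset=snip.anchor_offset,
        )

    classifications: list[SpirometryClassification] = []
    extractions: list[SpirometryExtraction] = []
    for proc in in_scope:
        extraction = extraction_by_id.get(proc.study_id)
        if extraction is None:
            classifications.append(_missing_classification(proc.study_id))
        else:
            extractions.append(extraction)
            classifications.append(resolve(extraction, criteria))

    funnel = {
        "n_procedures_input": len(procedures),
        "n_studies_in_scope": len(in_scope),
        "n_note_links": stats["n_pairs"],
        "n_studies_with_linked_note": stats["n_linked_studies"],
        "n_snippets": len(snippets),
        "n_studies_no_template": stats["n_no_template"],
        "n_classified_quantitative": sum(
            1 for c in classifications if c.obstruction_source is Source.QUANTITATIVE
        ),
    }
    return PipelineResult(
        classifications=classifications,
        snippets=snippets,
        extractions=extractions,
        n_studies=len(in_scope),
        n_linked=stats["n_linked_studies"],
        n_snippets=len(snippets),
        n_no_template=stats["n_no_template"],
        funnel=funnel,
    )
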