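"""Obstruction and severity classification.

Obstruction follows the fixed-ratio criterion: FEV1:FVC < 0.70 (strict).
FEV1 impairment follows the 2005 ATS/ERS severity bands on percent
predicted: normal >= 80, mild 70-79, moderate 60-69, moderately severe
50-59, severe 35-49, very severe < 35.  The printed integer ranges are
realised as half-open intervals on the real line ([70, 80) etc.) so
non-integer percents classify deterministically; at integer percents the
printed ranges are recovered exactly.

Quantitative values always win over qualitative descriptors; descriptors
are the fallback when a number was not extracted.  A conflict between the
two routes is logged as a discordance event for audit, never resolved in
the descriptor's favour.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .data_model import Obstruction, Severity, Source, SpirometryClassification
from .value_extractor import QualFev1, QualObstruction, SpirometryExtraction

__all__ = [
    "ClassificationCriteria",
    "DEFAULT_CRITERIA",
    "classify_obstruction",
    "grade_severity",
    "resolve",
]

logger = logging.getLogger(__name__)

#: severity bands as (band, lower edge); a percent x falls in the first
#: band whose lower edge satisfies x >= edge, scanning top-down
_DEFAULT_BAND_EDGES: tuple[tuple[Severity, float], ...] = (
    (Severity.NORMAL, 80.0),
    (Severity.MILD, 70.0),
    (Severity.MODERATE, 60.0),
    (Severity.MODERATELY_SEVERE, 50.0),
    (Severity.SEVERE, 35.0),
    (Severity.VERY_SEVERE, 0.0),
)

#: qualitative severity descriptors map to the same-named band
_QUAL_FEV1_TO_SEVERITY = {
    QualFev1.NORMAL: Severity.NORMAL,
    QualFev1.MILD: Severity.MILD,
    QualFev1.MODERATE: Severity.MODERATE,
    QualFev1.MODERATELY_SEVERE: Severity.MODERATELY_SEVERE,
    QualFev1.SEVERE: Severity.SEVERE,
    QualFev1.VERY_SEVERE: Severity.VERY_SEVERE,
}

#: severity-graded obstruction descriptors, usable as a severity fallback
_QUAL_OBS_TO_SEVERITY = {
    QualObstruction.MILD: Severity.MILD,
    QualObstruction.MODERATE: Severity.MODERATE,
    QualObstruction.MODERATELY_SEVERE: Severity.MODERATELY_SEVERE,
    QualObstruction.SEVERE: Severity.SEVERE,
    QualObstruction.VERY_SEVERE: Severity.VERY_SEVERE,
}


class ClassificationCriteria(BaseModel):
    """Thresholds for obstruction and severity grading.

    ``obstruction_threshold`` is applied as a strict less-than.
    ``severity_edges`` lists (band, lower bound) pairs with strictly
    decreasing bounds ending at 0, forming a disjoint half-open partition
    of the positive percent axis.
    """

    model_config = ConfigDict(frozen=True)

    obstruction_threshold: float = 0.70
    severity_edges: tuple[tuple[Severity, float], ...] = _DEFAULT_BAND_EDGES

    @field_validator("severity_edges")
    @classmethod
    def _check_edges(cls, v):
        edges = [e for _, e in v]
        if list(edges) != sorted(edges, reverse=True) or len(set(edges)) != len(edges):
            raise ValueError("severity band edges must be strictly decreasing")
        if edges[-1] != 0.0:
            raise ValueError("last band must reach down to 0")
        bands = [b for b, _ in v]
        if Severity.MISSING in bands:
            raise ValueError("'missing' is not a gradable band")
        return v


DEFAULT_CRITERIA = ClassificationCriteria()


def classify_obstruction(
    ratio_fraction: Optional[float],
    qualitative_obstruction: QualObstruction = QualObstruction.NONE_FOUND,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
    *,
    study_id: str = "",
) -> tuple[Obstruction, Source]:
    """Obstruction status with provenance.

    A present ratio decides alone (obstructed iff ratio < threshold); the
    descriptor is consulted only when the ratio is absent.  Any graded or
    unspecified obstruction descriptor means obstructed; a negated one
    means not obstructed.
    """
    if ratio_fraction is not None and not math.isnan(ratio_fraction):
        status = (
            Obstruction.OBSTRUCTED
            if ratio_fraction < criteria.obstruction_threshold
            else Obstruction.NOT_OBSTRUCTED
        )
        if qualitative_obstruction is not QualObstruction.NONE_FOUND:
            qual_status = (
                Obstruction.NOT_OBSTRUCTED
                if qualitative_obstruction is QualObstruction.NO_OBSTRUCTION
                else Obstruction.OBSTRUCTED
            )
            if qual_status is not status:
                logger.info(
                    "study %s: quantitative/qualitative obstruction discordance "
                    "(ratio %.3f vs descriptor %s); quantitative wins",
                    study_id,
                    ratio_fraction,
                    qualitative_obstruction.value,
                )
        return status, Source.QUANTITATIVE
    if qualitative_obstruction is QualObstruction.NO_OBSTRUCTION:
        return Obstruction.NOT_OBSTRUCTED, Source.QUALITATIVE
    if qualitative_obstruction is not QualObstruction.NONE_FOUND:
        return Obstruction.OBSTRUCTED, Source.QUALITATIVE
    return Obstruction.MISSING, Source.NONE


def grade_severity(
    fev1_pct_pred: Optional[float],
    qualitative_fev1: QualFev1 = QualFev1.NONE_FOUND,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> tuple[Severity, Source]:
    """FEV1 impairment band with provenance.

    Quantitative percent predicted is graded through the half-open band
    partition; the qualitative FEV1 descriptor is the fallback.
    """
    if fev1_pct_pred is not None and not math.isnan(fev1_pct_pred):
        if fev1_pct_pred <= 0:
            raise ValueError("fev1_pct_pred must be positive")
        for band, edge in criteria.severity_edges:
            if fev1_pct_pred >= edge:
                return band, Source.QUANTITATIVE
    if qualitative_fev1 in _QUAL_FEV1_TO_SEVERITY:
        return _QUAL_FEV1_TO_SEVERITY[qualitative_fev1], Source.QUALITATIVE
    return Severity.MISSING, Source.NONE


def resolve(
    extraction: SpirometryExtraction,
    criteria: ClassificationCriteria = DEFAULT_CRITERIA,
) -> SpirometryClassification:
    """Compose the two classifiers into a final per-study record.

    Never raises on missing data: absent values flow through as
    ``missing`` with source ``none``.  When no FEV1 value or FEV1
    descriptor exists but the obstruction descriptor itself carries a
    grade ("severe obstruction"), that grade is used for severity.
    """
    obstruction, obs_source = classify_obstruction(
        extraction.ratio_fraction,
        extraction.qualitative_obstruction,
        criteria,
        study_id=extraction.study_id,
    )
    severity, sev_source = grade_severity(
        extraction.fev1_pct_pred, extraction.qualitative_fev1, criteria
    )
    if (
        severity is Severity.MISSING
        and extraction.qualitative_obstruction in _QUAL_OBS_TO_SEVERITY
    ):
        severity = _QUAL_OBS_TO_SEVERITY[extraction.qualitative_obstruction]
        sev_source = Source.QUALITATIVE
    return SpirometryClassification(
        study_id=extraction.study_id,
        obstruction=obstruction,
        severity=severity,
        ratio_value=extraction.ratio_fraction,
        fev1_pct_pred=extraction.fev1_pct_pred,
        obstruction_source=obs_source,
        severity_source=sev_source,
    )
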