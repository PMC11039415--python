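"""Seedable multi-facility synthetic note corpus with ground truth.

The generator emulates the variability of templated pulmonary function
reports across facilities: each synthetic facility writes in one of the
shipped report dialects, a fraction of notes carry only qualitative
interpretations, a fraction carry an additional post-bronchodilator block
with different numbers, a fraction are distractors that mention FEV1 in
prose without any results template, and individual values go missing.

Ground truth is internally consistent by construction: the stored truth
labels are obtained by running the classification criteria over an
idealised extraction of exactly the values rendered into the note, so a
correct pipeline must recover them bit for bit on a clean corpus.

Defaults mirror the reference cross-tabulation marginals: obstruction
prevalence 0.707 and severity-band weights proportional to
4535 / 3397 / 3663 / 3270 / 5547 / 3317 with 1193 missing.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from . import classifier
from .data_model import ClinicalNote, ProcedureRecord, Obstruction, Severity
from .template_registry import FacilityTemplate, builtin_dialects
from .value_extractor import QualFev1, QualObstruction, SpirometryExtraction

__all__ = [
    "TruthDistribution",
    "NoiseConfig",
    "CorpusConfig",
    "CorpusBundle",
    "generate_corpus",
    "perturb_corpus",
]

SEVERITY_ORDER = [
    Severity.NORMAL,
    Severity.MILD,
    Severity.MODERATE,
    Severity.MODERATELY_SEVERE,
    Severity.SEVERE,
    Severity.VERY_SEVERE,
    Severity.MISSING,
]

#: integer percent-predicted sampling range per band
_BAND_PCT_RANGE = {
    Severity.NORMAL: (80, 120),
    Severity.MILD: (70, 79),
    Severity.MODERATE: (60, 69),
    Severity.MODERATELY_SEVERE: (50, 59),
    Severity.SEVERE: (35, 49),
    Severity.VERY_SEVERE: (15, 34),
}

_SEVERITY_PHRASE = {
    Severity.NORMAL: "The FEV1 is normal.",
    Severity.MILD: "The FEV1 is mildly reduced.",
    Severity.MODERATE: "The FEV1 is moderately reduced.",
    Severity.MODERATELY_SEVERE: "The FEV1 is moderately-severely reduced.",
    Severity.SEVERE: "The FEV1 is severely reduced.",
    Severity.VERY_SEVERE: "The FEV1 is very severely reduced.",
}

_OBS_SEVERITY_WORD = {
    Severity.MILD: "mild",
    Severity.MODERATE: "moderate",
    Severity.MODERATELY_SEVERE: "moderately severe",
    Severity.SEVERE: "severe",
    Severity.VERY_SEVERE: "very severe",
}

_QUAL_OBS_FROM_SEVERITY = {
    Severity.MILD: QualObstruction.MILD,
    Severity.MODERATE: QualObstruction.MODERATE,
    Severity.MODERATELY_SEVERE: QualObstruction.MODERATELY_SEVERE,
    Severity.SEVERE: QualObstruction.SEVERE,
    Severity.VERY_SEVERE: QualObstruction.VERY_SEVERE,
}

_QUAL_FEV1_FROM_SEVERITY = {
    Severity.NORMAL: QualFev1.NORMAL,
    Severity.MILD: QualFev1.MILD,
    Severity.MODERATE: QualFev1.MODERATE,
    Severity.MODERATELY_SEVERE: QualFev1.MODERATELY_SEVERE,
    Severity.SEVERE: QualFev1.SEVERE,
    Severity.VERY_SEVERE: QualFev1.VERY_SEVERE,
}


class TruthDistribution(BaseModel):
    """Marginal class frequencies the generator draws from."""

    model_config = ConfigDict(frozen=True)

    obstruction_prevalence: float = 0.707
    #: weights over severity bands in SEVERITY_ORDER (last = missing)
    severity_weights: tuple[float, ...] = (4535, 3397, 3663, 3270, 5547, 3317, 1193)

    @field_validator("obstruction_prevalence")
    @classmethod
    def _check_prev(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("obstruction_prevalence must lie in [0, 1]")
        return v

    @field_validator("severity_weights")
    @classmethod
    def _check_weights(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) != len(SEVERITY_ORDER):
            raise ValueError(f"need {len(SEVERITY_ORDER)} severity weights")
        if any(w < 0 for w in v) or sum(v) <= 0:
            raise ValueError("severity weights must be non-negative, sum > 0")
        return v

    def severity_probs(self) -> np.ndarray:
        w = np.asarray(self.severity_weights, dtype=float)
        return w / w.sum()


class NoiseConfig(BaseModel):
    """Which textual perturbations :func:`perturb_corpus` applies."""

    model_config = ConfigDict(frozen=True)

    whitespace_jitter: bool = False
    synonym_swap: bool = False  # "FEV1/FVC" <-> "FEV1:FVC"
    comma_separators: bool = False
    percent_dropout: bool = False

    def any_enabled(self) -> bool:
        return any(
            (self.whitespace_jitter, self.synonym_swap,
             self.comma_separators, self.percent_dropout)
        )


class CorpusConfig(BaseModel):
    """Shape and mix of the generated corpus; ``seed`` fixes everything."""

    model_config = ConfigDict(frozen=True)

    n_facilities: int = 3
    notes_per_facility: int = 50
    seed: int = 0
    #: weights over the shipped dialects, keyed by dialect name
    dialect_mix: dict[str, float] = {"riverside": 1.0, "lakeview": 1.0, "summit": 1.0}
    truth_distribution: TruthDistribution = TruthDistribution()
    p_qualitative_only: float = 0.10
    p_post_bd_section: float = 0.30
    p_distractor_note: float = 0.05
    p_missing_value: float = 0.05
    start_date: dt.date = dt.date(2019, 1, 7)

    @field_validator(
        "p_qualitative_only", "p_post_bd_section", "p_distractor_note",
        "p_missing_value",
    )
    @classmethod
    def _check_prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("n_facilities", "notes_per_facility")
    @classmethod
    def _check_pos(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("corpus dimensions must be positive")
        return v

    @model_validator(mode="after")
    def _check_mix(self) -> "CorpusConfig":
        if not self.dialect_mix or any(w < 0 for w in self.dialect_mix.values()):
            raise ValueError("dialect_mix must be non-empty with weights >= 0")
        if sum(self.dialect_mix.values()) <= 0:
            raise ValueError("dialect_mix weights must sum to > 0")
        unknown = set(self.dialect_mix) - set(builtin_dialects())
        if unknown:
            raise ValueError(f"unknown dialect(s) in mix: {sorted(unknown)}")
        return self


@dataclass
class CorpusBundle:
    """Everything one corpus draw produces."""

    notes: list[ClinicalNote]
    procedures: list[ProcedureRecord]
    truth: pd.DataFrame
    registry: dict[str, FacilityTemplate] = field(default_factory=dict)

    def __iter__(self):
        # allow `notes, procedures, truth = generate_corpus(cfg)`
        return iter((self.notes, self.procedures, self.truth))


# --------------------------------------------------------------------------
# note renderers, one per dialect


def _render_riverside(parts: "_NoteParts") -> str:
    lines = ["SPIROMETRY RESULTS", "Pre-bronchodilator:"]
    if parts.fev1_pct is not None:
        lines.append(f"  FEV1: {parts.fev1_liters:.2f} L ({parts.fev1_pct}% predicted)")
    if parts.ratio is not None:
        lines.append(f"  FEV1/FVC: {parts.ratio * 100:.1f}%")
    lines.append(f"Interpretation: {parts.interpretation}")
    if parts.post_bd:
        lines.append("Post-bronchodilator:")
        if parts.post_pct is not None:
            lines.append(
                f"  FEV1: {parts.post_liters:.2f} L ({parts.post_pct}% predicted)"
            )
        if parts.post_ratio is not None:
            lines.append(f"  FEV1/FVC: {parts.post_ratio * 100:.1f}%")
    return "\n".join(lines)


def _render_lakeview(parts: "_NoteParts") -> str:
    lines = ["PULMONARY FUNCTION TEST REPORT", "PRE-BRONCHODILATOR SPIROMETRY"]
    if parts.fev1_pct is not None:
        lines.append(f"FEV1 = {parts.fev1_liters:.2f} ({parts.fev1_pct} % pred)")
    if parts.ratio is not None:
        lines.append(f"FEV1/FVC = {parts.ratio * 100:.1f} %")
    lines.append(f"IMPRESSION: {parts.interpretation}")
    if parts.post_bd:
        lines.append("POST-BRONCHODILATOR SPIROMETRY")
        if parts.post_pct is not None:
            lines.append(f"FEV1 = {parts.post_liters:.2f} ({parts.post_pct} % pred)")
        if parts.post_ratio is not None:
            lines.append(f"FEV1/FVC = {parts.post_ratio * 100:.1f} %")
    return "\n".join(lines)


def _render_summit(parts: "_NoteParts") -> str:
    lines = ["Pulmonary Function Interpretation"]
    values = []
    if parts.fev1_pct is not None:
        values.append(
            f"FEV1 {parts.fev1_liters:.2f} L, {parts.fev1_pct} percent of predicted"
        )
    if parts.ratio is not None:
        values.append(f"FEV1/FVC ratio {parts.ratio:.3f}")
    if values:
        lines.append("Pre-bronchodilator values: " + ", ".join(values) + ".")
    lines.append(f"Impression: {parts.interpretation}")
    if parts.post_bd:
        post_values = []
        if parts.post_pct is not None:
            post_values.append(
                f"FEV1 {parts.post_liters:.2f} L, {parts.post_pct} percent of predicted"
            )
        if parts.post_ratio is not None:
            post_values.append(f"FEV1/FVC ratio {parts.post_ratio:.3f}")
        lines.append("Post-bronchodilator values: " + ", ".join(post_values) + ".")
    return "\n".join(lines)


_RENDERERS = {
    "riverside": _render_riverside,
    "lakeview": _render_lakeview,
    "summit": _render_summit,
}

_DISTRACTOR_TEXTS = [
    "Pulmonary clinic follow-up. Prior FEV1 values were reviewed and discussed "
    "with the patient; no new spirometry was performed today.",
    "Plan: continue current inhaler. Will repeat spirometry including FEV1 at "
    "the next visit.",
    "Chart review: historical FEV1 trend stable per outside records.",
]


@dataclass
class _NoteParts:
    fev1_liters: Optional[float] = None
    fev1_pct: Optional[int] = None
    ratio: Optional[float] = None
    interpretation: str = ""
    post_bd: bool = False
    post_liters: Optional[float] = None
    post_pct: Optional[int] = None
    post_ratio: Optional[float] = None


def _interpretation_sentence(
    obstructed: bool, severity: Severity, include_fev1_sentence: bool
) -> str:
    if obstructed:
        word = _OBS_SEVERITY_WORD.get(severity)
        base = (
            f"There is {word} obstruction."
            if word
            else "Airflow obstruction is present."
        )
    else:
        base = "No evidence of obstruction."
    if include_fev1_sentence and severity in _SEVERITY_PHRASE:
        base += " " + _SEVERITY_PHRASE[severity]
    return base


def _facility_dialects(config: CorpusConfig, rng: np.random.Generator) -> dict[str, str]:
    names = sorted(config.dialect_mix)
    probs = np.asarray([config.dialect_mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    return {
        f"F{i + 1:03d}": names[rng.choice(len(names), p=probs)]
        for i in range(config.n_facilities)
    }


def generate_corpus(config: CorpusConfig) -> CorpusBundle:
    """Draw a full corpus: notes, procedures, truth table, registry.

    One study/procedure per note; every draw flows through a single
    seeded generator so a fixed seed reproduces the corpus byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    dialects = builtin_dialects()
    facility_dialect = _facility_dialects(config, rng)

    registry = {
        fid: FacilityTemplate(facility_id=fid, **dialects[dname])
        for fid, dname in facility_dialect.items()
    }

    cpt_codes = sorted(
        {"94010", "94375", "94060", "94726", "94727", "94729", "94150"}
    )
    td = config.truth_distribution
    sev_probs = td.severity_probs()

    notes: list[ClinicalNote] = []
    procedures: list[ProcedureRecord] = []
    truth_rows: list[dict] = []
    study_no = 0

    for fid in sorted(facility_dialect):
        dialect_name = facility_dialect[fid]
        render = _RENDERERS[dialect_name]
        for _ in range(config.notes_per_facility):
            study_no += 1
            study_id = f"S{study_no:06d}"
            patient_id = f"P{study_no:06d}"
            note_id = f"N{study_no:06d}"
            proc_date = config.start_date + dt.timedelta(
                days=int(rng.integers(0, 365))
            )
            note_offset = int(rng.integers(-1, 22))
            cpt = cpt_codes[int(rng.integers(len(cpt_codes)))]

            # true physiology
            obstructed = bool(rng.random() < td.obstruction_prevalence)
            if obstructed:
                ratio = round(float(rng.uniform(0.400, 0.699)), 3)
                ratio = min(ratio, 0.699)
            else:
                ratio = round(float(rng.uniform(0.700, 0.900)), 3)
                ratio = max(ratio, 0.700)
            severity = SEVERITY_ORDER[int(rng.choice(len(sev_probs), p=sev_probs))]
            if severity is Severity.MISSING:
                pct: Optional[int] = None
            else:
                lo, hi = _BAND_PCT_RANGE[severity]
                pct = int(rng.integers(lo, hi + 1))

            # note kind
            u = rng.random()
            if u < config.p_distractor_note:
                kind = "distractor"
            elif u < config.p_distractor_note + config.p_qualitative_only:
                kind = "qualitative_only"
            else:
                kind = "templated"

            ratio_in_note = ratio
            pct_in_note = pct
            if kind == "templated" and rng.random() < config.p_missing_value:
                ratio_in_note = None  # the ratio line is simply not printed

            post_bd = kind == "templated" and rng.random() < config.p_post_bd_section

            if kind == "distractor":
                text = _DISTRACTOR_TEXTS[int(rng.integers(len(_DISTRACTOR_TEXTS)))]
                ideal = SpirometryExtraction(study_id=study_id)
                true_ratio, true_pct = None, None
            else:
                interpretation = _interpretation_sentence(
                    obstructed, severity, include_fev1_sentence=True
                )
                if kind == "qualitative_only":
                    parts = _NoteParts(interpretation=interpretation)
                    true_ratio, true_pct = None, None
                else:
                    liters = (
                        round(3.5 * pct_in_note / 100.0, 2)
                        if pct_in_note is not None
                        else None
                    )
                    parts = _NoteParts(
                        fev1_liters=liters,
                        fev1_pct=pct_in_note,
                        ratio=ratio_in_note,
                        interpretation=interpretation,
                        post_bd=post_bd,
                    )
                    if post_bd:
                        if pct_in_note is not None:
                            parts.post_pct = min(pct_in_note + 6, 130)
                            parts.post_liters = round(3.5 * parts.post_pct / 100.0, 2)
                        parts.post_ratio = (
                            min(round(ratio + 0.030, 3), 0.95)
                            if ratio_in_note is not None
                            else None
                        )
                        if parts.post_pct is None and parts.post_ratio is None:
                            parts.post_bd = False
                    text = render(parts)
                    true_ratio = ratio_in_note
                    true_pct = pct_in_note
                if kind == "qualitative_only":
                    text = render(parts)
                # idealised extraction: exactly what the note supports
                qual_obs = (
                    _QUAL_OBS_FROM_SEVERITY.get(
                        severity, QualObstruction.UNSPECIFIED_OBSTRUCTION
                    )
                    if obstructed
                    else QualObstruction.NO_OBSTRUCTION
                )
                qual_fev1 = _QUAL_FEV1_FROM_SEVERITY.get(severity, QualFev1.NONE_FOUND)
                prov = {}
                if true_ratio is not None:
                    prov["ratio_raw"] = ("ratio", "", 0)
                if true_pct is not None:
                    prov["fev1_pct_pred"] = ("fev1_pct_pred", "", 0)
                ideal = SpirometryExtraction(
                    study_id=study_id,
                    fev1_pct_pred=float(true_pct) if true_pct is not None else None,
                    ratio_raw=true_ratio,
                    ratio_fraction=true_ratio,
                    qualitative_obstruction=qual_obs,
                    qualitative_fev1=qual_fev1,
                    provenance=prov,
                )

            truth_cls = classifier.resolve(ideal)

            notes.append(
                ClinicalNote(
                    note_id=note_id,
                    patient_id=patient_id,
                    facility_id=fid,
                    note_date=proc_date + dt.timedelta(days=note_offset),
                    text=text,
                )
            )
            procedures.append(
                ProcedureRecord(
                    study_id=study_id,
                    patient_id=patient_id,
                    facility_id=fid,
                    procedure_date=proc_date,
                    cpt_code=cpt,
                    has_structured_fev1=False,
                )
            )
            truth_rows.append(
                {
                    "study_id": study_id,
                    "facility_id": fid,
                    "dialect": dialect_name,
                    "note_kind": kind,
                    "true_ratio": true_ratio,
                    "true_pct_pred": true_pct,
                    "true_obstruction": truth_cls.obstruction.value,
                    "true_severity": truth_cls.severity.value,
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "study_id", "facility_id", "dialect", "note_kind",
            "true_ratio", "true_pct_pred", "true_obstruction", "true_severity",
        ],
    )
    return CorpusBundle(notes=notes, procedures=procedures, truth=truth,
                        registry=registry)


# --------------------------------------------------------------------------
# perturbations

_NUM4_RE_SRC = r"\d{4,}"


def _perturb_text(text: str, noise: NoiseConfig, rng: np.random.Generator) -> str:
    import re

    if noise.synonym_swap:
        text = text.replace("FEV1/FVC", "FEV1:FVC")
    if noise.comma_separators:
        def _commafy(m: "re.Match[str]") -> str:
            s = m.group(0)
            out = ""
            for i, ch in enumerate(reversed(s)):
                if i and i % 3 == 0:
                    out = "," + out
                out = ch + out
            return out

        text = re.sub(_NUM4_RE_SRC, _commafy, text)
    if noise.percent_dropout:
        text = text.replace("%", "")
    if noise.whitespace_jitter:
        # widen some existing single spaces; never touches token interiors
        out = []
        for ch in text:
            out.append(ch)
            if ch == " " and rng.random() < 0.3:
                out.append(" ")
        text = "".join(out)
    return text


def perturb_corpus(
    notes: Sequence[ClinicalNote], noise_config: NoiseConfig, seed: int
) -> list[ClinicalNote]:
    """Deterministically perturbed copy of a note collection.

    Ground truth is untouched: perturbations change surface form only
    (spacing, label synonyms, digit grouping, percent signs), all of which
    the shipped dialect patterns tolerate.
    """
    rng = np.random.default_rng(seed)
    if not noise_config.any_enabled():
        return list(notes)
    out = []
    for note in notes:
        out.append(
            note.model_copy(update={"text": _perturb_text(note.text, noise_config, rng)})
        )
    return out
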