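"""Pull spirometry values and descriptors out of a snippet.

Only pre-bronchodilator content is eligible: segments opened by a
post-bronchodilator marker are blanked (replaced by spaces, so every
offset still indexes the original snippet) before any pattern runs.

Quantitative slots take the first match in reading order; captured numbers
tolerate comma thousands separators and an optional "%" suffix, and values
outside configurable plausibility ranges are dropped and logged rather
than propagated.  Qualitative descriptors are resolved through a shipped,
editable lexicon with negation entries ("no evidence of obstruction")
and longest-match precedence.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .template_registry import FacilityTemplate

__all__ = [
    "QualObstruction",
    "QualFev1",
    "SpirometryExtraction",
    "PlausibilityRanges",
    "LexiconEntry",
    "load_lexicon",
    "parse_lexicon",
    "default_lexicon",
    "mask_post_bronchodilator",
    "extract_quantitative",
    "normalize_ratio",
    "extract_qualitative",
    "extract_all",
]

logger = logging.getLogger(__name__)


class QualObstruction(str, enum.Enum):
    NONE_FOUND = "none_found"
    NO_OBSTRUCTION = "no_obstruction"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"
    VERY_SEVERE = "very_severe"
    UNSPECIFIED_OBSTRUCTION = "unspecified_obstruction"


class QualFev1(str, enum.Enum):
    NONE_FOUND = "none_found"
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"
    VERY_SEVERE = "very_severe"


class SpirometryExtraction(BaseModel):
    """Raw extracted values for one study, before classification.

    ``provenance`` maps each populated field to (pattern slot, matched
    text, offset into the original snippet).
    """

    model_config = ConfigDict(frozen=True)

    study_id: str
    fev1_liters: Optional[float] = None
    fev1_pct_pred: Optional[float] = None
    ratio_raw: Optional[float] = None
    ratio_fraction: Optional[float] = None
    qualitative_obstruction: QualObstruction = QualObstruction.NONE_FOUND
    qualitative_fev1: QualFev1 = QualFev1.NONE_FOUND
    provenance: dict[str, tuple[str, str, int]] = {}

    @model_validator(mode="after")
    def _check(self) -> "SpirometryExtraction":
        if self.ratio_fraction is not None and self.ratio_raw is None:
            raise ValueError("ratio_fraction present requires ratio_raw present")
        for field in ("fev1_liters", "fev1_pct_pred", "ratio_raw"):
            if getattr(self, field) is not None and field not in self.provenance:
                raise ValueError(f"present value {field} lacks a provenance entry")
        return self


@dataclass(frozen=True)
class PlausibilityRanges:
    """Open intervals outside which an extracted value is discarded.

    Chosen to reject page numbers, dates and list indices captured by
    loose patterns; the ratio range applies to the normalised fraction.
    """

    fev1_liters: tuple[float, float] = (0.2, 10.0)
    fev1_pct_pred: tuple[float, float] = (5.0, 200.0)
    ratio_fraction: tuple[float, float] = (0.1, 1.5)


DEFAULT_RANGES = PlausibilityRanges()

_BLANK_LINE_RE = re.compile(r"\n[ \t]*\n")


def mask_post_bronchodilator(snippet_text: str, template: FacilityTemplate) -> str:
    """Blank post-bronchodilator segments, preserving text length.

    From each occurrence of a post-BD marker, characters are replaced by
    spaces up to the next pre-BD marker, the end of the line group (a
    blank line), or the end of the snippet — whichever comes first.
    """
    if not template.post_bd_markers:
        return snippet_text
    post_res = [re.compile(p, re.IGNORECASE) for p in template.post_bd_markers]
    pre_res = [re.compile(p, re.IGNORECASE) for p in template.pre_bd_markers]

    chars = list(snippet_text)
    for post_re in post_res:
        for m in post_re.finditer(snippet_text):
            start = m.start()
            candidates = [len(snippet_text)]
            for pre_re in pre_res:
                pm = pre_re.search(snippet_text, m.end())
                if pm:
                    candidates.append(pm.start())
            bm = _BLANK_LINE_RE.search(snippet_text, m.end())
            if bm:
                candidates.append(bm.start())
            end = min(candidates)
            for i in range(start, end):
                if chars[i] != "\n":
                    chars[i] = " "
    return "".join(chars)


def _parse_number(raw: str) -> Optional[float]:
    cleaned = raw.strip().rstrip("%").strip().replace(",", "")
    try:
        return float(cleaned)
    except ValueError:
        return None


def normalize_ratio(ratio_raw: float) -> Optional[float]:
    """Bring a printed FEV1:FVC ratio onto the fraction scale.

    Reports print the ratio either as a fraction ("0.65") or as a percent
    ("65%"); values at or below 1.0 pass through, values in (1, 120] are
    divided by 100, anything larger is implausible and dropped.
    """
    if ratio_raw <= 1.0:
        return ratio_raw
    if ratio_raw <= 120.0:
        return ratio_raw / 100.0
    logger.info("dropping implausible ratio value %s", ratio_raw)
    return None


def extract_quantitative(
    masked_text: str,
    template: FacilityTemplate,
    *,
    study_id: str = "",
    ranges: PlausibilityRanges = DEFAULT_RANGES,
) -> SpirometryExtraction:
    """First-match extraction of the three quantitative slots.

    A slot with no match is absent; a match whose parsed value falls
    outside its plausibility range is dropped and logged.
    """
    values: dict[str, Optional[float]] = {}
    provenance: dict[str, tuple[str, str, int]] = {}

    for slot, field, rng in (
        ("fev1_liters", "fev1_liters", ranges.fev1_liters),
        ("fev1_pct_pred", "fev1_pct_pred", ranges.fev1_pct_pred),
        ("ratio", "ratio_raw", None),
    ):
        pattern = template.compiled_pattern(slot)
        if pattern is None:
            continue
        m = pattern.search(masked_text)
        if not m:
            continue
        raw = m.group(1) if m.groups() else m.group(0)
        value = _parse_number(raw)
        if value is None:
            continue
        if rng is not None and not rng[0] < value < rng[1]:
            logger.info(
                "study %s: dropping implausible %s value %s (matched %r)",
                study_id,
                field,
                value,
                m.group(0),
            )
            continue
        values[field] = value
        provenance[field] = (slot, m.group(0), m.start())

    ratio_fraction = None
    if "ratio_raw" in values:
        ratio_fraction = normalize_ratio(values["ratio_raw"])
        if ratio_fraction is not None:
            lo, hi = ranges.ratio_fraction
            if not lo < ratio_fraction < hi:
                logger.info(
                    "study %s: dropping implausible ratio fraction %s",
                    study_id,
                    ratio_fraction,
                )
                ratio_fraction = None
        if ratio_fraction is None:
            del values["ratio_raw"]
            del provenance["ratio_raw"]

    return SpirometryExtraction(
        study_id=study_id,
        fev1_liters=values.get("fev1_liters"),
        fev1_pct_pred=values.get("fev1_pct_pred"),
        ratio_raw=values.get("ratio_raw"),
        ratio_fraction=ratio_fraction,
        provenance=provenance,
    )


@dataclass(frozen=True)
class LexiconEntry:
    pattern: re.Pattern
    field: str  # "obstruction" | "fev1"
    category: str
    negation: bool = False


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Load an ordered descriptor lexicon from a YAML file."""
    return parse_lexicon(Path(path).read_text(encoding="utf-8"))


def parse_lexicon(text: str) -> list[LexiconEntry]:
    doc = yaml.safe_load(text)
    entries = []
    for item in doc["entries"]:
        if item["field"] not in ("obstruction", "fev1"):
            raise ValueError(f"lexicon entry field must be obstruction|fev1: {item}")
        entries.append(
            LexiconEntry(
                pattern=re.compile(item["pattern"], re.IGNORECASE),
                field=item["field"],
                category=item["category"],
                negation=bool(item.get("negation", False)),
            )
        )
    return entries


_DEFAULT_LEXICON: Optional[list[LexiconEntry]] = None


def default_lexicon() -> list[LexiconEntry]:
    """The lexicon shipped with the package (cached)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        from importlib.resources import files

        _DEFAULT_LEXICON = parse_lexicon(
            files("pftmine.data").joinpath("lexicon.yaml").read_text(encoding="utf-8")
        )
    return _DEFAULT_LEXICON


def _search_regions(
    masked_text: str, template: FacilityTemplate
) -> list[tuple[int, str]]:
    """Regions to scan for descriptors: the dialect's qualitative sections
    if a pattern is configured, else the whole snippet."""
    section = template.compiled_pattern("qualitative_section")
    if section is None:
        return [(0, masked_text)]
    regions = [(m.start(), m.group(0)) for m in section.finditer(masked_text)]
    return regions or [(0, masked_text)]


def _best_match(
    matches: list[tuple[int, int, str]], anchor_offset: int
) -> Optional[tuple[int, int, str]]:
    # drop matches strictly contained in a longer match (longest-match
    # precedence: "moderately severe obstruction" beats "severe obstruction")
    kept = []
    for i, (s, e, cat) in enumerate(matches):
        contained = any(
            (s2 <= s and e <= e2) and (s2, e2) != (s, e)
            for j, (s2, e2, _) in enumerate(matches)
            if j != i
        )
        if not contained:
            kept.append((s, e, cat))
    if not kept:
        return None
    # nearest to the anchor wins; ties to the earlier, then longer, match
    kept.sort(key=lambda m: (abs(m[0] - anchor_offset), m[0], -(m[1] - m[0])))
    return kept[0]


def extract_qualitative(
    masked_text: str,
    template: FacilityTemplate,
    lexicon: Optional[Sequence[LexiconEntry]] = None,
    *,
    anchor_offset: int = 0,
) -> tuple[QualObstruction, QualFev1, dict[str, tuple[str, str, int]]]:
    """Resolve qualitative obstruction and FEV1 descriptors.

    When several descriptors match, the one whose offset is nearest the
    anchor wins, after discarding matches contained in longer ones (so a
    negated phrase suppresses the bare descriptor inside it).
    """
    lexicon = default_lexicon() if lexicon is None else lexicon
    by_field: dict[str, list[tuple[int, int, str]]] = {"obstruction": [], "fev1": []}
    text_at: dict[tuple[int, int], str] = {}
    for region_start, region_text in _search_regions(masked_text, template):
        for entry in lexicon:
            for m in entry.pattern.finditer(region_text):
                span = (region_start + m.start(), region_start + m.end())
                by_field[entry.field].append((span[0], span[1], entry.category))
                text_at[span] = m.group(0)

    provenance: dict[str, tuple[str, str, int]] = {}

    best_obs = _best_match(by_field["obstruction"], anchor_offset)
    qual_obstruction = QualObstruction.NONE_FOUND
    if best_obs:
        s, e, cat = best_obs
        qual_obstruction = QualObstruction(cat)
        provenance["qualitative_obstruction"] = ("qualitative_section", text_at[(s, e)], s)

    best_fev1 = _best_match(by_field["fev1"], anchor_offset)
    qual_fev1 = QualFev1.NONE_FOUND
    if best_fev1:
        s, e, cat = best_fev1
        qual_fev1 = QualFev1(cat)
        provenance["qualitative_fev1"] = ("qualitative_section", text_at[(s, e)], s)

    return qual_obstruction, qual_fev1, provenance


def extract_all(
    snippet_text: str,
    template: FacilityTemplate,
    *,
    study_id: str = "",
    lexicon: Optional[Sequence[LexiconEntry]] = None,
    ranges: PlausibilityRanges = DEFAULT_RANGES,
    anchor_offset: int = 0,
) -> SpirometryExtraction:
    """Mask post-bronchodilator content, then run all slots.

    Pure and deterministic: identical snippet and template always yield an
    identical extraction.
    """
    masked = mask_post_bronchodilator(snippet_text, template)
    quant = extract_quantitative(
        masked, template, study_id=study_id, ranges=ranges
    )
    qual_obs, qual_fev1, qual_prov = extract_qualitative(
        masked, template, lexicon, anchor_offset=anchor_offset
    )
    provenance = dict(quant.provenance)
    provenance.update(qual_prov)
    return SpirometryExtraction(
        study_id=study_id,
        fev1_liters=quant.fev1_liters,
        fev1_pct_pred=quant.fev1_pct_pred,
        ratio_raw=quant.ratio_raw,
        ratio_fraction=quant.ratio_fraction,
        qualitative_obstruction=qual_obs,
        qualitative_fev1=qual_fev1,
        provenance=provenance,
    )
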