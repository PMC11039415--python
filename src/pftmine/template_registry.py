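"""Registry of facility-specific note templates.

Each facility that reports pulmonary function tests with a consistent
syntactical convention gets a :class:`FacilityTemplate`: the anchor phrase
that delineates the start of PFT results, the snippet window sizes, and the
dialect's extraction patterns.  Facility-specific behaviour is data, not
code branches — the registry is a YAML (or JSON) file.

Notes from facilities without a registered template are never guessed at;
they are skipped and counted.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "FacilityTemplate",
    "RegistryError",
    "load_registry",
    "parse_registry",
    "template_for",
    "builtin_dialects",
]

#: the four extraction slots a dialect may define
PATTERN_SLOTS = ("fev1_liters", "fev1_pct_pred", "ratio", "qualitative_section")

#: default markers opening a post-bronchodilator segment
DEFAULT_POST_BD_MARKERS = [r"post[\s-]?(?:bronchodilator|bd|drug)\b"]
#: default markers returning to pre-bronchodilator content
DEFAULT_PRE_BD_MARKERS = [r"pre[\s-]?(?:bronchodilator|bd|drug)\b"]


class RegistryError(ValueError):
    """Registry file failed to load: bad pattern, duplicate facility, etc."""


class FacilityTemplate(BaseModel):
    """Anchor phrase plus extraction dialect for one facility.

    ``anchor_pattern`` and every dialect pattern are regular-expression
    source strings, compiled eagerly (case-insensitive) so malformed
    patterns surface at load time rather than mid-extraction.
    """

    model_config = ConfigDict(frozen=True)

    facility_id: str
    anchor_pattern: str
    before_chars: int = 150
    after_chars: int = 1000
    dialect_patterns: dict[str, str] = {}
    post_bd_markers: list[str] = DEFAULT_POST_BD_MARKERS
    pre_bd_markers: list[str] = DEFAULT_PRE_BD_MARKERS

    @field_validator("before_chars", "after_chars")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("window sizes must be non-negative")
        return v

    @field_validator("anchor_pattern")
    @classmethod
    def _compiles(cls, v: str) -> str:
        try:
            re.compile(v, re.IGNORECASE)
        except re.error as exc:
            raise ValueError(f"anchor_pattern: invalid pattern: {exc}") from exc
        return v

    @field_validator("dialect_patterns")
    @classmethod
    def _slots_valid(cls, v: dict[str, str]) -> dict[str, str]:
        unknown = set(v) - set(PATTERN_SLOTS)
        if unknown:
            raise ValueError(f"unknown pattern slot(s): {sorted(unknown)}")
        for slot, src in v.items():
            try:
                re.compile(src, re.IGNORECASE)
            except re.error as exc:
                raise ValueError(f"slot {slot!r}: invalid pattern: {exc}") from exc
        return v

    @field_validator("post_bd_markers", "pre_bd_markers")
    @classmethod
    def _markers_compile(cls, v: list[str]) -> list[str]:
        for src in v:
            try:
                re.compile(src, re.IGNORECASE)
            except re.error as exc:
                raise ValueError(f"marker {src!r}: invalid pattern: {exc}") from exc
        return v

    def compiled_anchor(self) -> re.Pattern:
        return re.compile(self.anchor_pattern, re.IGNORECASE)

    def compiled_pattern(self, slot: str) -> Optional[re.Pattern]:
        src = self.dialect_patterns.get(slot)
        return re.compile(src, re.IGNORECASE) if src is not None else None


def _template_from_entry(
    entry: dict, dialects: dict[str, dict], source: str
) -> FacilityTemplate:
    if "facility_id" not in entry:
        raise RegistryError(f"{source}: facility entry without facility_id: {entry}")
    fid = str(entry["facility_id"])
    fields: dict = {}
    if "dialect" in entry:
        name = entry["dialect"]
        if name not in dialects:
            raise RegistryError(f"{source}: facility {fid}: unknown dialect {name!r}")
        fields.update(dialects[name])
    fields.update({k: v for k, v in entry.items() if k != "dialect"})
    try:
        return FacilityTemplate(**fields)
    except ValueError as exc:
        raise RegistryError(f"{source}: facility {fid}: {exc}") from exc


def parse_registry(doc: dict, source: str = "<registry>") -> dict[str, FacilityTemplate]:
    """Build a registry from a parsed YAML/JSON document.

    The document has an optional ``dialects`` map of named pattern sets and
    a ``facilities`` list; each facility entry either references a dialect
    by name or inlines the template fields.  Duplicate facility ids are a
    hard error — silent override is an audit hazard.
    """
    if not isinstance(doc, dict) or "facilities" not in doc:
        raise RegistryError(f"{source}: expected a mapping with a 'facilities' list")
    dialects = doc.get("dialects") or {}
    registry: dict[str, FacilityTemplate] = {}
    for entry in doc["facilities"]:
        tmpl = _template_from_entry(dict(entry), dialects, source)
        if tmpl.facility_id in registry:
            raise RegistryError(
                f"{source}: duplicate facility entry {tmpl.facility_id!r}"
            )
        registry[tmpl.facility_id] = tmpl
    return registry


def load_registry(path: str | Path) -> dict[str, FacilityTemplate]:
    """Load and validate a facility-template registry file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return parse_registry(doc, source=str(path))


def template_for(
    facility_id: str, registry: dict[str, FacilityTemplate]
) -> Optional[FacilityTemplate]:
    """Exact lookup; ``None`` for unregistered facilities (skip, don't guess)."""
    return registry.get(facility_id)


def builtin_dialects() -> dict[str, dict]:
    """The synthetic report dialects shipped with the package.

    These are plausible reconstructions of templated PFT report styles, not
    transcriptions of any real facility's notes.
    """
    from importlib.resources import files

    doc = yaml.safe_load(
        files("pftmine.data").joinpath("dialects.yaml").read_text(encoding="utf-8")
    )
    return doc["dialects"]
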