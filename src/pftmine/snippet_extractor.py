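"""Anchor location and character-window snippet cutting.

A templated PFT note is recognised by its facility's anchor phrase; the
unit handed to pattern matching is the fixed character window around the
first anchor match — up to ``before_chars`` characters before the match
start and ``after_chars`` after the match end, truncated at note
boundaries.  No tokenisation or sentence segmentation is involved: pure
character-window logic.

All offsets are 0-based, half-open, and refer to the *normalised* note
text.
"""

from __future__ import annotations

import re
import unicodedata
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .template_registry import FacilityTemplate

__all__ = ["Snippet", "normalize_text", "find_anchor", "extract_snippet"]


class Snippet(BaseModel):
    """A windowed excerpt tied to its source note and anchor match."""

    model_config = ConfigDict(frozen=True)

    study_id: str
    note_id: str
    facility_id: str
    text: str
    #: offsets of the anchor match within the normalised note text
    anchor_start: int
    anchor_end: int
    #: offset of ``text[0]`` within the normalised note text
    window_start: int

    @model_validator(mode="after")
    def _check_span(self) -> "Snippet":
        if not 0 <= self.anchor_start < self.anchor_end:
            raise ValueError("anchor span must be non-empty and non-negative")
        if self.window_start > self.anchor_start:
            raise ValueError("window must start at or before the anchor")
        return self

    @property
    def anchor_offset(self) -> int:
        """Offset of the anchor match start within :attr:`text`."""
        return self.anchor_start - self.window_start


_CRLF_RE = re.compile(r"\r\n?")


def normalize_text(raw: str) -> str:
    """Normalise a note body for matching.

    NFC unicode normalisation, CR/LF and lone CR to LF, and non-breaking
    spaces to ordinary spaces.  Idempotent; all downstream offsets refer to
    the output of this function.
    """
    text = unicodedata.normalize("NFC", raw)
    text = _CRLF_RE.sub("\n", text)
    return text.replace("\u00a0", " ")


def find_anchor(
    note_text: str, template: FacilityTemplate
) -> Optional[tuple[int, int]]:
    """Span of the first anchor-pattern match in normalised text, or None.

    Only the first match is used: a note listing several studies yields a
    single window (sequential studies within one snippet are not
    partitioned).
    """
    m = template.compiled_anchor().search(note_text)
    return (m.start(), m.end()) if m else None


def extract_snippet(
    note_text: str,
    span: tuple[int, int],
    template: FacilityTemplate,
    *,
    study_id: str = "",
    note_id: str = "",
) -> Snippet:
    """Cut the character window around an anchor span.

    The window covers ``[anchor_start - before_chars, anchor_end +
    after_chars)`` with "up to" semantics at both note boundaries, so the
    anchor match itself is always fully inside the snippet.
    """
    anchor_start, anchor_end = span
    if not 0 <= anchor_start < anchor_end <= len(note_text):
        raise ValueError(f"span {span} invalid for note of length {len(note_text)}")
    start = max(0, anchor_start - template.before_chars)
    end = min(len(note_text), anchor_end + template.after_chars)
    return Snippet(
        study_id=study_id,
        note_id=note_id,
        facility_id=template.facility_id,
        text=note_text[start:end],
        anchor_start=anchor_start,
        anchor_end=anchor_end,
        window_start=start,
    )
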