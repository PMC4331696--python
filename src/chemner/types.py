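"""Core domain containers: documents, mentions, tokens and sentence spans.

Offsets are 0-based, half-open and counted in Unicode code points.  A
document's title and abstract are separate coordinate spaces, flagged
``"T"`` and ``"A"`` respectively, following the CHEMDNER corpus layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

SECTIONS = ("T", "A")

#: CHEMDNER mention subtypes (the last two are the coordination and
#: catch-all categories).
SUBTYPES = (
    "SYSTEMATIC",
    "TRIVIAL",
    "FAMILY",
    "ABBREVIATION",
    "FORMULA",
    "IDENTIFIER",
    "MULTIPLE",
    "NO_CLASS",
)


class CorpusError(ValueError):
    """Malformed corpus content (bad line, bad offsets, unknown document)."""


@dataclass(frozen=True)
class Mention:
    """A chemical entity mention anchored in one document section.

    Parameters
    ----------
    section : {"T", "A"}
        Title or abstract coordinate space.
    start, end : int
        0-based, half-open character offsets into the section text.
    text : str
        Surface string; must equal the section substring at ``[start, end)``.
    subtype : str, optional
        CHEMDNER subtype, carried on gold mentions for error breakdowns.
    confidence : float, optional
        Score in [0, 1] attached to predicted mentions.
    """

    section: str
    start: int
    end: int
    text: str
    subtype: Optional[str] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"section must be one of {SECTIONS}, got {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if len(self.text) != self.end - self.start:
            raise ValueError(
                f"mention text length {len(self.text)} != span length "
                f"{self.end - self.start} for {self.text!r}"
            )
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise ValueError(f"unknown mention subtype {self.subtype!r}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence out of [0, 1]: {self.confidence}")

    @property
    def span(self) -> tuple:
        return (self.section, self.start, self.end)

    def with_confidence(self, confidence: float) -> "Mention":
        return replace(self, confidence=confidence)


@dataclass
class Document:
    """A sectioned document (title + abstract) with its mentions."""

    doc_id: str
    title: str
    abstract: str
    mentions: List[Mention] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section {section!r}")

    def validate_mentions(self) -> None:
        """Check that every mention's text equals its offset substring."""
        for m in self.mentions:
            text = self.section_text(m.section)
            if m.end > len(text):
                raise CorpusError(
                    f"{self.doc_id}: mention span {m.span} exceeds section length {len(text)}"
                )
            found = text[m.start : m.end]
            if found != m.text:
                raise CorpusError(
                    f"{self.doc_id}: annotation text mismatch at {m.span}: "
                    f"expected {m.text!r}, found {found!r}"
                )

    def copy_without_mentions(self) -> "Document":
        return Document(self.doc_id, self.title, self.abstract, [])


@dataclass(frozen=True)
class Token:
    """A surface token with offsets in section space plus tag annotations."""

    surface: str
    start: int
    end: int
    lemma: str = ""
    pos: str = ""
    chunk: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.surface):
            raise ValueError(
                f"token span [{self.start},{self.end}) inconsistent with "
                f"surface {self.surface!r}"
            )

    def tagged(self, lemma: str, pos: str, chunk: str) -> "Token":
        return replace(self, lemma=lemma, pos=pos, chunk=chunk)


@dataclass
class SentenceSpan:
    """A sentence's character span and its tokens."""

    start: int
    end: int
    tokens: List[Token] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.tokens:
            if not (self.start <= t.start and t.end <= self.end):
                raise ValueError(f"token {t.surface!r} outside sentence span")
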