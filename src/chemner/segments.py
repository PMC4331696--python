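"""Chemical basic-name-segment decomposition and composition ratio.

Systematic chemical names are built from morpheme-like *basic name
segments* ("meth", "oxy", "idine", ...).  A token is decomposed by
splitting it at letter/digit/punctuation boundaries; each maximal letter
run is then covered left-to-right by greedy longest matches against a
segment dictionary, with any residue kept as an unmatched fragment.

Two statistics feed the recogniser: the *segment count* (matched pieces
plus unmatched and numeric fragments, delimiters excluded) used as a CRF
feature, and the *composition ratio* (dictionary-matched characters over
all characters of the token) used by the composition-based relabelling
heuristic.  Numeric runs therefore count toward the segment count but
never toward the ratio's numerator.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources as _ilr
from typing import FrozenSet, Iterable, List, Tuple


class PieceKind(enum.Enum):
    MATCHED = "MATCHED"
    UNMATCHED_FRAGMENT = "UNMATCHED_FRAGMENT"
    NUMERIC_FRAGMENT = "NUMERIC_FRAGMENT"
    DELIMITER = "DELIMITER"


@dataclass(frozen=True)
class Piece:
    text: str
    kind: PieceKind


@dataclass(frozen=True)
class Decomposition:
    """Ordered pieces whose texts concatenate back to the original token."""

    token: str
    pieces: Tuple[Piece, ...]

    def matched_chars(self) -> int:
        return sum(len(p.text) for p in self.pieces if p.kind is PieceKind.MATCHED)

    def segment_count(self) -> int:
        return sum(1 for p in self.pieces if p.kind is not PieceKind.DELIMITER)


class SegmentDictionary:
    """A set of lowercase alphabetic basic-name segments."""

    def __init__(self, entries: Iterable[str]):
        cleaned = set()
        for entry in entries:
            seg = entry.strip().lower()
            if not seg:
                continue
            if not seg.isascii() or not seg.isalpha():
                raise ValueError(f"segment {entry!r} must be alphabetic")
            cleaned.add(seg)
        if not cleaned:
            raise ValueError("segment dictionary must be non-empty")
        self.entries: FrozenSet[str] = frozenset(cleaned)
        self.max_len = max(len(s) for s in cleaned)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, segment: str) -> bool:
        return segment in self.entries

    @classmethod
    def from_file(cls, path) -> "SegmentDictionary":
        with open(path, encoding="utf-8") as fh:
            return cls(line for line in fh)


def load_segment_dictionary(path=None) -> SegmentDictionary:
    """Load a segment dictionary file, or the packaged fixture subset."""
    if path is None:
        text = _ilr.files("chemner.resources").joinpath("segments.txt").read_text("utf-8")
        return SegmentDictionary(text.splitlines())
    return SegmentDictionary.from_file(path)


_RUNS = re.compile(r"[A-Za-z]+|[0-9]+|[^A-Za-z0-9]+")


def _cover_letter_run(run: str, sd: SegmentDictionary) -> List[Piece]:
    """Greedy leftmost-longest cover of a letter run; residues become
    unmatched fragments."""
    low = run.lower()
    pieces: List[Piece] = []
    pending_start = None
    i = 0
    n = len(run)
    while i < n:
        best = 0
        for length in range(min(sd.max_len, n - i), 0, -1):
            if low[i : i + length] in sd.entries:
                best = length
                break
        if best:
            if pending_start is not None:
                pieces.append(Piece(run[pending_start:i], PieceKind.UNMATCHED_FRAGMENT))
                pending_start = None
            pieces.append(Piece(run[i : i + best], PieceKind.MATCHED))
            i += best
        else:
            if pending_start is None:
                pending_start = i
            i += 1
    if pending_start is not None:
        pieces.append(Piece(run[pending_start:], PieceKind.UNMATCHED_FRAGMENT))
    return pieces


def decompose(token: str, sd: SegmentDictionary) -> Decomposition:
    """Decompose a token into matched segments, fragments and delimiters."""
    if not token:
        raise ValueError("token must be non-empty")
    pieces: List[Piece] = []
    for match in _RUNS.finditer(token):
        run = match.group(0)
        if run[0].isascii() and run[0].isalpha():
            pieces.extend(_cover_letter_run(run, sd))
        elif run.isdigit():
            pieces.append(Piece(run, PieceKind.NUMERIC_FRAGMENT))
        else:
            pieces.append(Piece(run, PieceKind.DELIMITER))
    return Decomposition(token, tuple(pieces))


def count_segments(token: str, sd: SegmentDictionary) -> int:
    """Number of basic segments: matched + unmatched + numeric fragments."""
    if not token:
        return 0
    return decompose(token, sd).segment_count()


def composition_ratio(token: str, sd: SegmentDictionary) -> float:
    """Fraction of the token's characters covered by matched segments."""
    if not token:
        raise ValueError("token must be non-empty")
    return decompose(token, sd).matched_chars() / len(token)
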