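"""Recall-boosting post-processing heuristics and CDI ranking.

Two rule-based steps run after CRF decoding, both monotone in the set of
chemical-labelled tokens (a label is never removed):

* **Abbreviation recognition** — when a recognised entity is immediately
  followed by ``( x )`` and ``x`` was labelled non-chemical, ``x`` becomes
  a candidate short form; if its characters occur in order within the
  entity string, every occurrence of that surface in the document is
  relabelled as a single-token chemical mention.
* **Composition-based relabelling** — a token labelled ``O`` with
  confidence below ``t1`` is relabelled ``B`` when its chemical segment
  composition ratio exceeds ``t2``.  Defaults ``t1 = 0.93`` and
  ``t2 = 0.9`` are the precision/F1-optimal settings; both comparisons
  are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set, Tuple

from .segments import SegmentDictionary, composition_ratio
from .types import Mention, Token

__all__ = [
    "RelabelConfig",
    "verify_abbreviation",
    "find_abbreviation_candidates",
    "relabel_surfaces",
    "recognise_abbreviations",
    "relabel_by_composition",
    "rank_cdi",
]


@dataclass(frozen=True)
class RelabelConfig:
    """Thresholds and switches for the post-processing heuristics."""

    t1: float = 0.93
    t2: float = 0.9
    enable_abbrev: bool = True
    enable_composition: bool = True

    def __post_init__(self) -> None:
        for name, value in (("t1", self.t1), ("t2", self.t2)):
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def verify_abbreviation(candidate: str, entity: str) -> bool:
    """True iff the candidate's characters occur in order (not necessarily
    contiguously) within the entity, case-insensitively."""
    if not candidate or not entity:
        raise ValueError("candidate and entity must be non-empty")
    entity_low = entity.lower()
    pos = 0
    for ch in candidate.lower():
        found = entity_low.find(ch, pos)
        if found < 0:
            return False
        pos = found + 1
    return True


def find_abbreviation_candidates(
    tokens: Sequence[Token],
    labels: Sequence[str],
    mentions: Sequence[Mention],
) -> Set[str]:
    """Surfaces verified as short forms of entities they parenthetically follow.

    For a mention whose last token is at position ``i``, requires
    ``tokens[i+1] == '('``, ``tokens[i+3] == ')'`` and ``labels[i+2] == 'O'``.
    """
    end_index = {tok.end: i for i, tok in enumerate(tokens)}
    candidates: Set[str] = set()
    for m in mentions:
        i = end_index.get(m.end)
        if i is None or i + 3 >= len(tokens):
            continue
        if (
            tokens[i + 1].surface == "("
            and tokens[i + 3].surface == ")"
            and labels[i + 2] == "O"
        ):
            short = tokens[i + 2].surface
            if verify_abbreviation(short, m.text):
                candidates.add(short)
    return candidates


def relabel_surfaces(
    tokens: Sequence[Token],
    labels: Sequence[str],
    confidences: Sequence[float],
    surfaces: Iterable[str],
    new_confidence: float = 1.0,
) -> Tuple[List[str], List[float]]:
    """Relabel every O-labelled occurrence of the given surfaces as B."""
    surfaces = set(surfaces)
    labels = list(labels)
    confidences = list(confidences)
    for i, tok in enumerate(tokens):
        if labels[i] == "O" and tok.surface in surfaces:
            labels[i] = "B"
            confidences[i] = new_confidence
    return labels, confidences


def recognise_abbreviations(
    tokens: Sequence[Token],
    labels: Sequence[str],
    confidences: Sequence[float],
    mentions: Sequence[Mention],
) -> Tuple[List[str], List[float]]:
    """Apply abbreviation recognition within one token sequence.

    Document-global application across sections is handled by the
    recogniser, which pools candidates from all sections before
    relabelling each of them.
    """
    candidates = find_abbreviation_candidates(tokens, labels, mentions)
    if not candidates:
        return list(labels), list(confidences)
    return relabel_surfaces(tokens, labels, confidences, candidates)


def relabel_by_composition(
    tokens: Sequence[Token],
    labels: Sequence[str],
    confidences: Sequence[float],
    segment_dict: SegmentDictionary,
    config: RelabelConfig = RelabelConfig(),
) -> Tuple[List[str], List[float]]:
    """Relabel low-confidence O tokens whose segment composition is high.

    Strict comparisons throughout: confidence < t1 and ratio > t2.  The
    relabelled token's confidence becomes its composition ratio.
    """
    labels = list(labels)
    confidences = list(confidences)
    for i, tok in enumerate(tokens):
        if labels[i] != "O" or confidences[i] >= config.t1:
            continue
        ratio = composition_ratio(tok.surface, segment_dict)
        if ratio > config.t2:
            labels[i] = "B"
            confidences[i] = ratio
    return labels, confidences


def rank_cdi(mentions: Sequence[Mention]) -> List[Mention]:
    """Deduplicate mentions by exact surface string (keeping each string's
    maximum confidence) and rank by descending confidence, ties by string."""
    best = {}
    for m in mentions:
        if m.confidence is None:
            raise ValueError(f"mention {m.text!r} has no confidence; cannot rank")
        kept = best.get(m.text)
        if kept is None or m.confidence > kept.confidence:
            best[m.text] = m
    return sorted(best.values(), key=lambda m: (-m.confidence, m.text))
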