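"""Seed-reproducible synthetic corpora for training and evaluation.

Documents are built from template sentences whose slots are filled either
with generated chemical-like names (gold mentions, exact offsets) or with
non-chemical distractor nouns.  Names are assembled from the packaged
basic-segment fixture dictionary plus affix suffixes, so the knowledge-rich
features are informative by construction: every generated name has a
chemical segment composition ratio above 0.5.  Abbreviation patterns
``long name (ABBR)`` are emitted with short forms whose characters are a
subsequence of the long form, and the templates include acronym words
(ELISA, WHO, HPLC) that are never chemical, plus a Table-8-style
``{name}-induced`` frame that exercises the hyphen tokenisation rule.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .lexicons import load_affix_lists
from .segments import SegmentDictionary, composition_ratio, load_segment_dictionary
from .types import Document, Mention

__all__ = ["SynthConfig", "generate_name", "generate_abbreviation", "generate_corpus"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings (defaults are the package's study conditions)."""

    n_documents: int = 100
    names_per_doc: Tuple[int, int] = (2, 5)
    abbreviation_rate: float = 0.25
    distractor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        for name in ("abbreviation_rate", "distractor_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.names_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("names_per_doc must be a non-empty ascending range")


_DISTRACTORS = ("placebo", "saline", "buffer", "vehicle", "plasma", "serum", "lysate")

_TITLE_TEMPLATE = "Effects of {} on cell viability"

_ABSTRACT_TEMPLATES = (
    "It attenuated {}-induced gestation in rats.",
    "We tested {} and {} in cultured cells.",
    "Treatment with {} increased the yield markedly.",
    "Samples containing {} were analysed by ELISA.",
    "The compound {} inhibited growth according to WHO criteria.",
    "Exposure to {} reduced receptor binding in the HPLC assay.",
)

_ABBREV_TEMPLATE = "Administration of {} ({}) was evaluated, and {} levels rose rapidly."


def _default_suffixes() -> Tuple[str, ...]:
    affixes = load_affix_lists()
    return tuple(sorted(s for bucket in affixes.suffixes.values() for s in bucket))


class _NameGrammar:
    def __init__(self, segment_dict: Optional[SegmentDictionary] = None):
        self.segment_dict = segment_dict or load_segment_dictionary()
        self.segments = tuple(sorted(self.segment_dict.entries))
        self.suffixes = _default_suffixes()

    def name(self, rng: random.Random) -> Tuple[str, Tuple[str, ...]]:
        for _ in range(64):
            segs = tuple(rng.choice(self.segments) for _ in range(rng.randint(2, 5)))
            body = "".join(segs)
            if rng.random() < 0.3:
                body += rng.choice(self.suffixes)
            if rng.random() < 0.3:
                locant = str(rng.randint(1, 20))
                if rng.random() < 0.3:
                    locant += f",{rng.randint(1, 20)}"
                body = f"{locant}-{body}"
            if composition_ratio(body, self.segment_dict) > 0.5:
                return body, segs
        raise RuntimeError("name grammar failed to satisfy the composition bound")


def generate_name(rng: random.Random, segment_dict: Optional[SegmentDictionary] = None) -> str:
    """Draw one chemical-like name with composition ratio > 0.5."""
    return _NameGrammar(segment_dict).name(rng)[0]


def generate_abbreviation(segments: Sequence[str]) -> str:
    """Upper-case initials of the name's segments (a subsequence by
    construction)."""
    return "".join(s[0] for s in segments).upper()


def _render(template: str, fills: Sequence[Tuple[str, Optional[str]]]):
    """Fill ``{}`` slots; returns (text, [(start, end, text, subtype), ...])."""
    parts = template.split("{}")
    if len(parts) != len(fills) + 1:
        raise ValueError("template arity mismatch")
    text = parts[0]
    spans = []
    for (fill, subtype), part in zip(fills, parts[1:]):
        start = len(text)
        text += fill
        if subtype is not None:
            spans.append((start, len(text), fill, subtype))
        text += part
    return text, spans


def generate_corpus(cfg: SynthConfig) -> List[Document]:
    """Generate gold-annotated documents, deterministically per seed."""
    rng = random.Random(cfg.seed)
    grammar = _NameGrammar()
    docs: List[Document] = []
    for n in range(cfg.n_documents):
        doc_id = f"SYN{n:05d}"
        mentions: List[Mention] = []

        def slot_fill() -> Tuple[str, Optional[str]]:
            if rng.random() < cfg.distractor_rate:
                return rng.choice(_DISTRACTORS), None
            return grammar.name(rng)[0], "SYSTEMATIC"

        title, title_spans = _render(_TITLE_TEMPLATE, [slot_fill()])
        mentions.extend(
            Mention("T", s, e, t, subtype=st) for s, e, t, st in title_spans
        )

        sentences: List[Tuple[str, list]] = []
        budget = rng.randint(*cfg.names_per_doc)
        if rng.random() < cfg.abbreviation_rate:
            long_name, segs = grammar.name(rng)
            abbr = generate_abbreviation(segs)
            sentences.append(
                _render(
                    _ABBREV_TEMPLATE,
                    [
                        (long_name, "SYSTEMATIC"),
                        (abbr, "ABBREVIATION"),
                        (abbr, "ABBREVIATION"),
                    ],
                )
            )
            budget -= 1
        while budget > 0:
            template = rng.choice(_ABSTRACT_TEMPLATES)
            arity = template.count("{}")
            fills = [slot_fill() for _ in range(arity)]
            sentences.append(_render(template, fills))
            budget -= sum(1 for _, subtype in fills if subtype is not None) or 1

        abstract = ""
        for sent_text, spans in sentences:
            if abstract:
                abstract += " "
            base = len(abstract)
            abstract += sent_text
            mentions.extend(
                Mention("A", base + s, base + e, t, subtype=st)
                for s, e, t, st in spans
            )
        docs.append(Document(doc_id, title, abstract, mentions))
    for doc in docs:
        doc.validate_mentions()
    return docs
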