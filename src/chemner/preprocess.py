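"""Sentence splitting, chemistry-aware tokenisation and tag annotation.

Two rule-based splitters are provided: a *scientific* one that allows
sentences to begin with lower-case material (protein names such as p53)
and a *general* one that insists on an upper-case letter after a
boundary.  Two tokenisers are provided: a *chemistry* tokeniser that keeps
long systematic names (e.g. ``4,9-Diazadodecane-1,12-diamine``) intact as
single tokens while splitting a hyphen that joins a chemical-like prefix
to a plain English word (``GSK214a-induced`` -> ``GSK214a``, ``-induced``),
and a *general* tokeniser that splits at every punctuation character.

Lemma/POS/chunk annotation goes through a pluggable tagger: any callable
taking the list of token surfaces and returning three equal-length
sequences (lemmas, POS tags, chunk tags).  A deterministic rule-based
tagger is included as the default.
"""

from __future__ import annotations

import re
from typing import Callable, List, Sequence, Tuple

from .types import SentenceSpan, Token

TaggerFn = Callable[[Sequence[str]], Tuple[Sequence[str], Sequence[str], Sequence[str]]]

# Abbreviations whose trailing period never ends a sentence.
_ABBREVIATIONS = {"e.g.", "i.e.", "cf.", "vs.", "ca.", "al.", "fig.", "figs.", "approx.", "no."}

# Plain English words that, as the fragment after a hyphen, trigger a split
# so the chemical prefix stands alone (closed list; hyphen stays attached to
# the following fragment).
HYPHEN_SPLIT_WORDS = frozenset(
    {
        "induced",
        "treated",
        "mediated",
        "dependent",
        "based",
        "related",
        "associated",
        "containing",
        "coated",
        "stimulated",
        "derived",
        "activated",
        "free",
        "like",
        "specific",
        "positive",
        "negative",
    }
)

_BOUNDARY = re.compile(r"[.!?]+(\s+)")
_OPENERS = "([{"
_CLOSERS = ")]}"
_TRAILING = ".,;:!?\"'"


def split_sentences(text: str, mode: str = "scientific") -> List[SentenceSpan]:
    """Split section text into sentence spans (tokens left empty).

    ``scientific`` mode accepts any non-space character after a terminal
    punctuation + whitespace boundary; ``general`` mode requires an ASCII
    upper-case letter.
    """
    if mode not in ("scientific", "general"):
        raise ValueError(f"unknown splitter mode {mode!r}")
    if not text.strip():
        return []
    boundaries = [0]
    for match in _BOUNDARY.finditer(text):
        after = match.end()
        if after >= len(text):
            continue
        nxt = text[after]
        if mode == "general" and not ("A" <= nxt <= "Z"):
            continue
        # Do not break after known abbreviations ("e.g.", "et al.", ...).
        prefix = text[: match.end() - len(match.group(1))]
        last_word = prefix.rsplit(None, 1)[-1].lower() if prefix.split() else ""
        if last_word in _ABBREVIATIONS:
            continue
        boundaries.append(after)
    boundaries.append(len(text))
    spans: List[SentenceSpan] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        chunk = text[lo:hi]
        stripped = chunk.strip()
        if not stripped:
            continue
        start = lo + (len(chunk) - len(chunk.lstrip()))
        spans.append(SentenceSpan(start, start + len(stripped)))
    return spans


def _split_hyphen_word(core: str) -> List[str]:
    """Split ``core`` before hyphens that join it to a plain English word."""
    pieces: List[str] = []
    current = 0
    idx = 0
    while idx < len(core):
        if core[idx] == "-":
            match = re.match(r"-([A-Za-z]+)", core[idx:])
            if match and match.group(1).lower() in HYPHEN_SPLIT_WORDS:
                after = idx + len(match.group(0))
                if after == len(core) or core[after] in "-.,;:":
                    if idx > current:
                        pieces.append(core[current:idx])
                    current = idx
        idx += 1
    pieces.append(core[current:])
    return [p for p in pieces if p]


def _tokenise_chunk_chemistry(chunk: str, offset: int) -> List[Token]:
    tokens: List[Token] = []
    lo, hi = 0, len(chunk)
    leading: List[Tuple[str, int]] = []
    trailing: List[Tuple[str, int]] = []
    while lo < hi and chunk[lo] in _OPENERS + "\"'":
        leading.append((chunk[lo], lo))
        lo += 1
    while hi > lo:
        c = chunk[hi - 1]
        if c in _TRAILING:
            trailing.append((c, hi - 1))
            hi -= 1
        elif c in _CLOSERS:
            # Peel a closing bracket only when unbalanced within the chunk,
            # so "In(0.2)Ga(0.8)As"-style internals survive.
            rest = chunk[lo:hi]
            opener = _OPENERS[_CLOSERS.index(c)]
            if rest.count(opener) < rest.count(c):
                trailing.append((c, hi - 1))
                hi -= 1
            else:
                break
        else:
            break
    for ch, pos in leading:
        tokens.append(Token(ch, offset + pos, offset + pos + 1))
    core = chunk[lo:hi]
    if core:
        pos = lo
        for piece in _split_hyphen_word(core):
            tokens.append(Token(piece, offset + pos, offset + pos + len(piece)))
            pos += len(piece)
    for ch, pos in reversed(trailing):
        tokens.append(Token(ch, offset + pos, offset + pos + 1))
    return tokens


_GENERAL_TOKEN = re.compile(r"[A-Za-z0-9]+|[^A-Za-z0-9\s]")


def tokenise(text: str, mode: str = "chemistry", offset: int = 0) -> List[Token]:
    """Tokenise sentence text, producing tokens with absolute offsets.

    ``offset`` is the sentence's start position in section coordinates.
    """
    if mode == "general":
        return [
            Token(m.group(0), offset + m.start(), offset + m.end())
            for m in _GENERAL_TOKEN.finditer(text)
        ]
    if mode != "chemistry":
        raise ValueError(f"unknown tokeniser mode {mode!r}")
    tokens: List[Token] = []
    for match in re.finditer(r"\S+", text):
        tokens.extend(_tokenise_chunk_chemistry(match.group(0), offset + match.start()))
    return tokens


def tag_tokens(tokens: Sequence[Token], tagger: TaggerFn = None) -> List[Token]:
    """Attach lemma/POS/chunk annotations from a pluggable tagger."""
    if tagger is None:
        tagger = RuleTagger()
    surfaces = [t.surface for t in tokens]
    lemmas, pos_tags, chunks = tagger(surfaces)
    if not (len(lemmas) == len(pos_tags) == len(chunks) == len(tokens)):
        raise ValueError(
            f"tagger returned {len(lemmas)}/{len(pos_tags)}/{len(chunks)} "
            f"annotations for {len(tokens)} tokens"
        )
    return [t.tagged(l, p, c) for t, l, p, c in zip(tokens, lemmas, pos_tags, chunks)]


def preprocess_section(
    text: str,
    splitter: str = "scientific",
    tokeniser: str = "chemistry",
    tagger: TaggerFn = None,
) -> List[SentenceSpan]:
    """Full pre-processing pipeline for one section: split, tokenise, tag."""
    sentences = split_sentences(text, mode=splitter)
    out: List[SentenceSpan] = []
    for sent in sentences:
        tokens = tokenise(text[sent.start : sent.end], mode=tokeniser, offset=sent.start)
        out.append(SentenceSpan(sent.start, sent.end, tag_tokens(tokens, tagger)))
    return out


# ---------------------------------------------------------------------------
# Deterministic rule-based fallback tagger


_PRONOUNS = {"it", "he", "she", "they", "we", "i", "you", "this", "that"}
_DETERMINERS = {"the", "a", "an", "these", "those", "each", "every", "its"}
_PREPOSITIONS = {
    "in", "on", "of", "with", "for", "at", "by", "from", "to", "into",
    "against", "after", "before", "during", "under", "via", "per",
}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_NP_POS = {"NN", "NNS", "NNP", "PRP", "DT", "JJ", "CD"}


class RuleTagger:
    """Suffix-rule POS tagger, rule lemmatiser and regex-style chunker.

    Deterministic and dependency-free; a learned tagger can be substituted
    through the same callable interface.
    """

    def __call__(self, surfaces: Sequence[str]):
        pos = [self._pos(s) for s in surfaces]
        lemmas = [self._lemma(s, p) for s, p in zip(surfaces, pos)]
        chunks = self._chunk(pos)
        return lemmas, pos, chunks

    @staticmethod
    def _pos(surface: str) -> str:
        if not any(c.isalnum() for c in surface):
            return surface if len(surface) == 1 else "SYM"
        low = surface.lower()
        if surface.startswith("-"):
            return "JJ"
        if low in _PRONOUNS:
            return "PRP" if low not in ("this", "that") else "DT"
        if low in _DETERMINERS:
            return "DT"
        if low in _PREPOSITIONS:
            return "IN"
        if low in _CONJUNCTIONS:
            return "CC"
        if low.isdigit():
            return "CD"
        if low.endswith("ing") and len(low) > 4:
            return "VBG"
        if low.endswith("ed") and len(low) > 3:
            return "VBD"
        if low.endswith("ly") and len(low) > 3:
            return "RB"
        if any(c.isdigit() for c in surface) or any(c.isupper() for c in surface[1:]):
            return "NN"
        if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
            return "NNS"
        return "NN"

    @staticmethod
    def _lemma(surface: str, pos: str) -> str:
        if not any(c.isalnum() for c in surface) or surface.startswith("-"):
            return surface
        if pos == "NNS":
            if surface.lower().endswith("ies") and len(surface) > 4:
                return surface[:-3] + "y"
            return surface[:-1]
        if pos == "VBD" and surface.lower().endswith("ed"):
            return surface[:-1]
        return surface

    @staticmethod
    def _chunk(pos_tags: Sequence[str]) -> List[str]:
        chunks: List[str] = []
        prev = None
        for tag in pos_tags:
            if tag in _NP_POS:
                kind = "NP"
            elif tag.startswith("VB"):
                kind = "VP"
            elif tag == "IN":
                kind = "PP"
            else:
                kind = None
            if kind is None:
                chunks.append("O")
            elif kind == prev:
                chunks.append(f"I-{kind}")
            else:
                chunks.append(f"B-{kind}")
            prev = kind
        return chunks


class ReplayTagger:
    """Tagger that replays a fixed surface -> (lemma, pos, chunk) table.

    Used to inject reference annotations (e.g. from an external tagger's
    printed output) into the pipeline; unseen surfaces fall back to the
    rule tagger.
    """

    def __init__(self, table):
        self.table = dict(table)
        self._fallback = RuleTagger()

    def __call__(self, surfaces: Sequence[str]):
        lemmas, pos, chunks = [], [], []
        fb = None
        for i, s in enumerate(surfaces):
            if s in self.table:
                l, p, c = self.table[s]
            else:
                if fb is None:
                    fb = self._fallback(surfaces)
                l, p, c = fb[0][i], fb[1][i], fb[2][i]
            lemmas.append(l)
            pos.append(p)
            chunks.append(c)
        return lemmas, pos, chunks
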