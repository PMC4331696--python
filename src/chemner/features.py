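"""Per-token feature extraction for the CRF sequence labeller.

The *default* set captures weakly chemical-indicative signal: character
n-grams (n = 2, 3, 4) of the active token, surface/normalised/lemma/POS
unigrams and bigrams within a distance of two, chunk information, and 21
orthographic flags.  The *knowledge-rich* set adds features derived from
chemical resources: a Greek-character flag, full and brief word shapes,
dictionary-match features from compiled lexicons, chemical prefix/suffix
matches, a bucketed basic-segment count and a periodic-table symbol flag.

All features are categorical presence features (namespaced strings); the
extraction is a pure function of the sentence, the resources and the
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .lexicons import (
    AffixLists,
    CompiledLexicon,
    lexicon_features,
    match_affixes,
    normalise,
    tag_lexicon,
)
from .segments import SegmentDictionary, count_segments
from .types import Token

GREEK_LETTER_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
)

WINDOW = 2  # context distance is fixed at two tokens either side
NGRAM_SIZES = (2, 3, 4)
SEGMENT_COUNT_CAP = 5  # buckets 0..4 and ">=5"


def char_ngrams(token: str, n: int) -> Set[str]:
    """All contiguous substrings of length ``n`` (as a set)."""
    return {token[i : i + n] for i in range(len(token) - n + 1)}


def _is_upper(c: str) -> bool:
    return "A" <= c <= "Z"


def _is_lower(c: str) -> bool:
    return "a" <= c <= "z"


def _is_digit(c: str) -> bool:
    return "0" <= c <= "9"


def _shape_char(c: str) -> str:
    if _is_digit(c):
        return "0"
    if _is_upper(c):
        return "A"
    if _is_lower(c):
        return "a"
    return "_"


def word_shape(token: str) -> Tuple[str, str]:
    """Full and brief word shapes (digits->0, upper->A, lower->a, other->_);
    the brief variant collapses runs of identical shape characters."""
    full = "".join(_shape_char(c) for c in token)
    brief = []
    for c in full:
        if not brief or brief[-1] != c:
            brief.append(c)
    return full, "".join(brief)


def contains_greek_char(token: str) -> bool:
    """True if any character is in the Unicode Greek blocks."""
    return any("Ͱ" <= c <= "Ͽ" or "ἀ" <= c <= "῿" for c in token)


def orthographic_features(token: str) -> Set[str]:
    """The 21 default orthographic boolean flags (emitted when true)."""
    if not token:
        return set()
    feats: Set[str] = set()
    chars = list(token)
    low = token.lower()

    def flag(name: str, cond: bool) -> None:
        if cond:
            feats.add(f"orth:{name}")

    flag("init_upper", _is_upper(chars[0]))
    flag("all_digits", all(_is_digit(c) for c in chars))
    flag("has_digit", any(_is_digit(c) for c in chars))
    flag("all_alnum", all(_is_digit(c) or _is_upper(c) or _is_lower(c) for c in chars))
    flag("upper_digits", all(_is_digit(c) or _is_upper(c) for c in chars))
    flag("all_upper", all(_is_upper(c) for c in chars))
    flag("no_lower", not any(_is_lower(c) for c in chars))
    flag("noninit_upper", any(_is_upper(c) for c in chars[1:]))
    flag("two_upper", any(_is_upper(a) and _is_upper(b) for a, b in zip(chars, chars[1:])))
    flag("greek_name", any(name in low for name in GREEK_LETTER_NAMES))
    flag("comma", "," in token)
    flag("period", "." in token)
    flag("hyphen", "-" in token)
    flag("slash", "/" in token)
    flag("lsquare", "[" in token)
    flag("rsquare", "]" in token)
    flag("lparen", "(" in token)
    flag("rparen", ")" in token)
    flag("semicolon", ";" in token)
    flag("percent", "%" in token)
    flag("apostrophe", "'" in token)
    return feats


_ADJACENT_OFFSETS = tuple((o, o + 1) for o in range(-WINDOW, WINDOW))


def context_ngrams(tokens: Sequence[Token], index: int) -> Set[str]:
    """Surface/normalised/lemma/POS unigram and bigram context features
    within a distance of two, plus chunk information for the active token."""
    n = len(tokens)
    feats: Set[str] = set()

    def attrs(j: int):
        t = tokens[j]
        return {
            "w": t.surface,
            "wn": word_shape(t.surface)[0],
            "l": t.lemma,
            "p": t.pos,
            "lp": f"{t.lemma}:{t.pos}",
        }

    for off in range(-WINDOW, WINDOW + 1):
        j = index + off
        if 0 <= j < n:
            for key, value in attrs(j).items():
                feats.add(f"{key}{off}={value}")
    for o1, o2 in _ADJACENT_OFFSETS:
        a, b = index + o1, index + o2
        if 0 <= a and b < n:
            left, right = attrs(a), attrs(b)
            for key in ("w", "wn", "l", "p", "lp"):
                feats.add(f"{key}b{o1}={left[key]}|{right[key]}")

    chunk = tokens[index].chunk
    feats.add(f"chk={chunk or 'O'}")
    feats.add(f"chkend={tokens[_chunk_end(tokens, index)].surface}")
    return feats


def _chunk_end(tokens: Sequence[Token], index: int) -> int:
    """Index of the final token of the chunk enclosing ``index``."""
    tag = tokens[index].chunk
    if not tag or tag == "O" or "-" not in tag:
        return index
    kind = tag.split("-", 1)[1]
    j = index
    while j + 1 < len(tokens) and tokens[j + 1].chunk == f"I-{kind}":
        j += 1
    return j


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction switches; the context window is fixed at two."""

    knowledge_rich: bool = True
    window: int = WINDOW
    ngram_sizes: Tuple[int, ...] = NGRAM_SIZES

    def __post_init__(self) -> None:
        if self.window != WINDOW:
            raise ValueError("context window is fixed at 2")


@dataclass
class Resources:
    """Chemical knowledge resources backing the enriched feature set."""

    lexicons: Tuple[CompiledLexicon, ...] = ()
    affixes: Optional[AffixLists] = None
    elements: Optional[FrozenSet[str]] = None
    segment_dict: Optional[SegmentDictionary] = None


class FeatureExtractor:
    """Assembles per-token feature sets for whole sentences.

    Dictionary tagging operates on normalised lemmas, computed once per
    sentence and shared across tokens.
    """

    def __init__(self, config: FeatureConfig = None, resources: Resources = None):
        self.config = config or FeatureConfig()
        self.resources = resources or Resources()
        if self.config.knowledge_rich:
            missing = [
                name
                for name, value in (
                    ("affixes", self.resources.affixes),
                    ("elements", self.resources.elements),
                    ("segment_dict", self.resources.segment_dict),
                )
                if value is None
            ]
            if missing:
                raise ValueError(
                    "knowledge-rich features require resources: " + ", ".join(missing)
                )

    def sentence_features(self, tokens: Sequence[Token]) -> List[Set[str]]:
        if not tokens:
            return []
        lexicon_labels: Dict[str, List[str]] = {}
        if self.config.knowledge_rich and self.resources.lexicons:
            norm = [normalise(t.lemma or t.surface) for t in tokens]
            for lex in self.resources.lexicons:
                lexicon_labels[lex.name] = tag_lexicon(norm, lex)
        return [
            self._token_features(tokens, i, lexicon_labels) for i in range(len(tokens))
        ]

    def _token_features(
        self,
        tokens: Sequence[Token],
        index: int,
        lexicon_labels: Dict[str, List[str]],
    ) -> Set[str]:
        token = tokens[index]
        feats: Set[str] = {"bias"}
        for n in self.config.ngram_sizes:
            feats.update(f"c{n}={g}" for g in char_ngrams(token.surface, n))
        feats.update(context_ngrams(tokens, index))
        feats.update(orthographic_features(token.surface))
        if not self.config.knowledge_rich:
            return feats

        if contains_greek_char(token.surface):
            feats.add("orth:greek_char")
        full, brief = word_shape(token.surface)
        feats.add(f"shp={full}")
        feats.add(f"shpb={brief}")
        surfaces = [t.surface for t in tokens]
        for name, labels in lexicon_labels.items():
            feats.update(
                lexicon_features(labels, surfaces, index, prefix=f"dict{name}")
            )
        for (side, size), affix in match_affixes(token.surface, self.resources.affixes).items():
            if affix is not None:
                feats.add(f"{'pre' if side == 'prefix' else 'suf'}{size}={affix}")
        count = count_segments(token.surface, self.resources.segment_dict)
        bucket = f">={SEGMENT_COUNT_CAP}" if count >= SEGMENT_COUNT_CAP else str(count)
        feats.add(f"nseg={bucket}")
        if token.surface in self.resources.elements:
            feats.add("elem")
        return feats


def assemble(
    tokens: Sequence[Token],
    index: int,
    config: FeatureConfig = None,
    resources: Resources = None,
) -> Set[str]:
    """Feature vector for one token (convenience over FeatureExtractor)."""
    extractor = FeatureExtractor(config, resources)
    return extractor.sentence_features(tokens)[index]
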