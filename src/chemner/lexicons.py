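"""Dictionary compilation, longest-match BIO tagging, affixes and elements.

Dictionary entries and input tokens are normalised before matching:
letters are lower-cased, digits become ``0`` and every other character
becomes ``_``.  Matching is greedy leftmost-longest over normalised token
sequences and the result is encoded as a per-token B/I/O label sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _ilr
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

AFFIX_SIZES = (2, 3, 4)


def normalise(form: str) -> str:
    """Normalise a surface/lemma form: a-z kept, A-Z lowered, digits -> '0',
    everything else -> '_'.  Length-preserving and idempotent."""
    out = []
    for c in form:
        if c.isdigit():
            out.append("0")
        elif c.isalpha():
            low = c.lower()
            out.append(low if len(low) == 1 else "_")
        else:
            out.append("_")
    return "".join(out)


class CompiledLexicon:
    """A named dictionary of normalised multi-token entries."""

    def __init__(self, name: str, entries: Iterable):
        self.name = name
        compiled: Set[Tuple[str, ...]] = set()
        for entry in entries:
            parts = entry.split() if isinstance(entry, str) else list(entry)
            norm = tuple(normalise(p) for p in parts if p)
            if not norm or any(not t for t in norm):
                raise ValueError(f"empty entry in lexicon {name!r}")
            compiled.add(norm)
        self.entries: FrozenSet[Tuple[str, ...]] = frozenset(compiled)
        self.max_len = max((len(e) for e in compiled), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, item) -> bool:
        return tuple(item) in self.entries

    @classmethod
    def from_file(cls, name: str, path) -> "CompiledLexicon":
        with open(path, encoding="utf-8") as fh:
            entries = [line.strip() for line in fh if line.strip()]
        return cls(name, entries)


def tag_lexicon(norm_tokens: Sequence[str], lexicon: CompiledLexicon) -> List[str]:
    """Greedy leftmost-longest BIO tagging of a normalised token sequence."""
    n = len(norm_tokens)
    labels = ["O"] * n
    i = 0
    while i < n:
        best = 0
        upper = min(lexicon.max_len, n - i)
        for length in range(upper, 0, -1):
            if tuple(norm_tokens[i : i + length]) in lexicon.entries:
                best = length
                break
        if best:
            labels[i] = "B"
            for j in range(i + 1, i + best):
                labels[j] = "I"
            i += best
        else:
            i += 1
    return labels


def lexicon_features(
    labels: Sequence[str],
    surfaces: Sequence[str],
    index: int,
    window: int = 2,
    prefix: str = "dict",
) -> Set[str]:
    """Dictionary-match features for the token at ``index``.

    Emits label unigrams/bigrams and surface:label unigrams/bigrams for
    offsets within ``window`` of the active token.
    """
    if len(labels) != len(surfaces):
        raise ValueError("labels and surfaces must be aligned")
    n = len(labels)
    feats: Set[str] = set()
    for off in range(-window, window + 1):
        j = index + off
        if 0 <= j < n:
            feats.add(f"{prefix}U{off}={labels[j]}")
            feats.add(f"{prefix}WU{off}={surfaces[j]}:{labels[j]}")
    for off in range(-window, window):
        a, b = index + off, index + off + 1
        if 0 <= a and b < n:
            feats.add(f"{prefix}B{off}={labels[a]}|{labels[b]}")
            feats.add(f"{prefix}WB{off}={surfaces[a]}:{labels[a]}|{surfaces[b]}:{labels[b]}")
    return feats


@dataclass(frozen=True)
class AffixLists:
    """Chemical prefix/suffix lists partitioned by length (2, 3, 4)."""

    prefixes: Dict[int, FrozenSet[str]]
    suffixes: Dict[int, FrozenSet[str]]

    @classmethod
    def from_iterables(cls, prefixes: Iterable[str], suffixes: Iterable[str]) -> "AffixLists":
        def partition(items):
            buckets = {size: set() for size in AFFIX_SIZES}
            for item in items:
                affix = item.strip().lower()
                if not affix:
                    continue
                if len(affix) not in AFFIX_SIZES:
                    raise ValueError(
                        f"affix {affix!r} has length {len(affix)}; expected 2-4"
                    )
                buckets[len(affix)].add(affix)
            return {size: frozenset(v) for size, v in buckets.items()}

        return cls(partition(prefixes), partition(suffixes))

    @classmethod
    def from_files(cls, prefix_path, suffix_path) -> "AffixLists":
        def read(path):
            with open(path, encoding="utf-8") as fh:
                return [line.strip() for line in fh if line.strip()]

        return cls.from_iterables(read(prefix_path), read(suffix_path))


def match_affixes(token: str, lists: AffixLists) -> Dict[Tuple[str, int], Optional[str]]:
    """Match the token's boundary substrings against the affix lists.

    Returns a map from (side, size) to the matched affix or None; matching
    is case-insensitive and a slot requires the token to be at least
    ``size`` characters long.
    """
    if not token:
        raise ValueError("token must be non-empty")
    low = token.lower()
    out: Dict[Tuple[str, int], Optional[str]] = {}
    for size in AFFIX_SIZES:
        pre = low[:size] if len(low) >= size else None
        suf = low[-size:] if len(low) >= size else None
        out[("prefix", size)] = pre if pre in lists.prefixes[size] else None
        out[("suffix", size)] = suf if suf in lists.suffixes[size] else None
    return out


def _read_resource_lines(filename: str) -> List[str]:
    text = _ilr.files("chemner.resources").joinpath(filename).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def load_affix_lists(prefix_path=None, suffix_path=None) -> AffixLists:
    """Load affix lists from files, or the packaged fixture lists."""
    if prefix_path is None and suffix_path is None:
        return AffixLists.from_iterables(
            _read_resource_lines("prefixes.txt"), _read_resource_lines("suffixes.txt")
        )
    return AffixLists.from_files(prefix_path, suffix_path)


def load_element_symbols(path=None) -> FrozenSet[str]:
    """Load the periodic-table symbol list (packaged 118-symbol default)."""
    if path is None:
        return frozenset(_read_resource_lines("elements.txt"))
    with open(path, encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def match_element_symbol(token: str, symbols: Optional[FrozenSet[str]] = None) -> bool:
    """Exact, case-sensitive membership in the element symbol list."""
    if symbols is None:
        symbols = load_element_symbols()
    return token in symbols
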