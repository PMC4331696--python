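"""BIO encoding of gold mentions and decoding of label sequences.

Encoding assigns ``B`` to the first token overlapping a mention, ``I`` to
subsequent overlapping tokens and ``O`` elsewhere.  A gold boundary that
falls inside a token expands to the whole token with a warning, since
token splitting would change the feature space.  Decoding inverts this:
every maximal ``B I*`` run becomes a mention spanning the first token's
start to the last token's end, with the mention confidence taken as the
minimum of its member-token confidences.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence

from .types import Mention, Token

__all__ = ["encode_bio", "decode_mentions", "is_valid_bio", "check_bio"]


def is_valid_bio(labels: Sequence[str]) -> bool:
    """True iff no ``I`` opens the sequence or follows an ``O``."""
    prev = "O"
    for lab in labels:
        if lab not in ("B", "I", "O"):
            return False
        if lab == "I" and prev == "O":
            return False
        prev = lab
    return True


def check_bio(labels: Sequence[str]) -> None:
    if not is_valid_bio(labels):
        raise ValueError(f"invalid BIO sequence: {list(labels)}")


def encode_bio(tokens: Sequence[Token], mentions: Sequence[Mention]) -> List[str]:
    """Project gold mentions onto tokens as B/I/O labels.

    Raises on overlapping gold mentions; warns when a mention boundary
    falls strictly inside a token.
    """
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping gold mentions: {a.text!r}@{a.start} and {b.text!r}@{b.start}"
            )
    labels = ["O"] * len(tokens)
    for m in ordered:
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < m.end and tok.end > m.start:
                if tok.start < m.start or tok.end > m.end:
                    warnings.warn(
                        f"mention boundary inside token {tok.surface!r} "
                        f"(mention {m.text!r}); labelling the whole token",
                        stacklevel=2,
                    )
                labels[i] = "B" if first else "I"
                first = False
    return labels


def decode_mentions(
    labels: Sequence[str],
    tokens: Sequence[Token],
    section: str,
    section_text: str,
    confidences: Optional[Sequence[float]] = None,
) -> List[Mention]:
    """Convert a valid BIO sequence back into mentions."""
    if len(labels) != len(tokens):
        raise ValueError("labels and tokens must be aligned")
    check_bio(labels)
    mentions: List[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        if labels[i] != "B":
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == "I":
            j += 1
        start, end = tokens[i].start, tokens[j].end
        conf = None
        if confidences is not None:
            conf = float(min(confidences[i : j + 1]))
        mentions.append(
            Mention(section, start, end, section_text[start:end], confidence=conf)
        )
        i = j + 1
    return mentions
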