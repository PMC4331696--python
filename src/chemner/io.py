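"""Readers and writers for CHEMDNER-style corpora and prediction files.

Formats
-------
Abstracts TSV
    ``doc_id <TAB> title <TAB> abstract`` — one document per line.
Annotations TSV
    ``doc_id <TAB> T|A <TAB> start <TAB> end <TAB> text <TAB> subtype``.
CEM predictions TSV
    ``doc_id <TAB> S:start:end <TAB> rank <TAB> confidence`` where ``S`` is
    ``T`` or ``A``; ranks are 1-based per document in descending confidence,
    ties broken by ``(section, start, end)``.
CDI predictions TSV
    ``doc_id <TAB> text <TAB> rank <TAB> confidence``.
CoNLL-BIO
    One token per line (``surface lemma pos chunk label``, tab-separated),
    blank line between sentences.

All files are UTF-8 without BOM; confidences are serialised with six
decimal places so output is byte-stable.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

from .types import SUBTYPES, CorpusError, Document, Mention, Token

BIO_LABELS = ("B", "I", "O")


def read_abstracts(path) -> List[Document]:
    """Read a CHEMDNER-style abstracts TSV into mention-less documents."""
    docs: List[Document] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise CorpusError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, title, abstract = fields
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(docs: Sequence[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def _parse_subtype(value: str) -> str:
    value = value.strip().upper().replace(" ", "_")
    if value in ("", "UNTYPED"):
        return None
    if value not in SUBTYPES:
        raise CorpusError(f"unknown mention subtype {value!r}")
    return value


def read_annotations(path, docs: Sequence[Document]) -> List[Document]:
    """Attach gold annotations to ``docs``, verifying text/offset agreement."""
    by_id: Dict[str, Document] = {d.doc_id: d for d in docs}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CorpusError(
                    f"{path}: line {lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            doc_id, section, start_s, end_s, text, subtype = fields
            if doc_id not in by_id:
                raise CorpusError(f"{path}: line {lineno}: unknown doc_id {doc_id!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusError(f"{path}: line {lineno}: non-integer offsets") from exc
            doc = by_id[doc_id]
            mention = Mention(section, start, end, text, subtype=_parse_subtype(subtype))
            section_text = doc.section_text(section)
            found = section_text[start:end]
            if found != text:
                raise CorpusError(
                    f"{path}: line {lineno}: text mismatch at {doc_id}/{section}:"
                    f"{start}:{end}: expected {text!r}, found {found!r}"
                )
            doc.mentions.append(mention)
    return list(docs)


def read_corpus(abstracts_path, annotations_path=None) -> List[Document]:
    docs = read_abstracts(abstracts_path)
    if annotations_path is not None:
        read_annotations(annotations_path, docs)
    return docs


def write_annotations(docs: Sequence[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            for m in d.mentions:
                subtype = m.subtype if m.subtype is not None else "UNTYPED"
                fh.write(f"{d.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t{subtype}\n")


def _ranked(mentions: Iterable[Mention]) -> List[Tuple[int, Mention]]:
    for m in mentions:
        if m.confidence is None:
            raise ValueError(f"mention {m.text!r} has no confidence; cannot rank")
    ordered = sorted(mentions, key=lambda m: (-m.confidence, m.section, m.start, m.end))
    return list(enumerate(ordered, start=1))


def write_cem_predictions(docs: Sequence[Document], path) -> None:
    """Write mention-level (CEM) predictions with per-document ranks."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            for rank, m in _ranked(d.mentions):
                fh.write(
                    f"{d.doc_id}\t{m.section}:{m.start}:{m.end}\t{rank}\t{m.confidence:.6f}\n"
                )


def read_cem_predictions(path) -> List[Tuple[str, str, int, int, int, float]]:
    """Parse a CEM prediction file into (doc_id, section, start, end, rank, conf)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusError(f"{path}: line {lineno}: expected 4 fields")
            doc_id, loc, rank_s, conf_s = fields
            try:
                section, start_s, end_s = loc.split(":")
                rows.append(
                    (doc_id, section, int(start_s), int(end_s), int(rank_s), float(conf_s))
                )
            except ValueError as exc:
                raise CorpusError(f"{path}: line {lineno}: malformed fields") from exc
    return rows


def write_cdi_predictions(ranked: Dict[str, List[Mention]], path) -> None:
    """Write ranked unique-mention (CDI) lists, one line per (doc, string)."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, mentions in ranked.items():
            for rank, m in enumerate(mentions, start=1):
                if m.confidence is None:
                    raise ValueError(f"mention {m.text!r} has no confidence; cannot rank")
                fh.write(f"{doc_id}\t{m.text}\t{rank}\t{m.confidence:.6f}\n")


def read_cdi_predictions(path) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusError(f"{path}: line {lineno}: expected 4 fields")
            out.setdefault(fields[0], []).append(fields[1])
    return out


# ---------------------------------------------------------------------------
# CoNLL-style BIO column files


def write_conll_bio(sentences: Sequence[Tuple[Sequence[Token], Sequence[str]]], path) -> None:
    """Write (tokens, labels) sentences as a 5-column CoNLL-style file."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, labels in sentences:
            if len(tokens) != len(labels):
                raise ValueError("token/label length mismatch")
            for tok, label in zip(tokens, labels):
                if label not in BIO_LABELS:
                    raise ValueError(f"invalid BIO label {label!r}")
                fh.write(f"{tok.surface}\t{tok.lemma}\t{tok.pos}\t{tok.chunk}\t{label}\n")
            fh.write("\n")


def read_conll_bio(path) -> List[Tuple[List[Token], List[str]]]:
    """Read a CoNLL-style BIO file.

    Offsets are reconstructed by laying the surfaces out with single-space
    gaps, since the column format does not record character positions.
    """
    sentences: List[Tuple[List[Token], List[str]]] = []
    tokens: List[Token] = []
    labels: List[str] = []
    cursor = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                if tokens:
                    sentences.append((tokens, labels))
                tokens, labels, cursor = [], [], 0
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise CorpusError(f"{path}: line {lineno}: expected 5 columns")
            surface, lemma, pos, chunk, label = fields
            if label not in BIO_LABELS:
                raise CorpusError(f"{path}: line {lineno}: invalid BIO label {label!r}")
            tokens.append(Token(surface, cursor, cursor + len(surface), lemma, pos, chunk))
            labels.append(label)
            cursor += len(surface) + 1
    if tokens:
        sentences.append((tokens, labels))
    return sentences
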