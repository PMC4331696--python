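"""Mention-level (CEM) and document-indexing (CDI) evaluation.

Precision ``P = TP/(TP+FP)``, recall ``R = TP/(TP+FN)`` and
``F1 = 2PR/(P+R)``, with ``0/0`` defined as 0.  Micro averaging pools
TP/FP/FN counts over all documents; macro averaging takes the mean of
per-document metrics (documents with neither gold nor predicted mentions
are excluded from the macro mean).  CEM matching is strict-span and
type-agnostic; CDI matching is exact unique-string per document.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from .types import Document

__all__ = [
    "EvalReport",
    "evaluate_cem",
    "evaluate_cdi",
    "fn_breakdown",
    "breakdown_percentages",
    "token_level_counts",
]


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass(frozen=True)
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    scope: str  # micro | macro
    mode: str  # CEM | CDI

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "scope": self.scope,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        head = "mode\tscope\ttp\tfp\tfn\tprecision\trecall\tf1"
        row = (
            f"{self.mode}\t{self.scope}\t{self.tp}\t{self.fp}\t{self.fn}"
            f"\t{self.precision:.4f}\t{self.recall:.4f}\t{self.f1:.4f}"
        )
        return f"{head}\n{row}\n"


def _per_document_counts_cem(gold: Document, pred: Document) -> Tuple[int, int, int]:
    gold_spans = {m.span for m in gold.mentions}
    pred_spans = [m.span for m in pred.mentions]
    dupes = [s for s, k in Counter(pred_spans).items() if k > 1]
    if dupes:
        raise ValueError(f"{pred.doc_id}: duplicate predictions for spans {dupes}")
    pred_set = set(pred_spans)
    tp = len(gold_spans & pred_set)
    return tp, len(pred_set) - tp, len(gold_spans) - tp


def _aggregate(counts: List[Tuple[int, int, int]], scope: str, mode: str) -> EvalReport:
    tp = sum(c[0] for c in counts)
    fp = sum(c[1] for c in counts)
    fn = sum(c[2] for c in counts)
    if scope == "micro":
        p, r, f1 = _prf(tp, fp, fn)
    elif scope == "macro":
        per_doc = [_prf(*c) for c in counts if sum(c) > 0]
        if per_doc:
            p = sum(x[0] for x in per_doc) / len(per_doc)
            r = sum(x[1] for x in per_doc) / len(per_doc)
            f1 = sum(x[2] for x in per_doc) / len(per_doc)
        else:
            p = r = f1 = 0.0
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return EvalReport(tp, fp, fn, p, r, f1, scope, mode)


def _paired(gold_docs: Sequence[Document], pred_docs: Sequence[Document]):
    pred_by_id = {d.doc_id: d for d in pred_docs}
    missing = [d.doc_id for d in gold_docs if d.doc_id not in pred_by_id]
    unknown = set(pred_by_id) - {d.doc_id for d in gold_docs}
    if missing or unknown:
        raise ValueError(
            f"document ids do not align (missing={missing[:3]}, unknown={sorted(unknown)[:3]})"
        )
    return [(g, pred_by_id[g.doc_id]) for g in gold_docs]


def evaluate_cem(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    scope: str = "micro",
) -> EvalReport:
    """Strict-span mention-level evaluation."""
    counts = [_per_document_counts_cem(g, p) for g, p in _paired(gold_docs, pred_docs)]
    return _aggregate(counts, scope, "CEM")


def evaluate_cdi(
    gold_docs: Sequence[Document],
    predictions: Mapping[str, Sequence[str]],
    scope: str = "micro",
) -> EvalReport:
    """Unique-mention-string evaluation against per-document ranked lists."""
    counts = []
    for gold in gold_docs:
        pred_list = list(predictions.get(gold.doc_id, []))
        dupes = [s for s, k in Counter(pred_list).items() if k > 1]
        if dupes:
            raise ValueError(f"{gold.doc_id}: duplicate strings in ranked list: {dupes}")
        gold_strings = {m.text for m in gold.mentions}
        pred_strings = set(pred_list)
        tp = len(gold_strings & pred_strings)
        counts.append((tp, len(pred_strings) - tp, len(gold_strings) - tp))
    return _aggregate(counts, scope, "CDI")


def fn_breakdown(
    gold_docs: Sequence[Document], pred_docs: Sequence[Document]
) -> Dict[str, Tuple[int, float]]:
    """False negatives grouped by gold mention subtype.

    Returns subtype -> (count, percentage of all FN, 2 dp), ordered by
    descending count.
    """
    counts: Counter = Counter()
    for gold, pred in _paired(gold_docs, pred_docs):
        pred_spans = {m.span for m in pred.mentions}
        for m in gold.mentions:
            if m.span not in pred_spans:
                counts[m.subtype if m.subtype is not None else "UNTYPED"] += 1
    percentages = breakdown_percentages(counts)
    return {
        subtype: (count, percentages[subtype])
        for subtype, count in counts.most_common()
    }


def breakdown_percentages(counts: Mapping[str, int]) -> Dict[str, float]:
    """Percentages (2 dp) of each category's share of the total count."""
    total = sum(counts.values())
    if total == 0:
        return {}
    return {key: round(100.0 * value / total, 2) for key, value in counts.items()}


def token_level_counts(
    gold_labels: Sequence[Sequence[str]], pred_labels: Sequence[Sequence[str]]
) -> Tuple[int, int, int]:
    """Token-level (tp, fp, fn) where 'chemical' means a non-O label."""
    tp = fp = fn = 0
    for gold, pred in zip(gold_labels, pred_labels):
        if len(gold) != len(pred):
            raise ValueError("label sequences must be aligned")
        for g, p in zip(gold, pred):
            g_chem, p_chem = g != "O", p != "O"
            tp += g_chem and p_chem
            fp += p_chem and not g_chem
            fn += g_chem and not p_chem
    return tp, fp, fn
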