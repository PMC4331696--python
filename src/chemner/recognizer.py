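"""End-to-end chemical entity recogniser as a scikit-learn estimator.

``ChemicalEntityRecognizer`` composes the full pipeline: rule-based
sentence splitting and tokenisation, pluggable lemma/POS/chunk tagging,
feature assembly (default or knowledge-rich), a linear-chain CRF, and the
two recall-boosting post-processing heuristics.  ``fit`` consumes
gold-annotated :class:`~chemner.types.Document` objects; ``predict``
returns documents whose mentions are the recogniser's output with
marginal-probability confidences suitable for CEM/CDI ranking.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Optional, Sequence, Tuple

from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .crf import ChainCRF
from .features import FeatureConfig, FeatureExtractor, Resources
from .lexicons import AffixLists, CompiledLexicon, load_affix_lists, load_element_symbols
from .pipeline import decode_mentions, encode_bio
from .postprocess import (
    RelabelConfig,
    find_abbreviation_candidates,
    rank_cdi,
    relabel_by_composition,
    relabel_surfaces,
)
from .preprocess import preprocess_section
from .segments import SegmentDictionary, load_segment_dictionary
from .types import SECTIONS, Document, Mention, Token

SectionState = Tuple[List[Token], List[str], List[float]]


class ChemicalEntityRecognizer(BaseEstimator):
    """Chemical NER over sectioned documents.

    Parameters
    ----------
    splitter : {"scientific", "general"}
        Sentence-splitting rule set.
    tokeniser : {"chemistry", "general"}
        Tokenisation rule set.
    knowledge_rich : bool
        Enable the chemical knowledge-rich feature extractors.
    abbrev, composition : bool
        Post-processing switches; both require ``knowledge_rich``.
    t1, t2 : float
        Confidence and composition thresholds of the relabelling heuristic.
    c2 : float
        CRF L2 regularisation strength.
    max_iter : int
        CRF optimiser iteration cap.
    lexicons : sequence of CompiledLexicon
        User-supplied dictionaries (may be empty).
    affix_lists, element_symbols, segment_dict
        Chemical resources; packaged fixtures are used when None.
    tagger : callable, optional
        Pluggable lemma/POS/chunk annotator (rule tagger when None).
    seed : int
        Recorded for provenance; training itself is deterministic.
    """

    def __init__(
        self,
        splitter: str = "scientific",
        tokeniser: str = "chemistry",
        knowledge_rich: bool = True,
        abbrev: bool = True,
        composition: bool = True,
        t1: float = 0.93,
        t2: float = 0.9,
        c2: float = 1.0,
        max_iter: int = 150,
        lexicons: Sequence[CompiledLexicon] = (),
        affix_lists: Optional[AffixLists] = None,
        element_symbols=None,
        segment_dict: Optional[SegmentDictionary] = None,
        tagger=None,
        seed: int = 0,
    ):
        self.splitter = splitter
        self.tokeniser = tokeniser
        self.knowledge_rich = knowledge_rich
        self.abbrev = abbrev
        self.composition = composition
        self.t1 = t1
        self.t2 = t2
        self.c2 = c2
        self.max_iter = max_iter
        self.lexicons = lexicons
        self.affix_lists = affix_lists
        self.element_symbols = element_symbols
        self.segment_dict = segment_dict
        self.tagger = tagger
        self.seed = seed

    # -- configuration -------------------------------------------------------

    def _validate_params(self) -> None:
        if (self.abbrev or self.composition) and not self.knowledge_rich:
            raise ValueError(
                "post-processing heuristics require knowledge_rich features"
            )

    def _resolved_resources(self) -> Resources:
        return Resources(
            lexicons=tuple(self.lexicons),
            affixes=self.affix_lists or load_affix_lists(),
            elements=(
                self.element_symbols
                if self.element_symbols is not None
                else load_element_symbols()
            ),
            segment_dict=self.segment_dict or load_segment_dictionary(),
        )

    def config_fingerprint(self) -> str:
        """Stable digest of the estimator's scalar configuration."""
        payload = {
            k: v
            for k, v in self.get_params().items()
            if isinstance(v, (str, int, float, bool, type(None)))
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- shared plumbing -----------------------------------------------------

    def _sentences(self, text: str):
        return preprocess_section(
            text, splitter=self.splitter, tokeniser=self.tokeniser, tagger=self.tagger
        )

    def gold_sequences(self, docs: Sequence[Document]):
        """Tokenise documents and project gold mentions to BIO labels.

        Yields (doc_id, section, tokens, labels) per sentence.
        """
        for doc in docs:
            for section in SECTIONS:
                text = doc.section_text(section)
                if not text.strip():
                    continue
                section_mentions = [m for m in doc.mentions if m.section == section]
                for sent in self._sentences(text):
                    in_sent = [
                        m
                        for m in section_mentions
                        if m.start < sent.end and m.end > sent.start
                    ]
                    yield doc.doc_id, section, sent.tokens, encode_bio(sent.tokens, in_sent)

    # -- estimator API -------------------------------------------------------

    def fit(self, docs: Sequence[Document], y=None):
        """Train the CRF on gold-annotated documents."""
        self._validate_params()
        docs = list(docs)
        if not docs:
            raise ValueError("training corpus is empty")
        resources = self._resolved_resources()
        self.extractor_ = FeatureExtractor(
            FeatureConfig(knowledge_rich=self.knowledge_rich), resources
        )
        X, labels = [], []
        for _, _, tokens, sent_labels in self.gold_sequences(docs):
            if tokens:
                X.append(self.extractor_.sentence_features(tokens))
                labels.append(sent_labels)
        self.crf_ = ChainCRF(c2=self.c2, max_iter=self.max_iter).fit(X, labels)
        self.n_sentences_ = len(X)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "crf_"):
            raise NotFittedError("ChemicalEntityRecognizer is not fitted")

    def _label_section(self, text: str) -> SectionState:
        tokens: List[Token] = []
        labels: List[str] = []
        confs: List[float] = []
        for sent in self._sentences(text):
            if not sent.tokens:
                continue
            feats = self.extractor_.sentence_features(sent.tokens)
            (sent_labels, sent_confs) = self.crf_.predict_with_confidence([feats])[0]
            tokens.extend(sent.tokens)
            labels.extend(sent_labels)
            confs.extend(sent_confs)
        return tokens, labels, confs

    def label_document(self, doc: Document) -> Dict[str, SectionState]:
        """CRF labels and confidences per section, with post-processing."""
        self._check_fitted()
        state: Dict[str, SectionState] = {}
        for section in SECTIONS:
            text = doc.section_text(section)
            state[section] = self._label_section(text) if text.strip() else ([], [], [])

        if self.abbrev:
            candidates = set()
            for section in SECTIONS:
                tokens, labels, confs = state[section]
                if not tokens:
                    continue
                mentions = decode_mentions(
                    labels, tokens, section, doc.section_text(section), confs
                )
                candidates |= find_abbreviation_candidates(tokens, labels, mentions)
            if candidates:
                for section in SECTIONS:
                    tokens, labels, confs = state[section]
                    if tokens:
                        labels, confs = relabel_surfaces(tokens, labels, confs, candidates)
                        state[section] = (tokens, labels, confs)

        if self.composition:
            cfg = RelabelConfig(t1=self.t1, t2=self.t2)
            segment_dict = self.extractor_.resources.segment_dict
            for section in SECTIONS:
                tokens, labels, confs = state[section]
                if tokens:
                    labels, confs = relabel_by_composition(
                        tokens, labels, confs, segment_dict, cfg
                    )
                    state[section] = (tokens, labels, confs)
        return state

    def predict(self, docs: Sequence[Document]) -> List[Document]:
        """Annotate documents, returning copies carrying predicted mentions."""
        self._check_fitted()
        out: List[Document] = []
        for doc in docs:
            state = self.label_document(doc)
            predicted = doc.copy_without_mentions()
            for section in SECTIONS:
                tokens, labels, confs = state[section]
                if tokens:
                    predicted.mentions.extend(
                        decode_mentions(
                            labels, tokens, section, doc.section_text(section), confs
                        )
                    )
            out.append(predicted)
        return out

    def predict_cdi(self, docs: Sequence[Document]) -> Dict[str, List[Mention]]:
        """Ranked unique-mention lists per document."""
        return {d.doc_id: rank_cdi(d.mentions) for d in self.predict(docs)}

    def score(self, docs: Sequence[Document], y=None) -> float:
        """CEM micro-averaged F1 against the documents' gold mentions."""
        from .evaluate import evaluate_cem

        return evaluate_cem(docs, self.predict(docs), scope="micro").f1

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialise configuration, resources and CRF weights to JSON."""
        self._check_fitted()
        resources = self.extractor_.resources
        payload = {
            "params": {
                k: v
                for k, v in self.get_params().items()
                if isinstance(v, (str, int, float, bool, type(None)))
            },
            "fingerprint": self.config_fingerprint(),
            "lexicons": [
                {"name": lex.name, "entries": sorted(" ".join(e) for e in lex.entries)}
                for lex in resources.lexicons
            ],
            "prefixes": sorted(a for b in resources.affixes.prefixes.values() for a in b),
            "suffixes": sorted(a for b in resources.affixes.suffixes.values() for a in b),
            "elements": sorted(resources.elements),
            "segments": sorted(resources.segment_dict.entries),
            "crf": self.crf_.to_dict(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ChemicalEntityRecognizer":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        model = cls(**payload["params"])
        model.lexicons = tuple(
            CompiledLexicon(item["name"], item["entries"]) for item in payload["lexicons"]
        )
        model.affix_lists = AffixLists.from_iterables(
            payload["prefixes"], payload["suffixes"]
        )
        model.element_symbols = frozenset(payload["elements"])
        model.segment_dict = SegmentDictionary(payload["segments"])
        model.extractor_ = FeatureExtractor(
            FeatureConfig(knowledge_rich=model.knowledge_rich),
            model._resolved_resources(),
        )
        model.crf_ = ChainCRF.from_dict(payload["crf"])
        return model
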