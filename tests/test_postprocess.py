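import random

import pytest

from chemner.pipeline import decode_mentions
from chemner.postprocess import (
    RelabelConfig,
    find_abbreviation_candidates,
    rank_cdi,
    recognise_abbreviations,
    relabel_by_composition,
    verify_abbreviation,
)
from chemner.preprocess import tokenise
from chemner.types import Mention, Token


class TestVerifyAbbreviation:
    @pytest.mark.parametrize(
        "candidate,entity,expected",
        [
            ("STMP", "sodium trimetaphosphate", True),
            ("XYZ", "glucose", False),
            ("HES-HEMA", "hydroxyethyl starch-hydroxyethyl methacrylate", True),
            ("stmp", "Sodium Trimetaphosphate", True),
            ("SS", "sulfate", False),  # second S has no later occurrence
        ],
    )
    def test_subsequence_scan(self, candidate, entity, expected):
        assert verify_abbreviation(candidate, entity) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            verify_abbreviation("", "x")


TEXT = (
    "It was phosphorylated with sodium trimetaphosphate (STMP) at ambient "
    "temperature and STMP accumulated."
)


def stmp_fixture():
    tokens = tokenise(TEXT, "chemistry")
    surfaces = [t.surface for t in tokens]
    labels = ["O"] * len(tokens)
    i, j = surfaces.index("sodium"), surfaces.index("trimetaphosphate")
    labels[i], labels[j] = "B", "I"
    confs = [0.95] * len(tokens)
    mentions = decode_mentions(labels, tokens, "A", TEXT, confs)
    return tokens, labels, confs, mentions


class TestAbbreviationRecognition:
    def test_all_occurrences_captured(self):
        tokens, labels, confs, mentions = stmp_fixture()
        new_labels, _ = recognise_abbreviations(tokens, labels, confs, mentions)
        stmp_positions = [i for i, t in enumerate(tokens) if t.surface == "STMP"]
        assert len(stmp_positions) == 2
        assert all(new_labels[i] == "B" for i in stmp_positions)
        # nothing else changed
        for i, lab in enumerate(labels):
            if i not in stmp_positions:
                assert new_labels[i] == lab

    def test_no_closing_parenthesis_no_change(self):
        text = "sodium trimetaphosphate ( STMP here STMP later"
        tokens = tokenise(text, "chemistry")
        labels = ["B", "I"] + ["O"] * (len(tokens) - 2)
        confs = [0.9] * len(tokens)
        mentions = decode_mentions(labels, tokens, "A", text, confs)
        new_labels, _ = recognise_abbreviations(tokens, labels, confs, mentions)
        assert new_labels == labels

    def test_already_chemical_candidate_no_trigger(self):
        tokens, labels, confs, mentions = stmp_fixture()
        first = [i for i, t in enumerate(tokens) if t.surface == "STMP"][0]
        labels = list(labels)
        labels[first] = "B"  # candidate slot already chemical
        mentions = decode_mentions(labels, tokens, "A", TEXT, confs)
        assert find_abbreviation_candidates(tokens, labels, mentions) == set()

    def test_failed_verification_no_change(self):
        text = "pure glucose ( XYZ ) and XYZ again"
        tokens = tokenise(text, "chemistry")
        labels = ["O", "B"] + ["O"] * (len(tokens) - 2)
        confs = [0.9] * len(tokens)
        mentions = decode_mentions(labels, tokens, "A", text, confs)
        new_labels, _ = recognise_abbreviations(tokens, labels, confs, mentions)
        assert new_labels == labels


class TestCompositionRelabelling:
    def tok(self, word):
        return [Token(word, 0, len(word))]

    def test_low_confidence_high_ratio_relabelled(self, segment_dict):
        labels, confs = relabel_by_composition(
            self.tok("polycalcium"), ["O"], [0.90], segment_dict, RelabelConfig()
        )
        assert labels == ["B"]
        assert confs[0] == pytest.approx(1.0)

    def test_confident_outside_untouched(self, segment_dict):
        labels, _ = relabel_by_composition(
            self.tok("polycalcium"), ["O"], [0.99], segment_dict, RelabelConfig()
        )
        assert labels == ["O"]

    def test_low_ratio_untouched(self, segment_dict):
        labels, _ = relabel_by_composition(
            self.tok("palytoxin"), ["O"], [0.90], segment_dict, RelabelConfig()
        )
        assert labels == ["O"]

    def test_strict_threshold_comparisons(self, segment_dict):
        cfg = RelabelConfig(t1=0.93, t2=1.0)
        # ratio 1.0 is not > 1.0; confidence exactly t1 is not < t1
        labels, _ = relabel_by_composition(
            self.tok("polycalcium"), ["O"], [0.92], segment_dict, cfg
        )
        assert labels == ["O"]
        labels, _ = relabel_by_composition(
            self.tok("polycalcium"), ["O"], [0.93], segment_dict, RelabelConfig()
        )
        assert labels == ["O"]

    def test_chemical_labels_never_removed(self, segment_dict):
        rng = random.Random(31)
        words = ["polycalcium", "palytoxin", "buffer", "methyloxy", "z9"]
        for _ in range(200):
            n = rng.randint(1, 6)
            tokens = []
            cursor = 0
            for _ in range(n):
                w = rng.choice(words)
                tokens.append(Token(w, cursor, cursor + len(w)))
                cursor += len(w) + 1
            labels, prev = [], "O"
            for _ in range(n):
                lab = rng.choice(["B", "O"] + (["I"] if prev != "O" else []))
                labels.append(lab)
                prev = lab
            confs = [rng.random() for _ in range(n)]
            before = {i for i, l in enumerate(labels) if l != "O"}
            new_labels, _ = relabel_by_composition(
                tokens, labels, confs, segment_dict, RelabelConfig()
            )
            after = {i for i, l in enumerate(new_labels) if l != "O"}
            assert before <= after


class TestRankCdi:
    def mention(self, text, conf):
        return Mention("A", 0, len(text), text, confidence=conf)

    def test_dedupe_keeps_max_confidence(self):
        ranked = rank_cdi(
            [self.mention("aspirin", 0.9), self.mention("aspirin", 0.7), self.mention("NO2", 0.8)]
        )
        assert [(m.text, m.confidence) for m in ranked] == [("aspirin", 0.9), ("NO2", 0.8)]

    def test_empty(self):
        assert rank_cdi([]) == []

    def test_matches_bruteforce(self):
        rng = random.Random(2)
        strings = ["aa", "bb", "cc", "dd"]
        for _ in range(100):
            mentions = [
                self.mention(rng.choice(strings), round(rng.random(), 3))
                for _ in range(rng.randint(0, 10))
            ]
            best = {}
            for m in mentions:
                best[m.text] = max(best.get(m.text, 0.0), m.confidence)
            expected = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
            got = [(m.text, m.confidence) for m in rank_cdi(mentions)]
            assert got == expected
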