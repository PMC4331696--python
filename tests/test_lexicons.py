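import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemner.lexicons import (
    CompiledLexicon,
    lexicon_features,
    load_element_symbols,
    match_affixes,
    match_element_symbol,
    normalise,
    tag_lexicon,
)

TABLE10_SURFACES = [
    "For", "the", "preparation", "of", "hydrogel", "microspheres", "based", "on",
    "hydroxyethyl", "starch", "-", "hydroxyethyl", "methacrylate", "(", "HES-HEMA", ")",
]
TABLE10_NORMAL = [
    "for", "the", "preparation", "of", "hydrogel", "microsphere", "base", "on",
    "hydroxyethyl", "starch", "_", "hydroxyethyl", "methacrylate", "_", "hes_hema", "_",
]
TABLE10_CTD = list("OOOOBOOOBIOBIOOO")


class TestNormalise:
    @pytest.mark.parametrize(
        "form,expected",
        [("HES-HEMA", "hes_hema"), ("(", "_"), ("GSK214a", "gsk000a"), ("", "")],
    )
    def test_examples(self, form, expected):
        assert normalise(form) == expected

    @given(st.text(max_size=30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_idempotent_and_length_preserving(self, form):
        norm = normalise(form)
        assert len(norm) == len(form)
        assert normalise(norm) == norm


def brute_force_tag(tokens, entries):
    """Leftmost-longest reference: at each position prefer the longest match."""
    labels = ["O"] * len(tokens)
    i = 0
    while i < len(tokens):
        lengths = [
            n
            for n in range(len(tokens) - i, 0, -1)
            if tuple(tokens[i : i + n]) in entries
        ]
        if lengths:
            n = max(lengths)
            labels[i : i + n] = ["B"] + ["I"] * (n - 1)
            i += n
        else:
            i += 1
    return labels


class TestTagLexicon:
    def test_reference_ctd_column(self, ctd_lexicon):
        assert tag_lexicon(TABLE10_NORMAL, ctd_lexicon) == TABLE10_CTD

    def test_empty_lexicon_all_outside(self):
        lex = CompiledLexicon("empty", [])
        assert tag_lexicon(["a", "b"], lex) == ["O", "O"]

    def test_leftmost_wins_over_overlap(self):
        lex = CompiledLexicon("x", ["a b", "b c"])
        assert tag_lexicon(["a", "b", "c"], lex) == ["B", "I", "O"]

    def test_matches_bruteforce_on_random_sentences(self):
        rng = random.Random(42)
        vocab = ["a", "b", "c", "d"]
        entries = {("a", "b"), ("b",), ("c", "d", "a"), ("d",), ("a", "b", "c")}
        lex = CompiledLexicon("r", [" ".join(e) for e in entries])
        for _ in range(1000):
            tokens = [rng.choice(vocab) for _ in range(rng.randint(1, 8))]
            got = tag_lexicon(tokens, lex)
            assert got == brute_force_tag(tokens, entries)
            # BIO validity: no leading I, no I after O
            prev = "O"
            for lab in got:
                assert not (lab == "I" and prev == "O")
                prev = lab


class TestLexiconFeatures:
    def test_worked_example_starch(self, ctd_lexicon):
        labels = tag_lexicon(TABLE10_NORMAL, ctd_lexicon)
        index = TABLE10_SURFACES.index("starch")
        feats = lexicon_features(labels, TABLE10_SURFACES, index, prefix="dictCTD")
        assert "dictCTDWB-2=on:O|hydroxyethyl:B" in feats
        assert "dictCTDWB-1=hydroxyethyl:B|starch:I" in feats
        assert "dictCTDB-2=O|B" in feats
        assert "dictCTDB-1=B|I" in feats

    def test_single_token_window_truncation(self):
        feats = lexicon_features(["B"], ["x"], 0, prefix="d")
        assert feats == {"dU0=B", "dWU0=x:B"}

    def test_matches_bruteforce_window_enumeration(self):
        rng = random.Random(3)
        for _ in range(200):
            n = rng.randint(1, 7)
            labels = []
            prev = "O"
            for _ in range(n):
                lab = rng.choice(["B", "O"] + (["I"] if prev != "O" else []))
                labels.append(lab)
                prev = lab
            surfaces = [rng.choice("wxyz") for _ in range(n)]
            index = rng.randrange(n)
            expected = set()
            for off in range(-2, 3):
                j = index + off
                if 0 <= j < n:
                    expected.add(f"dU{off}={labels[j]}")
                    expected.add(f"dWU{off}={surfaces[j]}:{labels[j]}")
            for off in range(-2, 2):
                a, b = index + off, index + off + 1
                if 0 <= a and b < n:
                    expected.add(f"dB{off}={labels[a]}|{labels[b]}")
                    expected.add(
                        f"dWB{off}={surfaces[a]}:{labels[a]}|{surfaces[b]}:{labels[b]}"
                    )
            assert lexicon_features(labels, surfaces, index, prefix="d") == expected


class TestAffixes:
    TABLE11 = {
        "Incubation": {},
        "with": {},
        "diisopropyl": {("prefix", 2): "di", ("suffix", 2): "yl"},
        "fluorophosphate": {("prefix", 4): "fluo", ("suffix", 3): "ate"},
        "and": {},
        "bis-(4-nitrophenyl)": {},
        "phosphate": {("suffix", 3): "ate"},
    }

    @pytest.mark.parametrize("token", sorted(TABLE11))
    def test_reference_affix_matrix(self, token, affix_lists):
        got = match_affixes(token, affix_lists)
        expected = {
            (side, size): self.TABLE11[token].get((side, size))
            for side in ("prefix", "suffix")
            for size in (2, 3, 4)
        }
        assert got == expected

    def test_short_token_truncation(self, affix_lists):
        got = match_affixes("at", affix_lists)
        assert got[("prefix", 3)] is None and got[("prefix", 4)] is None
        assert got[("suffix", 3)] is None and got[("suffix", 4)] is None

    def test_case_insensitive(self, affix_lists):
        assert match_affixes("Diisopropyl", affix_lists)[("prefix", 2)] == "di"


class TestElements:
    def test_symbol_list_size(self):
        assert len(load_element_symbols()) == 118

    @pytest.mark.parametrize(
        "token,expected",
        [("Fe", True), ("fe", False), ("NO", False), ("No", True), ("Uue", False)],
    )
    def test_membership_case_sensitive(self, token, expected):
        assert match_element_symbol(token) is expected
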