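import pytest

from chemner.lexicons import CompiledLexicon, load_affix_lists
from chemner.preprocess import ReplayTagger
from chemner.segments import load_segment_dictionary
from chemner.types import Document, Mention

# Reference sentence: surfaces with lemma / POS / chunk annotations as an
# external tagger would supply them.
TABLE8_ROWS = [
    ("It", "It", "PRP", "B-NP"),
    ("attenuated", "attenuate", "VBD", "B-VP"),
    ("GSK214a", "GSK214a", "NN", "B-NP"),
    ("-induced", "-induced", "JJ", "I-NP"),
    ("gestation", "gestation", "NN", "I-NP"),
    ("in", "in", "IN", "B-PP"),
    ("rats", "rat", "NN", "B-NP"),
    (".", ".", ".", "O"),
]

TABLE8_SENTENCE = "It attenuated GSK214a-induced gestation in rats."


@pytest.fixture(scope="session")
def segment_dict():
    return load_segment_dictionary()


@pytest.fixture(scope="session")
def affix_lists():
    return load_affix_lists()


@pytest.fixture(scope="session")
def replay_tagger():
    return ReplayTagger({row[0]: row[1:] for row in TABLE8_ROWS})


@pytest.fixture(scope="session")
def ctd_lexicon():
    return CompiledLexicon(
        "CTD", ["hydrogel", "hydroxyethyl starch", "hydroxyethyl methacrylate"]
    )


@pytest.fixture
def small_doc():
    return Document(
        "D1",
        "Aspirin study",
        "We tested aspirin.",
        [Mention("A", 10, 17, "aspirin", subtype="TRIVIAL")],
    )
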