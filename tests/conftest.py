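import pytest

from helpers import make_lexicon


@pytest.fixture
def cat_lexicon():
    """Toy lexicon whose one-substitution neighbors of 'cat' are known."""
    return make_lexicon(
        ["oat", "cot", "vat", "cab", "mat", "trek"],
        freqs=[50, 40, 30, 20, 10, 5],
    )


@pytest.fixture
def nonword_lexicon():
    """Five-word lexicon for scoring the nonwords 'toosh' and 'dast'."""
    return make_lexicon(["dust", "dash", "dart", "daft", "tooth"])


@pytest.fixture
def pg_lexicon():
    """Lexicon with transcriptions: 'cat'/kæt has pg neighbors bat, cats, cap."""
    return make_lexicon(
        ["cat", "bat", "cats", "cap", "oat"],
        freqs=[100, 50, 20, 30, 10],
        ipas=["kæt", "bæt", "kæts", "kæp", "oʊt"],
    )
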