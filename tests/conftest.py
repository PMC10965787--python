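import pytest

from sentisess.lexicon import Lexicon, demo_lexicon


@pytest.fixture(scope="session")
def demo_lex() -> Lexicon:
    return demo_lexicon()


@pytest.fixture()
def tiny_lex() -> Lexicon:
    """Minimal lexicon used by hand-computed scoring examples."""
    return Lexicon(
        entries={"goed": 1, "slecht": -1, "blij": 1, "somber": -1},
        negators=frozenset({"niet", "geen"}),
        intensifiers=frozenset({"heel", "zeer"}),
        provenance=("tiny",),
    )
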