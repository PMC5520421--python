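from pathlib import Path

import pytest

from bifan.fixtures import builtin, load_corpus

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fig1():
    """The three-automaton worked example: (network, initial state, goal a2)."""
    return builtin("fig1")


@pytest.fixture(scope="session")
def corpus_instances():
    """The pinned 200-network random corpus as (net, s0, goal) triples."""
    text = (DATA / "corpus_an.txt").read_text(encoding="utf-8")
    return list(load_corpus(text))
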