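import numpy as np
import pytest

from evscore import synth
from evscore.pipeline import ScoringContext
from evscore.text_prep import tokenize


@pytest.fixture(scope="session")
def vocab():
    return synth.make_vocabulary(seed=3)


@pytest.fixture(scope="session")
def corpus_stats(vocab):
    _, stats = synth.make_corpus(vocab, n_docs=300, seed=3)
    return stats


@pytest.fixture(scope="session")
def scoring_context(vocab, corpus_stats):
    return ScoringContext(stats=corpus_stats, emb=vocab.embedding)


@pytest.fixture
def seq():
    """Tokenize a whitespace-separated string into a TermSequence."""
    return lambda text: tokenize(text)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
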