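import numpy as np
import pytest

from eventbtm import synthetic
from eventbtm.corpus_io import sentence_from_text
from eventbtm.roles import WordVectorTable
from eventbtm.schema import Span, default_role_table


@pytest.fixture(scope="session")
def role_table():
    return default_role_table()


@pytest.fixture(scope="session")
def example_sentence():
    """The worked position-embedding example: a deduce-result mention with
    trigger 'reveals', arguments 'Task difficulty' and 'BOLD responses',
    and the target phrase 'frontal and parietal cortices'."""
    sent = sentence_from_text(
        "Task difficulty reveals the BOLD responses in frontal and parietal cortices"
    )
    spans = {
        "trigger": Span(2, 2, "reveals"),
        "arg1": Span(0, 1, "Task difficulty"),
        "arg2": Span(4, 5, "BOLD responses"),
        "target": Span(7, 10, "frontal and parietal cortices"),
    }
    return sent, spans


@pytest.fixture(scope="session")
def small_bundle():
    """Noise-free separable corpus shared by recognition/role tests."""
    return synthetic.generate(
        synthetic.GeneratorConfig(n_docs=20, sentences_per_doc=5,
                                  noise_rate=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def word_vectors(small_bundle):
    vocab = sorted(
        {t.surface.lower() for s in small_bundle.all_sentences() for t in s.tokens}
    )
    return WordVectorTable.random(vocab, 100, seed=11)


@pytest.fixture(scope="session")
def tiny_rng():
    return np.random.default_rng(0)
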