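import numpy as np
import pytest

from contextsim import (
    LatentEmbeddingSpec,
    fig3_embeddings,
    fig3_fixture,
    make_embeddings,
    make_frequency_table,
    make_passages,
)


@pytest.fixture(scope="session")
def fig3():
    """(passage, printed correlation matrix) of the worked example."""
    return fig3_fixture()


@pytest.fixture(scope="session")
def fig3_table():
    """Embeddings reproducing the worked-example correlations exactly."""
    return fig3_embeddings()


@pytest.fixture(scope="session")
def small_table():
    """A 300-word, 60-dim synthetic embedding table (seeded)."""
    return make_embeddings(LatentEmbeddingSpec(vocab_size=300, dimension=60, seed=101))


@pytest.fixture(scope="session")
def small_passages(small_table):
    """~11 passages x ~50 words (>500 tokens) over small_table's vocabulary."""
    return make_passages(small_table, n_passages=11, seed=102)


@pytest.fixture(scope="session")
def small_freq(small_table):
    return make_frequency_table(small_table, seed=103)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
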