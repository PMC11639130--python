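import numpy as np
import pytest

from rxgl.chemio import FeatureVocab, split_dataset
from rxgl.model import ModelConfig, RXGLModel
from rxgl.synthetic_fixtures import (
    FixtureSpec,
    generate_reaction_set,
    load_golden_fixture,
)


@pytest.fixture(scope="session")
def vocab():
    return FeatureVocab()


@pytest.fixture(scope="session")
def tiny_records(vocab):
    """The 8-reaction golden corpus (2 families, 2 overlapped pairs)."""
    return load_golden_fixture("tiny", vocab=vocab)


@pytest.fixture(scope="session")
def small_records(vocab):
    """The 200-reaction golden corpus used for end-to-end training."""
    return load_golden_fixture("small", vocab=vocab)


@pytest.fixture(scope="session")
def small_split(small_records):
    return split_dataset(small_records, seed=0)


@pytest.fixture(scope="session")
def toy_records(vocab):
    """A 12-reaction corpus for fast forward/backward tests."""
    return generate_reaction_set(
        FixtureSpec(n_molecules=20, n_reactions=12, overlap_degree=3, seed=1),
        vocab=vocab,
    )


@pytest.fixture()
def toy_model(toy_records, vocab):
    return RXGLModel(toy_records, vocab, ModelConfig(dim=8, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def finite_difference(fn, arrays, eps=1e-6):
    """Central-difference gradients of scalar fn w.r.t. each array."""
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ij = it.multi_index
            old = arr[ij]
            arr[ij] = old + eps
            up = fn()
            arr[ij] = old - eps
            dn = fn()
            arr[ij] = old
            g[ij] = (up - dn) / (2 * eps)
        grads.append(g)
    return grads
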