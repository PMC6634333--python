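import numpy as np
import pytest

from lexnorm.containers import CountMatrix, SimilarityMatrix
from lexnorm.synthetic_data import GeneratorConfig, generate_lexicon


@pytest.fixture
def toy_records():
    """Hand-written association records over a 4-word vocabulary."""
    from lexnorm.containers import AssociationRecord

    return [
        AssociationRecord("p1", "dog", ["cat", "bone"]),
        AssociationRecord("p2", "dog", ["cat"]),
        AssociationRecord("p1", "cat", ["dog", "mouse"]),
        AssociationRecord("p2", "cat", ["mouse"]),
        AssociationRecord("p1", "mouse", ["cat", "cheese"]),
    ]


def make_similarity(words, values):
    """Build a SimilarityMatrix from a dense array, symmetrizing exactly."""
    values = np.asarray(values, dtype=float)
    values = (values + values.T) / 2
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(words, values)


@pytest.fixture
def six_word_similarity():
    rng = np.random.default_rng(42)
    words = [f"w{i}" for i in range(6)]
    raw = rng.uniform(0, 1, (6, 6))
    return make_similarity(words, raw)


@pytest.fixture(scope="session")
def small_lexicon():
    """A small synthetic lexicon reused across fast tests."""
    return generate_lexicon(GeneratorConfig(vocab_size=60, participants_per_cue=30, seed=11))
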