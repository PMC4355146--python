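import numpy as np
import pytest

from chromspec import (
    HMMParams,
    MarkMatrix,
    ObservationSequence,
    StateAnnotation,
    make_random_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    """A well-separated 3-state, 3-mark HMM satisfying identifiability."""
    return make_random_params(3, 3, seed=42)


@pytest.fixture
def toy_annotation():
    """10-segment single-chromosome annotation used by enrichment oracles.

    States:  1 1 2 2 2 3 3 1 2 3   (segment width 100 for easy arithmetic)
    """
    labels = {"chr1": np.array([1, 1, 2, 2, 2, 3, 3, 1, 2, 3])}
    return StateAnnotation(labels, segment_width=100)


def random_hmm(rng, K, N):
    """Unstructured random valid parameters (no identifiability constraints)."""
    A = rng.dirichlet(np.ones(K), size=K).T
    O = rng.dirichlet(np.ones(N), size=K).T
    pi = rng.dirichlet(np.ones(K))
    return HMMParams(A, O, pi)


def random_sequence(rng, T, N, chrom="chr1"):
    return ObservationSequence(chrom, rng.integers(0, N, size=T), N)
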