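import numpy as np
import pytest

from causal_emergence import (
    TransitionMatrix,
    make_block_model,
    make_cycle_plus_block,
    make_mesoscale_variant,
    make_permutation,
)


@pytest.fixture
def cycle_block():
    """8-state walkthrough system: deterministic 4-cycle plus a uniform
    4-state equivalency-class block."""
    return make_cycle_plus_block(4, 4)


@pytest.fixture
def block_model():
    """8-state two-block uniform block model (two equivalency classes)."""
    return make_block_model([4, 4])


@pytest.fixture
def mesoscale_model():
    """Block model whose first member per block is distinguishable."""
    return make_mesoscale_variant([4, 4], [0.7, 0.1, 0.1, 0.1])


@pytest.fixture
def perm8():
    """8-state cyclic permutation: the zero-emergence limit."""
    return make_permutation(8, [(i + 1) % 8 for i in range(8)])


@pytest.fixture
def uniform4():
    return TransitionMatrix(tuple("abcd"), np.full((4, 4), 0.25))


def random_tpm(rng: np.random.Generator, n: int) -> TransitionMatrix:
    """Dirichlet-row random TPM (dense, strictly positive rows)."""
    probs = rng.dirichlet(np.ones(n), size=n)
    return TransitionMatrix(tuple(str(i) for i in range(n)), probs)
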