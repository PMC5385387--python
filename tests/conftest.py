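import numpy as np
import pytest

from cxcircuit import (
    GeneratorSet,
    build_canonical_space,
    build_connection_matrix,
    reference_generator_set,
    reference_networks,
)


@pytest.fixture(scope="session")
def space():
    return build_canonical_space()


@pytest.fixture(scope="session")
def gens(space):
    return reference_generator_set(space)


@pytest.fixture(scope="session")
def plain_gens(space):
    """Generator set without the special PB-LN / EIP-IDFP permutations."""
    return GeneratorSet(space)


@pytest.fixture(scope="session")
def networks():
    return reference_networks()


@pytest.fixture(scope="session")
def observed(networks):
    return networks[0]


@pytest.fixture(scope="session")
def model(networks):
    return networks[1]


@pytest.fixture(scope="session")
def observed_matrix(observed):
    return build_connection_matrix(observed)


@pytest.fixture(scope="session")
def model_matrix(model):
    return build_connection_matrix(model)


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.35) -> np.ndarray:
    """Random binary adjacency without self-loops."""
    A = (rng.random((n, n)) < p).astype(np.int64)
    np.fill_diagonal(A, 0)
    return A
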