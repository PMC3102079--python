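import numpy as np
import pytest

from bnergm.network import Network


@pytest.fixture
def triangle():
    return Network(3, ((0, 1), (0, 2), (1, 2)))


@pytest.fixture
def path3():
    return Network(3, ((0, 1), (1, 2)))


@pytest.fixture
def four_cycle():
    return Network(4, ((0, 1), (1, 2), (2, 3), (0, 3)))


@pytest.fixture
def small_net():
    """5 nodes, 6 edges, contains triangles -- interior statistics."""
    return Network(5, ((0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
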