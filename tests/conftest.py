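import numpy as np
import pytest

from rsnet.connectivity import BinaryNetwork, ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def adjacency_to_network(a, sparsity=0.5):
    a = np.asarray(a)
    return BinaryNetwork(adjacency=a, sparsity=sparsity)


def fc_from_matrix(r):
    return ConnectivityMatrix(r=np.asarray(r, dtype=float))


@pytest.fixture
def k4():
    """Complete graph on 4 nodes."""
    a = np.ones((4, 4), dtype=int) - np.eye(4, dtype=int)
    return adjacency_to_network(a)


@pytest.fixture
def star4():
    """Star on 4 nodes: center 0 plus 3 leaves."""
    a = np.zeros((4, 4), dtype=int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return adjacency_to_network(a)


@pytest.fixture
def path3():
    """Path a-b-c on 3 nodes."""
    a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return adjacency_to_network(a)
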