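import numpy as np
import pytest

from vaxcampsim.network import ContactNetwork, generate_watts_strogatz


def make_net(edges, n=None):
    """Small fixture network from an explicit edge list."""
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    if n is None:
        n = int(edges.max()) + 1 if edges.size else 0
    return ContactNetwork(n_nodes=n, edges=edges)


@pytest.fixture
def path5():
    """Path graph 0-1-2-3-4."""
    return make_net([(0, 1), (1, 2), (2, 3), (3, 4)])


@pytest.fixture
def star10():
    """Star with center 0 and 10 leaves."""
    return make_net([(0, i) for i in range(1, 11)])


@pytest.fixture
def k3():
    """Triangle / complete graph on 3 nodes."""
    return make_net([(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def cycle6():
    return make_net([(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture
def ws_small():
    """A modest Watts-Strogatz graph for structural checks."""
    return generate_watts_strogatz(100, 6, 0.05, np.random.default_rng(42))
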