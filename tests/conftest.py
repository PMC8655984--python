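import numpy as np
import pytest

from rwrscreen import GeneSet, build_network, generate_network


@pytest.fixture
def pair_net():
    """Two nodes joined by a single edge."""
    return build_network([("n1", "n2", 5)])


@pytest.fixture
def path3_net():
    """Path a - b - c with equal weights."""
    return build_network([("a", "b", 100), ("b", "c", 100)])


@pytest.fixture
def seeds_ab():
    return GeneSet(identifiers=("a", "b"))


def random_connected_net(n_nodes: int, rng_seed: int):
    """Small connected random network (preferential attachment backbone)."""
    return generate_network(n_nodes, attach_degree=2, weight_range=(1, 999), rng_seed=rng_seed)


def linear_solve_rwr(net, seeds, r=0.8):
    """Closed-form RWR fixed point P = r (I - (1-r) M)^-1 P0.

    Independent oracle for the iterative walk: dense linear algebra, no
    shared code with the power iteration beyond the transition matrix
    definition.
    """
    from rwrscreen import transition_matrix

    n = net.n_nodes
    M = transition_matrix(net).toarray()
    p0 = np.zeros(n)
    idx = [net.index(g) for g in seeds]
    p0[idx] = 1.0 / len(idx)
    return np.linalg.solve(np.eye(n) - (1.0 - r) * M, r * p0)
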