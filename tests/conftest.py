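import numpy as np
import pytest

from ppimod.generate import Hyperparams, generate, planted_params
from ppimod.netio import AnnotatedNetwork


@pytest.fixture
def triangle():
    return AnnotatedNetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def four_cycle():
    return AnnotatedNetwork.from_edges(
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
    )


@pytest.fixture
def path_graph():
    return AnnotatedNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def planted_net():
    """Well-separated 3-module network with module-specific annotations."""
    hyper = Hyperparams(K=3)
    params = planted_params(3, 3, [6, 6, 6], eps_in=0.15, eps_out=0.01)
    net, truth = generate(hyper, 300, 3, [6, 6, 6], rng_seed=42, params=params)
    return net, truth


def random_graph_net(n, p, rng):
    """Simple Erdos-Renyi network with single-letter-free string ids."""
    adj = np.triu(rng.random((n, n)) < p, k=1)
    edges = [(f"n{i:02d}", f"n{j:02d}") for i, j in zip(*np.nonzero(adj))]
    extra = [f"n{i:02d}" for i in range(n)]
    return AnnotatedNetwork.from_edges(edges, extra_proteins=extra)


def random_membership(n, K, rng):
    from ppimod.infer import MembershipMatrix

    return MembershipMatrix(values=rng.dirichlet(np.ones(K), size=n))
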