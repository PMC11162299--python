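import numpy as np
import pytest

from hgcomplex.io import Complex, ComplexSet, InteractionNetwork
from hgcomplex.synthetic import generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle_network():
    return InteractionNetwork(
        nodes=["a", "b", "c"],
        edges={("a", "b"), ("a", "c"), ("b", "c")},
    )


@pytest.fixture
def small_benchmark():
    """A 60-node benchmark with 5 planted cliques; session-stable seed."""
    return generate_benchmark(
        n_nodes=60,
        n_complexes=5,
        background_edge_prob=0.02,
        within_complex_edge_prob=1.0,
        seed=7,
    )


def random_network(rng, n, p):
    nodes = [f"n{i}" for i in range(n)]
    edges = {
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return InteractionNetwork(nodes=nodes, edges=edges)


def random_complex_set(rng, n_complexes, universe, max_size=8):
    out = []
    for _ in range(n_complexes):
        size = int(rng.integers(1, max_size + 1))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        out.append(Complex(members=frozenset(members)))
    return ComplexSet(out)
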