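import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hyperreduce import Hypergraph

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def triangle_face():
    """Triangle with its 2-simplex: three pairwise edges plus the triple."""
    return Hypergraph.from_edges([[0, 1], [1, 2], [0, 2], [0, 1, 2]])


@pytest.fixture
def single_triple():
    """One 2-hyperedge on three nodes."""
    return Hypergraph.from_edges([[0, 1, 2]])


@pytest.fixture
def pairwise_triangle():
    """Complete pairwise graph on three nodes (no triple)."""
    return Hypergraph.from_edges([[0, 1], [1, 2], [0, 2]])


@pytest.fixture
def star10():
    """Hub with nine pairwise spokes."""
    return Hypergraph.from_edges([[0, i] for i in range(1, 10)])


def random_hypergraph_edges(rng: np.random.Generator, n=8, m=12):
    """Small random hypergraph edge list for property checks."""
    edges = []
    for _ in range(m):
        size = int(rng.integers(2, min(5, n) + 1))
        edges.append(sorted(int(x) for x in rng.choice(n, size, replace=False)))
    return edges
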