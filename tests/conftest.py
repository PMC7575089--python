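import networkx as nx
import numpy as np
import pytest

from patchlink import ClusteringState

# the 8-node, 10-link worked example used throughout the docs:
# adding (u, v) raises the clustering coefficient from 7/24 to 1/2
EXAMPLE_LINKS = [
    ("a", "b"), ("a", "w"), ("a", "c"), ("b", "u"), ("b", "w"),
    ("u", "e"), ("w", "c"), ("w", "d"), ("e", "v"), ("d", "v"),
]


@pytest.fixture
def example_graph() -> nx.Graph:
    return nx.Graph(EXAMPLE_LINKS)


@pytest.fixture
def example_state(example_graph) -> ClusteringState:
    return ClusteringState.from_graph(example_graph)


def random_graph(rng: np.random.Generator, n_max: int = 60,
                 density_range: tuple[float, float] = (0.02, 0.8)) -> nx.Graph:
    """A random simple graph with size and density drawn from *rng*."""
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(*density_range))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
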