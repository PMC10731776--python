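import numpy as np
import pytest

from microlink.containers import AssociationMatrix, DiseaseDAG
from microlink.synthetic import make_planted_association


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_assoc():
    """4 microbes x 3 diseases with a fixed pattern."""
    values = np.array([
        [1, 0, 1],
        [0, 1, 0],
        [1, 1, 0],
        [0, 0, 1],
    ])
    return AssociationMatrix(values, ["m1", "m2", "m3", "m4"],
                             ["d1", "d2", "d3"])


@pytest.fixture
def small_world():
    return make_planted_association(nm=40, nd=12, n_clusters=3, p_in=0.6,
                                    p_out=0.05, flip_noise=0.0, seed=42)


def random_dag(rng, max_nodes=12):
    """Random rooted ancestor DAG: nodes added one at a time, each new node
    gets >= 1 parent among later-added (higher) nodes... built top-down:
    root first, ancestors layered above with random child->parent edges
    guaranteeing reachability from the root."""
    n = int(rng.integers(1, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    root = names[0]
    edges = []
    for i in range(1, n):
        # connect node i as parent of at least one earlier node -> reachable
        child = names[int(rng.integers(0, i))]
        edges.append((child, names[i]))
        # extra edges earlier -> i keep it acyclic (edges always old -> new)
        for j in range(int(rng.integers(0, 2))):
            c2 = names[int(rng.integers(0, i))]
            if (c2, names[i]) not in edges:
                edges.append((c2, names[i]))
    return DiseaseDAG(root, frozenset(names), tuple(edges))
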