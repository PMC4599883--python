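import networkx as nx
import numpy as np
import pytest

from anatomynet.io import BONE, MUSCLE, AnatomicalNetwork


def net_from_nx(g: nx.Graph, node_class: str = BONE) -> AnatomicalNetwork:
    labels = [str(v) for v in g.nodes]
    adj = nx.to_numpy_array(g, dtype=int)
    return AnatomicalNetwork(labels, adj, {l: node_class for l in labels})


def random_net(n: int, p: float, seed: int) -> AnatomicalNetwork:
    return net_from_nx(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture
def triangle() -> AnatomicalNetwork:
    return net_from_nx(nx.complete_graph(3))


@pytest.fixture
def path3() -> AnatomicalNetwork:
    return net_from_nx(nx.path_graph(3))


@pytest.fixture
def k4() -> AnatomicalNetwork:
    return net_from_nx(nx.complete_graph(4))


@pytest.fixture
def two_bones_one_muscle() -> AnatomicalNetwork:
    """Two articulated bones and one muscle attached to both."""
    labels = ["bone_a", "bone_b", "muscle_x"]
    adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    classes = {"bone_a": BONE, "bone_b": BONE, "muscle_x": MUSCLE}
    return AnatomicalNetwork(labels, adj, classes)


@pytest.fixture
def sparse_muscular() -> AnatomicalNetwork:
    """57 muscles, 4 disjoint fusion contacts, 49 isolated — the muscular regime."""
    labels = [f"muscle_{i}" for i in range(57)]
    adj = np.zeros((57, 57), dtype=int)
    for a, b in [(0, 1), (2, 3), (4, 5), (6, 7)]:
        adj[a, b] = adj[b, a] = 1
    return AnatomicalNetwork(labels, adj, {l: MUSCLE for l in labels})
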