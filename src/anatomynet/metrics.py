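"""Global topology descriptors of anatomical networks.

Five global parameters summarize each network: density D = 2K/(N(N-1)),
mean clustering coefficient C (Watts–Strogatz node average; nodes of degree
< 2 contribute 0 and the mean divides by N), mean shortest path length L
over reachable unordered pairs, the diameter (longest geodesic), and degree
heterogeneity H = sigma_k / mu_k. Degree-indexed profiles P(k) and C(k)
feed the hierarchy test, and the weak-tie report ranks nodes whose removal
threatens connectivity (high betweenness, low clustering).
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .io import AnatomicalNetwork


@dataclasses.dataclass
class NetworkParams:
    N: int
    K: int
    D: float
    C: float
    L: float
    diameter: float
    H: float

    def as_row(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class DegreeProfiles:
    P: dict[int, float]          # degree -> n_k / N
    Cprof: dict[int, float]      # degree -> mean clustering of nodes with that degree


@dataclasses.dataclass
class WeakTieReport:
    clustering: dict[str, float]
    betweenness: dict[str, float]
    removal_impact: dict[str, tuple[int, int]]  # label -> (newly disconnected, components after)
    candidates: list[str]                       # high betweenness, low clustering first


def node_clustering(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering coefficients; degree < 2 nodes get 0."""
    a = adj.astype(np.float64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def _geodesics(adj: np.ndarray) -> np.ndarray:
    if adj.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(adj.astype(np.float64), method="D", unweighted=True)


def mean_path_length(adj: np.ndarray) -> tuple[float, float]:
    """(L, diameter) over reachable unordered pairs; (0, 0) if none."""
    d = _geodesics(adj)
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return 0.0, 0.0
    return float(finite.mean()), float(finite.max())


def basic_params(net: AnatomicalNetwork) -> NetworkParams:
    """The five global parameters plus N, K."""
    n = net.n_nodes
    if n == 0:
        raise ValueError("empty network")
    k = net.n_edges
    deg = net.degree().astype(float)
    density = 2.0 * k / (n * (n - 1)) if n > 1 else 0.0
    c = float(node_clustering(net.adjacency).mean())
    length, diam = mean_path_length(net.adjacency)
    mu = deg.mean()
    h = float(deg.std() / mu) if mu > 0 else 0.0
    return NetworkParams(N=n, K=k, D=density, C=c, L=length, diameter=diam, H=h)


def degree_profiles(net: AnatomicalNetwork) -> DegreeProfiles:
    """P(k) = n_k/N and C(k) = mean clustering of degree-k nodes."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    deg = net.degree()
    clust = node_clustering(net.adjacency)
    p: dict[int, float] = {}
    cprof: dict[int, float] = {}
    for k in sorted(set(deg.tolist())):
        mask = deg == k
        p[int(k)] = float(mask.sum()) / net.n_nodes
        cprof[int(k)] = float(clust[mask].mean())
    return DegreeProfiles(P=p, Cprof=cprof)


def removal_impact(net: AnatomicalNetwork, label: str) -> tuple[int, int]:
    """Effect of deleting one node: (newly disconnected elements, components after).

    "Newly disconnected" counts remaining nodes that were in the deleted
    node's component but end up outside the largest surviving fragment of
    that component (0 if the component minus the node stays in one piece).
    """
    idx = net.index_of(label)
    n_before, comp_before = connected_components(net.adjacency, directed=False)
    keep = [i for i in range(net.n_nodes) if i != idx]
    sub = net.adjacency[np.ix_(keep, keep)]
    if sub.shape[0] == 0:
        return 0, 0
    n_after, comp_after = connected_components(sub, directed=False)
    same_comp = [j for j, i in enumerate(keep) if comp_before[i] == comp_before[idx]]
    if not same_comp:
        return 0, int(n_after)
    frags = comp_after[same_comp]
    sizes = np.bincount(frags, minlength=n_after)
    newly = int(len(same_comp) - sizes.max())
    return newly, int(n_after)


def weak_tie_report(net: AnatomicalNetwork) -> WeakTieReport:
    """Rank candidate weak ties: high betweenness first, low clustering breaking ties.

    Betweenness is the unnormalized shortest-path count. The top candidates
    are the nodes whose loss most threatens the cohesion of the network
    (e.g. the humerus in a limb skeleton).
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = net.to_networkx()
    btw = nx.betweenness_centrality(g, normalized=False)
    clust = dict(zip(net.labels, node_clustering(net.adjacency)))
    impact = {l: removal_impact(net, l) for l in net.labels}
    order = sorted(net.labels, key=lambda l: (-btw[l], clust[l], l))
    return WeakTieReport(
        clustering={l: float(clust[l]) for l in net.labels},
        betweenness={l: float(btw[l]) for l in net.labels},
        removal_impact=impact,
        candidates=order,
    )
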