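"""Connectivity modules by short-random-walk agglomeration (walktrap).

A connectivity module is a group of anatomical parts with more connections
among themselves than to the rest of the network. Modules are found with
the walktrap algorithm: a t-step random walk (default t = 3) started at a
node tends to stay inside the node's module, so nodes are compared by their
t-step transition probability vectors. Communities start as singletons and
are merged agglomeratively; at each step the pair of *adjacent* communities
whose merge minimizes the Ward-style cost

    dsigma(C1, C2) = (1/n) * |C1||C2| / (|C1|+|C2|) * sum_k (Pt_C1k - Pt_C2k)^2 / d_k

is fused, where Pt_C is the mean t-step probability vector of C's members,
d_k the degree of node k and n the number of nodes in the connected
component. As in the reference implementation of the algorithm, the walk is
made lazy by adding a self-loop to every vertex (degrees count the loop),
which removes periodicity artifacts on bipartite-like structures. The merge history is a dendrogram; the returned partition is the
cut maximizing Newman's modularity

    Q = (1/2K) * sum_ij [A_ij - k_i k_j / 2K] * delta(m_i, m_j)

over all cut levels. Connected components are processed independently (Q is
separable over components) and isolated nodes remain singleton modules.
"""

from __future__ import annotations

import dataclasses
import heapq
import warnings
from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import connected_components

from .io import AnatomicalNetwork

DEFAULT_STEPS = 3


@dataclasses.dataclass
class ComponentDendrogram:
    """Merge history of one connected component.

    ``nodes`` maps local indices to node labels; ``merges`` holds
    ``(a, b, new_id, height)`` with community ids local to the component
    (initial singletons are ids ``0..m-1``, merged communities get
    ``m, m+1, ...`` in merge order) and ``height`` the dsigma cost.
    """

    nodes: list[str]
    merges: list[tuple[int, int, int, float]]

    @property
    def n_levels(self) -> int:
        return len(self.merges) + 1

    def membership_at_level(self, level: int) -> list[int]:
        """Community id per local node after applying the first ``level`` merges."""
        if not 0 <= level <= len(self.merges):
            raise ValueError(f"level must be in [0, {len(self.merges)}]")
        m = len(self.nodes)
        parent = list(range(m + level))
        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        for a, b, new, _ in self.merges[:level]:
            parent[find(a)] = new
            parent[find(b)] = new
        return [find(i) for i in range(m)]

    def to_newick(self) -> str:
        """Newick-like text with dsigma heights as branch annotations."""
        rep: dict[int, str] = {i: lbl.replace(" ", "_") for i, lbl in enumerate(self.nodes)}
        for a, b, new, h in self.merges:
            rep[new] = f"({rep.pop(a)},{rep.pop(b)}):{h:.6g}"
        return "(" + ",".join(rep[i] for i in sorted(rep)) + ");" if len(rep) > 1 else rep.popitem()[1] + ";"


@dataclasses.dataclass
class MergeDendrogram:
    """Per-component walktrap merge histories over a whole network."""

    components: list[ComponentDendrogram]
    steps: int

    def merge_table(self) -> list[dict]:
        rows = []
        for ci, comp in enumerate(self.components):
            for a, b, new, h in comp.merges:
                rows.append({"component": ci, "a": a, "b": b, "merged": new, "height": h})
        return rows

    def to_newick(self) -> str:
        return "\n".join(c.to_newick() for c in self.components)


@dataclasses.dataclass
class ModulePartition:
    assignment: dict[str, int]
    q: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for label, mod in self.assignment.items():
            out.setdefault(mod, []).append(label)
        return out

    @classmethod
    def from_assignment(
        cls, net: AnatomicalNetwork, assignment: Mapping[str, int]
    ) -> "ModulePartition":
        part = cls(assignment=dict(assignment), q=0.0)
        part.q = modularity_q(net, part)
        return part


def _walktrap_component(
    adj: np.ndarray, labels: list[str], steps: int
) -> ComponentDendrogram:
    """Agglomerate one connected component (m >= 2 nodes, all degrees >= 1)."""
    m = adj.shape[0]
    # lazy walk: a self-loop at each vertex (as in the reference walktrap
    # implementation) makes the walk aperiodic; degrees include the loop
    lazy = adj + np.eye(m)
    deg = lazy.sum(axis=1)
    p = lazy / deg[:, None]
    pt = np.linalg.matrix_power(p, steps)

    size = {i: 1 for i in range(m)}
    vec = {i: pt[i] for i in range(m)}
    neighbors: dict[int, set[int]] = {
        i: set(np.nonzero(adj[i])[0].tolist()) - {i} for i in range(m)
    }
    alive = set(range(m))
    inv_deg = 1.0 / deg

    def dsigma(a: int, b: int) -> float:
        diff = vec[a] - vec[b]
        r2 = float((diff * diff * inv_deg).sum())
        return (size[a] * size[b]) / (size[a] + size[b]) * r2 / m

    heap: list[tuple[float, int, int]] = []
    for a in range(m):
        for b in neighbors[a]:
            if a < b:
                heapq.heappush(heap, (dsigma(a, b), a, b))

    merges: list[tuple[int, int, int, float]] = []
    current: dict[tuple[int, int], float] = {}
    for h, a, b in heap:
        current[(a, b)] = h

    next_id = m
    while len(alive) > 1:
        while heap:
            h, a, b = heapq.heappop(heap)
            if a in alive and b in alive and current.get((a, b)) == h:
                break
        else:
            break  # no adjacent pair left (cannot happen on a connected component)
        new = next_id
        next_id += 1
        merges.append((a, b, new, h))
        size[new] = size[a] + size[b]
        vec[new] = (size[a] * vec[a] + size[b] * vec[b]) / size[new]
        nbrs = (neighbors[a] | neighbors[b]) - {a, b}
        neighbors[new] = nbrs
        alive.discard(a)
        alive.discard(b)
        alive.add(new)
        for c in nbrs:
            neighbors[c].discard(a)
            neighbors[c].discard(b)
            neighbors[c].add(new)
            key = (min(c, new), max(c, new))
            val = dsigma(c, new)
            current[key] = val
            heapq.heappush(heap, (val, *key))
        del vec[a], vec[b], size[a], size[b], neighbors[a], neighbors[b]
    return ComponentDendrogram(nodes=labels, merges=merges)


def walktrap_dendrogram(
    net: AnatomicalNetwork, steps: int = DEFAULT_STEPS
) -> MergeDendrogram:
    """Per-component walktrap merge dendrogram.

    Isolated nodes bypass the walk and form single-node components with no
    merges; merges never cross components.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if net.n_nodes < 1:
        raise ValueError("empty network")
    n_comp, member = connected_components(net.adjacency, directed=False)
    comps: list[ComponentDendrogram] = []
    for c in range(n_comp):
        idx = np.nonzero(member == c)[0]
        labels = [net.labels[i] for i in idx]
        if len(idx) == 1:
            comps.append(ComponentDendrogram(nodes=labels, merges=[]))
            continue
        sub = net.adjacency[np.ix_(idx, idx)].astype(float)
        comps.append(_walktrap_component(sub, labels, steps))
    return MergeDendrogram(components=comps, steps=steps)


def modularity_q(net: AnatomicalNetwork, partition: ModulePartition | Mapping[str, int]) -> float:
    """Newman modularity of a partition (ordered-pair sum, diagonal included).

    Computed module-wise as sum_c [ L_c/K - (d_c/2K)^2 ] with L_c the
    within-module edge count and d_c the module degree sum, which equals the
    double sum (1/2K) sum_ij [A_ij - k_i k_j/2K] delta(m_i, m_j).
    """
    assignment = partition.assignment if isinstance(partition, ModulePartition) else dict(partition)
    missing = [l for l in net.labels if l not in assignment]
    if missing:
        raise ValueError(f"partition misses {len(missing)} node(s), e.g. {missing[0]!r}")
    k_tot = net.n_edges
    if k_tot == 0:
        warnings.warn("modularity of an edgeless network is defined as 0", stacklevel=2)
        return 0.0
    deg = net.degree()
    mods = np.array([assignment[l] for l in net.labels])
    q = 0.0
    for mod in set(mods.tolist()):
        idx = np.nonzero(mods == mod)[0]
        l_c = net.adjacency[np.ix_(idx, idx)].sum() / 2.0
        d_c = float(deg[idx].sum())
        q += l_c / k_tot - (d_c / (2.0 * k_tot)) ** 2
    return float(q)


def _component_q_contribution(
    adj_comp: np.ndarray, deg_global: np.ndarray, membership: list[int], k_tot: int
) -> float:
    """Contribution of one component's modules to the global Q."""
    member = np.asarray(membership)
    q = 0.0
    for mod in set(membership):
        idx = np.nonzero(member == mod)[0]
        l_c = adj_comp[np.ix_(idx, idx)].sum() / 2.0
        d_c = float(deg_global[idx].sum())
        q += l_c / k_tot - (d_c / (2.0 * k_tot)) ** 2
    return q


def best_partition(
    dendrogram: MergeDendrogram, net: AnatomicalNetwork
) -> ModulePartition:
    """Maximum-modularity cut of the dendrogram.

    Q decomposes over connected components, so each component's cut level is
    chosen independently by maximizing its contribution (ties broken toward
    fewer modules). Every level from all-singletons to one-block-per-
    component is considered. Isolated nodes are singleton modules.
    """
    k_tot = net.n_edges
    label_to_idx = {l: i for i, l in enumerate(net.labels)}
    deg = net.degree()
    assignment: dict[str, int] = {}
    next_module = 0
    for comp in dendrogram.components:
        idx = np.array([label_to_idx[l] for l in comp.nodes])
        if k_tot == 0 or len(comp.nodes) == 1:
            best_membership = list(range(len(comp.nodes)))
        else:
            adj_comp = net.adjacency[np.ix_(idx, idx)]
            deg_comp = deg[idx]
            best_q = -np.inf
            best_membership = None
            for level in range(comp.n_levels):
                membership = comp.membership_at_level(level)
                q = _component_q_contribution(adj_comp, deg_comp, membership, k_tot)
                # ties (within fp tolerance) go to the later level = fewer modules
                if q > best_q + 1e-12 or abs(q - best_q) <= 1e-12:
                    best_q, best_membership = q, membership
        remap: dict[int, int] = {}
        for label, com in zip(comp.nodes, best_membership):
            if com not in remap:
                remap[com] = next_module
                next_module += 1
            assignment[label] = remap[com]
    part = ModulePartition(assignment=assignment, q=0.0)
    if k_tot > 0:
        part.q = modularity_q(net, part)
    return part


def detect_modules(
    net: AnatomicalNetwork, steps: int = DEFAULT_STEPS
) -> tuple[MergeDendrogram, ModulePartition]:
    """Convenience wrapper: dendrogram plus its max-Q partition."""
    dend = walktrap_dendrogram(net, steps=steps)
    return dend, best_partition(dend, net)
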