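"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they are checking: shortest paths
by hand-rolled BFS, triangles by neighbor-set enumeration, modularity by the
literal double loop over ordered node pairs, and NMI by direct entropy
computation on the contingency table.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(adj: np.ndarray, src: int) -> list[float]:
    n = adj.shape[0]
    dist = [math.inf] * n
    dist[src] = 0
    q = deque([src])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == math.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_params(adj: np.ndarray) -> dict:
    n = adj.shape[0]
    deg = [int(adj[i].sum()) for i in range(n)]
    k = sum(deg) // 2
    clus = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            clus.append(0.0)
            continue
        tri = sum(
            1 for a in range(len(nbrs)) for b in range(a + 1, len(nbrs))
            if adj[nbrs[a], nbrs[b]]
        )
        clus.append(2.0 * tri / (len(nbrs) * (len(nbrs) - 1)))
    dists = []
    for i in range(n):
        d = bfs_distances(adj, i)
        dists.extend(d[j] for j in range(i + 1, n) if d[j] < math.inf)
    mu = sum(deg) / n if n else 0.0
    sd = math.sqrt(sum((d - mu) ** 2 for d in deg) / n) if n else 0.0
    return {
        "N": n,
        "K": k,
        "D": 2.0 * k / (n * (n - 1)) if n > 1 else 0.0,
        "C": sum(clus) / n,
        "L": sum(dists) / len(dists) if dists else 0.0,
        "diameter": max(dists) if dists else 0.0,
        "H": sd / mu if mu > 0 else 0.0,
    }


def brute_modularity(adj: np.ndarray, membership: list[int]) -> float:
    """Literal ordered-pair double sum, diagonal terms included."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    two_k = float(deg.sum())
    if two_k == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += adj[i, j] - deg[i] * deg[j] / two_k
    return q / two_k


def brute_nmi(labels_a: list, labels_b: list) -> float:
    """2 I(A;B) / (H(A) + H(B)) from the contingency table."""
    n = len(labels_a)
    ca = sorted(set(labels_a))
    cb = sorted(set(labels_b))
    table = np.zeros((len(ca), len(cb)))
    for a, b in zip(labels_a, labels_b):
        table[ca.index(a), cb.index(b)] += 1
    pa = table.sum(axis=1) / n
    pb = table.sum(axis=0) / n
    ha = -sum(p * math.log(p) for p in pa if p > 0)
    hb = -sum(p * math.log(p) for p in pb if p > 0)
    info = 0.0
    for i in range(len(ca)):
        for j in range(len(cb)):
            pij = table[i, j] / n
            if pij > 0:
                info += pij * math.log(pij / (pa[i] * pb[j]))
    if ha + hb == 0:
        return 1.0
    return 2.0 * info / (ha + hb)


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many — keep items small)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
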