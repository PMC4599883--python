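"""Small-world and hierarchy assessment against random null models.

A network is called small-world when its clustering is high and its paths
short relative to an ensemble of random networks with the same number of
nodes N and edges K. The size-corrected criterion used here is

    swi = (C / C_rand) / (L / L_rand)  >=  0.012 * N**1.11

with C_rand, L_rand the ensemble means over uniform simple G(N, K) graphs
(default ensemble size 10,000). Hierarchical organization is assessed by
power-law fits of the degree distribution P(k) and the clustering-by-degree
profile C(k): log-log least squares, with a verdict requiring both fits to
reach a configurable R^2 and the C(k) slope to be negative (clustering
concentrated in the sparsely connected periphery).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import networkx as nx
import numpy as np

from .io import AnatomicalNetwork
from .metrics import degree_profiles, mean_path_length, node_clustering

SW_COEFF = 0.012
SW_EXPONENT = 1.11
DEFAULT_N_RANDOM = 10_000
DEFAULT_R2_MIN = 0.7


@dataclasses.dataclass
class RandomEnsembleSummary:
    n_nodes: int
    n_edges: int
    n_random: int
    C_rand: float
    L_rand: float
    seed: int
    C_sd: float = 0.0   # spread of C over replicates (sd; se = sd/sqrt(n_random))
    L_sd: float = 0.0


@dataclasses.dataclass
class SmallWorldAssessment:
    swi: float | None
    threshold: float
    is_small_world: bool | None
    note: str = ""

    @property
    def assessable(self) -> bool:
        return self.swi is not None


@dataclasses.dataclass
class PowerLawFit:
    exponent: float      # fitted slope of log(value) on log(k); -alpha for a k**-alpha law
    intercept: float     # log(c)
    r_squared: float
    n_points: int


@dataclasses.dataclass
class HierarchyAssessment:
    pk_fit: PowerLawFit | None
    ck_fit: PowerLawFit | None
    is_hierarchical: bool | None
    criterion: str


def random_equivalent_ensemble(
    net: AnatomicalNetwork,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
) -> RandomEnsembleSummary:
    """Mean C and L over uniform simple graphs with the network's N and K.

    Each replicate is a G(N, K) graph; C and L follow the same conventions
    as :func:`anatomynet.metrics.basic_params` (L over reachable pairs).
    Per-replicate seeds derive deterministically from the master seed.
    """
    n, k = net.n_nodes, net.n_edges
    if k < 1:
        raise ValueError("need at least one edge to randomize")
    if k > n * (n - 1) // 2:
        raise ValueError("K exceeds the maximum for a simple graph")
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_random)
    c_vals = np.empty(n_random)
    l_vals = np.empty(n_random)
    for r in range(n_random):
        g = nx.gnm_random_graph(n, k, seed=int(child_seeds[r] % (2**31)))
        adj = nx.to_numpy_array(g, nodelist=range(n), dtype=np.int8)
        c_vals[r] = node_clustering(adj).mean()
        l_vals[r], _ = mean_path_length(adj)
    return RandomEnsembleSummary(
        n_nodes=n, n_edges=k, n_random=n_random,
        C_rand=float(c_vals.mean()), L_rand=float(l_vals.mean()), seed=seed,
        C_sd=float(c_vals.std()), L_sd=float(l_vals.std()),
    )


def small_world_threshold(n: int) -> float:
    return SW_COEFF * n ** SW_EXPONENT


def small_world_assess(
    net: AnatomicalNetwork, ensemble: RandomEnsembleSummary
) -> SmallWorldAssessment:
    """Size-corrected small-world verdict against the ensemble means."""
    from .metrics import basic_params

    params = basic_params(net)
    thr = small_world_threshold(params.N)
    if ensemble.C_rand <= 0 or ensemble.L_rand <= 0 or params.L <= 0:
        return SmallWorldAssessment(
            swi=None, threshold=thr, is_small_world=None,
            note="not assessable: degenerate clustering or path length in network or ensemble",
        )
    swi = (params.C / ensemble.C_rand) / (params.L / ensemble.L_rand)
    return SmallWorldAssessment(swi=float(swi), threshold=thr, is_small_world=bool(swi >= thr))


def power_law_fit(profile: Mapping[int, float]) -> PowerLawFit:
    """Least-squares fit of log(value) on log(k) over strictly positive points.

    For data following value = c * k**-alpha the fitted exponent is -alpha
    and r_squared is 1.
    """
    pts = [(k, v) for k, v in profile.items() if k > 0 and v > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 strictly positive points, got {len(pts)}")
    x = np.log(np.array([p[0] for p in pts], dtype=float))
    y = np.log(np.array([p[1] for p in pts], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(exponent=float(slope), intercept=float(intercept),
                       r_squared=r2, n_points=len(pts))


def hierarchy_assess(
    net: AnatomicalNetwork, r2_min: float = DEFAULT_R2_MIN
) -> HierarchyAssessment:
    """Power-law verdict on P(k) and C(k).

    Hierarchical iff both fits reach ``r2_min`` and the C(k) slope is
    negative. Degenerate degree structure (fewer than 3 usable points on
    either profile) yields a "not assessable" outcome.
    """
    criterion = (
        f"P(k) and C(k) log-log fits with R^2 >= {r2_min} and negative C(k) slope"
    )
    profs = degree_profiles(net)
    try:
        pk = power_law_fit(profs.P)
        ck = power_law_fit(profs.Cprof)
    except ValueError:
        return HierarchyAssessment(pk_fit=None, ck_fit=None, is_hierarchical=None,
                                   criterion=criterion + " (not assessable)")
    verdict = bool(
        pk.r_squared >= r2_min and ck.r_squared >= r2_min and ck.exponent < 0
    )
    return HierarchyAssessment(pk_fit=pk, ck_fit=ck, is_hierarchical=verdict,
                               criterion=criterion)
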