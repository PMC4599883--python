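"""Synthetic anatomical networks with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data:

* :func:`planted_partition_graph` draws Bernoulli edges with a higher
  within-module than between-module probability, providing a ground-truth
  partition for module-recovery benchmarks.
* :func:`limb_like_network` builds a stylized limb: a sparse, tree-like
  skeletal layer (girdle clique, stylopod-zeugopod chain, carpal block,
  digit chains — low density, few triangles), a near-empty muscular layer
  (isolated muscles plus rare fusion edges), and a musculoskeletal layer
  whose bone-muscle attachments span joints and thereby create the high
  triangle density seen when muscles are added to a limb skeleton.

Both are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .community import ModulePartition, modularity_q
from .io import BONE, MUSCLE, AnatomicalNetwork


@dataclasses.dataclass
class PlantedPartitionSpec:
    sizes: tuple[int, ...] = (20, 20, 20, 20)
    p_in: float = 0.5
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if any(s < 1 for s in self.sizes):
            raise ValueError("module sizes must be >= 1")


@dataclasses.dataclass
class LimbLikeSpec:
    n_digits: int = 5
    phalanges_per_digit: int = 3
    girdle_size: int = 3
    carpal_block: int = 8
    n_muscles: int = 40
    proximal_origin_fraction: float = 0.5
    span_joint_prob: float = 0.7
    fusion_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_digits < 1 or self.phalanges_per_digit < 1:
            raise ValueError("need at least one digit with one phalanx")
        if self.girdle_size < 1 or self.carpal_block < 2:
            raise ValueError("girdle_size >= 1 and carpal_block >= 2 required")
        if self.n_muscles < 0:
            raise ValueError("n_muscles must be >= 0")
        for p in (self.proximal_origin_fraction, self.span_joint_prob, self.fusion_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def planted_partition_graph(
    spec: PlantedPartitionSpec,
) -> tuple[AnatomicalNetwork, ModulePartition]:
    """Planted-partition benchmark graph plus its ground-truth partition."""
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.sizes)
    membership = np.repeat(np.arange(len(spec.sizes)), spec.sizes)
    labels = [f"m{membership[i]}_n{i}" for i in range(n)]
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in itertools.combinations(range(n), 2):
        p = spec.p_in if membership[i] == membership[j] else spec.p_out
        if rng.random() < p:
            adj[i, j] = adj[j, i] = 1
    net = AnatomicalNetwork(
        labels=labels,
        adjacency=adj,
        node_class={l: BONE for l in labels},
        meta={"generator": "planted_partition", "seed": str(spec.seed)},
    )
    truth = ModulePartition(
        assignment={labels[i]: int(membership[i]) for i in range(n)}, q=0.0
    )
    if net.n_edges > 0:
        truth.q = modularity_q(net, truth)
    return net, truth


def limb_like_network(spec: LimbLikeSpec = LimbLikeSpec()) -> AnatomicalNetwork:
    """Stylized musculoskeletal limb network (see module docstring).

    Proximal = girdle and stylopod bones plus every muscle attached to one
    of them; distal = everything else (zeugopod, carpals, digits and their
    muscles). Use :func:`anatomynet.io.extract_subsystem` to obtain the
    skeletal or muscular layer.
    """
    rng = np.random.default_rng(spec.seed)
    edges: list[tuple[str, str]] = []

    girdle = [f"girdle_{i}" for i in range(spec.girdle_size)]
    edges += list(itertools.combinations(girdle, 2))
    stylopod = "stylopod"
    edges += [(g, stylopod) for g in girdle]
    zeugopod = ["zeugopod_1", "zeugopod_2"]
    edges += [(stylopod, z) for z in zeugopod]
    edges.append(tuple(zeugopod))
    carpals = [f"carpal_{i}" for i in range(spec.carpal_block)]
    edges += list(zip(carpals[:-1], carpals[1:]))
    edges += [(zeugopod[0], carpals[0]), (zeugopod[1], carpals[1])]
    digit_bones: list[str] = []
    for d in range(spec.n_digits):
        chain = [f"digit{d}_metacarpal"] + [
            f"digit{d}_phalanx{p}" for p in range(spec.phalanges_per_digit)
        ]
        digit_bones += chain
        edges.append((carpals[d % spec.carpal_block], chain[0]))
        edges += list(zip(chain[:-1], chain[1:]))

    bones = girdle + [stylopod] + zeugopod + carpals + digit_bones
    proximal_bones = set(girdle) | {stylopod}
    distal_bones = [b for b in bones if b not in proximal_bones]
    origin_pool = girdle + [stylopod] + zeugopod

    bone_index = {b: i for i, b in enumerate(bones)}
    skel_adj = np.zeros((len(bones), len(bones)), dtype=np.int8)
    for a, b in edges:
        skel_adj[bone_index[a], bone_index[b]] = 1
        skel_adj[bone_index[b], bone_index[a]] = 1

    muscles = [f"muscle_{i}" for i in range(spec.n_muscles)]
    for m in muscles:
        if rng.random() < spec.proximal_origin_fraction:
            origin = origin_pool[rng.integers(len(origin_pool))]
        else:
            origin = distal_bones[rng.integers(len(distal_bones))]
        insertion = distal_bones[rng.integers(len(distal_bones))]
        while insertion == origin:
            insertion = distal_bones[rng.integers(len(distal_bones))]
        edges += [(m, origin), (m, insertion)]
        if rng.random() < spec.span_joint_prob:
            nbrs = np.nonzero(skel_adj[bone_index[insertion]])[0]
            if nbrs.size:
                partner = bones[nbrs[rng.integers(nbrs.size)]]
                if partner != origin:
                    edges.append((m, partner))
    # rare fusions / shared tendons between muscles
    for m in muscles:
        if rng.random() < spec.fusion_prob and len(muscles) > 1:
            other = muscles[rng.integers(len(muscles))]
            while other == m:
                other = muscles[rng.integers(len(muscles))]
            edges.append((m, other))

    labels = bones + muscles
    index = {l: i for i, l in enumerate(labels)}
    adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
    for a, b in edges:
        adj[index[a], index[b]] = 1
        adj[index[b], index[a]] = 1

    node_class = {b: BONE for b in bones} | {m: MUSCLE for m in muscles}
    region = {b: ("proximal" if b in proximal_bones else "distal") for b in bones}
    for m in muscles:
        attached = [labels[j] for j in np.nonzero(adj[index[m]])[0]]
        region[m] = (
            "proximal" if any(a in proximal_bones for a in attached) else "distal"
        )
    return AnatomicalNetwork(
        labels=labels,
        adjacency=adj,
        node_class=node_class,
        region=region,
        meta={"generator": "limb_like", "seed": str(spec.seed), "system": "musculoskeletal"},
    )
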