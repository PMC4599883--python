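"""Partition and parameter comparison across limbs, stages and hypotheses.

Two partitions of (partly) shared anatomical elements are compared two
ways. The co-classification similarity ratio restricts both partitions to
their common elements, finds the one-to-one module correspondence that
maximizes total overlap (optimal assignment on the module-overlap
contingency table), and reports matched elements / common elements. The
normalized mutual information (NMI) compares partitions or a priori
functional/developmental groupings on the full contingency table, oriented
so identical partitions score 1 ("similarity %" = 100 x NMI).

Across-limb comparisons (e.g. upper vs lower limb) require an explicit
serial-correspondence label map (humerus <-> femur, ...): label identity is
never inferred. Finally, proximal and distal sub-networks of two limbs are
compared by the mean absolute relative difference of their global
parameters (D, C, L, H).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score

from .community import ModulePartition
from .io import AnatomicalNetwork, split_by_region
from .metrics import NetworkParams, basic_params


@dataclasses.dataclass
class SimilarityResult:
    n_common: int
    n_coclassified: int
    ratio: float
    module_matching: list[tuple[int, int]]  # (module in A, matched module in B)

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


@dataclasses.dataclass
class NMIComparison:
    nmi: float

    @property
    def similarity_percent(self) -> float:
        return 100.0 * self.nmi


def _as_assignment(p: ModulePartition | Mapping[str, object]) -> dict[str, object]:
    return dict(p.assignment) if isinstance(p, ModulePartition) else dict(p)


def partition_similarity(
    p_a: ModulePartition | Mapping[str, object],
    p_b: ModulePartition | Mapping[str, object],
    label_map: Mapping[str, str] | None = None,
) -> SimilarityResult:
    """Co-classification ratio between two module partitions.

    ``label_map`` translates labels of ``p_b`` into the namespace of
    ``p_a`` (serial correspondences across limbs). Elements not shared by
    both partitions are ignored; an empty common set is an error.
    """
    a = _as_assignment(p_a)
    b = _as_assignment(p_b)
    if label_map is not None:
        inv = {str(v).strip(): str(k).strip() for k, v in label_map.items()}
        fwd = {str(k).strip(): str(v).strip() for k, v in label_map.items()}
        # accept the map in either orientation (A->B or B->A)
        mapped = {fwd.get(l, inv.get(l, l)): m for l, m in b.items()}
        b = mapped
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError(
            "no elements in common; across-limb comparisons need a label_map "
            "of serial correspondences"
        )
    mods_a = sorted({a[l] for l in common})
    mods_b = sorted({b[l] for l in common})
    table = np.zeros((len(mods_a), len(mods_b)), dtype=int)
    ia = {m: i for i, m in enumerate(mods_a)}
    ib = {m: i for i, m in enumerate(mods_b)}
    for l in common:
        table[ia[a[l]], ib[b[l]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    matched = int(table[rows, cols].sum())
    matching = [(mods_a[r], mods_b[c]) for r, c in zip(rows, cols) if table[r, c] > 0]
    return SimilarityResult(
        n_common=len(common),
        n_coclassified=matched,
        ratio=matched / len(common),
        module_matching=matching,
    )


def nmi_similarity(
    partition: ModulePartition | Mapping[str, object],
    grouping: ModulePartition | Mapping[str, object],
) -> NMIComparison:
    """Normalized mutual information between a partition and a grouping.

    Both sides are restricted to their common elements (with a warning if
    either holds extras); identical divisions score 1. When both sides are
    the single-group division NMI is defined as 1 (they match trivially).
    """
    a = _as_assignment(partition)
    b = _as_assignment(grouping)
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("no elements in common")
    if len(common) < max(len(a), len(b)):
        warnings.warn(
            f"restricting NMI to {len(common)} common elements", stacklevel=2
        )
    la = [a[l] for l in common]
    lb = [b[l] for l in common]
    if len(set(la)) == 1 and len(set(lb)) == 1:
        return NMIComparison(nmi=1.0)
    # arithmetic-mean normalization: 2 I(A;B) / (H(A) + H(B))
    val = normalized_mutual_info_score(
        _codes(la), _codes(lb), average_method="arithmetic"
    )
    return NMIComparison(nmi=float(val))


def _codes(labels: list) -> list[int]:
    seen: dict = {}
    return [seen.setdefault(l, len(seen)) for l in labels]


def params_dissimilarity(a: NetworkParams, b: NetworkParams) -> float:
    """Mean absolute relative difference over D, C, L and H.

    Each parameter contributes |x_a - x_b| / mean(x_a, x_b) (0 when both
    are 0), so the score is 0 for identical parameter vectors and symmetric
    in its arguments.
    """
    total = 0.0
    for attr in ("D", "C", "L", "H"):
        xa, xb = getattr(a, attr), getattr(b, attr)
        denom = (abs(xa) + abs(xb)) / 2.0
        total += abs(xa - xb) / denom if denom > 0 else 0.0
    return total / 4.0


def proximal_distal_params(
    net_ul: AnatomicalNetwork,
    net_ll: AnatomicalNetwork,
    regions_ul: Mapping[str, str] | None = None,
    regions_ll: Mapping[str, str] | None = None,
) -> dict:
    """Compare proximal-vs-proximal and distal-vs-distal sub-network topology.

    Returns per-subgraph :class:`NetworkParams` plus the two dissimilarity
    scores; a lower ``dist_vs_dist`` than ``prox_vs_prox`` means the distal
    regions of the two limbs are organized more alike than the proximal
    ones. Empty sub-networks yield a "not assessable" entry.
    """
    ul_prox, ul_dist = split_by_region(net_ul, regions_ul)
    ll_prox, ll_dist = split_by_region(net_ll, regions_ll)
    subs = {
        "UL_proximal": ul_prox, "UL_distal": ul_dist,
        "LL_proximal": ll_prox, "LL_distal": ll_dist,
    }
    params = {
        name: (basic_params(sub) if sub.n_nodes > 0 else None)
        for name, sub in subs.items()
    }

    def score(x: NetworkParams | None, y: NetworkParams | None):
        if x is None or y is None:
            return None  # not assessable: an empty region subgraph
        return params_dissimilarity(x, y)

    return {
        "params": params,
        "prox_vs_prox": score(params["UL_proximal"], params["LL_proximal"]),
        "dist_vs_dist": score(params["UL_distal"], params["LL_distal"]),
    }
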