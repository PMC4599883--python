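"""End-to-end analysis and comparison reports.

``analyze_networks`` runs, for each input network and requested system
(skeletal / muscular / musculoskeletal), the full pipeline: global
parameters, random-ensemble small-world assessment, power-law hierarchy
assessment, and walktrap module detection with the max-Q cut. The result
is one parameter-table row per analyzed network (N, K, D, C, L, Diameter,
H, verdicts, module count, Q) plus per-network module membership tables
and dendrograms. ``compare_reports`` emits pairwise co-classification and
NMI similarity tables and, when region maps are available, the
proximal/distal parameter comparison. All randomness flows from one master
seed, so regeneration from the same inputs is identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import community, compare, io, metrics, nullmodels

PARAM_COLUMNS = ["network", "system", "N", "K", "D", "C", "L", "Diameter", "H",
                 "swi", "sw_threshold", "is_small_world", "is_hierarchical",
                 "n_modules", "Q"]


@dataclasses.dataclass
class NetworkAnalysis:
    name: str
    system: str
    params: metrics.NetworkParams
    small_world: nullmodels.SmallWorldAssessment | None
    hierarchy: nullmodels.HierarchyAssessment | None
    dendrogram: community.MergeDendrogram
    partition: community.ModulePartition

    def row(self) -> dict:
        p = self.params
        sw = self.small_world
        return {
            "network": self.name,
            "system": self.system,
            "N": p.N, "K": p.K, "D": p.D, "C": p.C, "L": p.L,
            "Diameter": p.diameter, "H": p.H,
            "swi": None if sw is None else sw.swi,
            "sw_threshold": None if sw is None else sw.threshold,
            "is_small_world": None if sw is None else sw.is_small_world,
            "is_hierarchical": None if self.hierarchy is None else self.hierarchy.is_hierarchical,
            "n_modules": self.partition.n_modules,
            "Q": self.partition.q,
        }


@dataclasses.dataclass
class AnalysisReport:
    analyses: list[NetworkAnalysis]
    seed: int
    n_random: int
    steps: int
    r2_min: float

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame([a.row() for a in self.analyses], columns=PARAM_COLUMNS)

    def get(self, name: str, system: str) -> NetworkAnalysis:
        for a in self.analyses:
            if a.name == name and a.system == system:
                return a
        raise KeyError(f"no analysis for {name!r}/{system!r}")


def analyze_network(
    net: io.AnatomicalNetwork,
    name: str,
    system: str,
    seed: int = 0,
    n_random: int = nullmodels.DEFAULT_N_RANDOM,
    steps: int = community.DEFAULT_STEPS,
    r2_min: float = nullmodels.DEFAULT_R2_MIN,
) -> NetworkAnalysis:
    params = metrics.basic_params(net)
    small_world = None
    if params.K >= 1:
        ens = nullmodels.random_equivalent_ensemble(net, n_random=n_random, seed=seed)
        small_world = nullmodels.small_world_assess(net, ens)
    hierarchy = nullmodels.hierarchy_assess(net, r2_min=r2_min)
    dend, part = community.detect_modules(net, steps=steps)
    return NetworkAnalysis(
        name=name, system=system, params=params,
        small_world=small_world, hierarchy=hierarchy,
        dendrogram=dend, partition=part,
    )


def analyze_networks(
    nets: Mapping[str, io.AnatomicalNetwork],
    systems: Sequence[str] = io.SYSTEMS,
    seed: int = 0,
    n_random: int = nullmodels.DEFAULT_N_RANDOM,
    steps: int = community.DEFAULT_STEPS,
    r2_min: float = nullmodels.DEFAULT_R2_MIN,
) -> AnalysisReport:
    """Analyze each named musculoskeletal network, per requested system."""
    analyses = []
    for name, net in nets.items():
        for system in systems:
            sub = io.extract_subsystem(net, system)
            if sub.n_nodes == 0:
                continue
            analyses.append(
                analyze_network(sub, name, system, seed=seed, n_random=n_random,
                                steps=steps, r2_min=r2_min)
            )
    return AnalysisReport(analyses=analyses, seed=seed, n_random=n_random,
                          steps=steps, r2_min=r2_min)


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Serialize the parameter table, module tables and dendrograms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.params_table().to_csv(out / "network_params.csv", index=False)
    run_info = {
        "seed": report.seed, "n_random": report.n_random,
        "steps": report.steps, "r2_min": report.r2_min,
    }
    (out / "run_info.json").write_text(json.dumps(run_info, indent=2) + "\n")
    for a in report.analyses:
        stem = f"{a.name}_{a.system}"
        rows = [
            {"label": l, "module": m} for l, m in sorted(a.partition.assignment.items())
        ]
        pd.DataFrame(rows).to_csv(out / f"{stem}_modules.csv", index=False)
        (out / f"{stem}_dendrogram.nwk").write_text(a.dendrogram.to_newick() + "\n")
    return out


def compare_reports(
    report_a: AnalysisReport,
    report_b: AnalysisReport,
    system: str = "musculoskeletal",
    label_map: Mapping[str, str] | None = None,
    groupings: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise similarity of every network in A against every network in B.

    Reports the co-classification ratio and the NMI similarity for the
    requested system; ``groupings`` (name -> label -> group) are compared
    by NMI against every partition of report A.
    """
    rows = []
    for a in report_a.analyses:
        if a.system != system:
            continue
        for b in report_b.analyses:
            if b.system != system:
                continue
            sim = compare.partition_similarity(a.partition, b.partition, label_map)
            nmi = compare.nmi_similarity(
                a.partition,
                b.partition if label_map is None
                else _remap(b.partition, label_map),
            )
            rows.append({
                "network_a": a.name, "network_b": b.name, "system": system,
                "kind": "partition", "n_common": sim.n_common,
                "similarity_ratio": sim.ratio, "similarity_percent": sim.percent,
                "nmi": nmi.nmi, "nmi_percent": nmi.similarity_percent,
            })
        for gname, grouping in (groupings or {}).items():
            nmi = compare.nmi_similarity(a.partition, grouping)
            rows.append({
                "network_a": a.name, "network_b": gname, "system": system,
                "kind": "grouping", "n_common": len(set(a.partition.assignment) & set(grouping)),
                "similarity_ratio": None, "similarity_percent": None,
                "nmi": nmi.nmi, "nmi_percent": nmi.similarity_percent,
            })
    return pd.DataFrame(rows)


def _remap(p: community.ModulePartition, label_map: Mapping[str, str]) -> dict[str, int]:
    inv = {str(v).strip(): str(k).strip() for k, v in label_map.items()}
    fwd = {str(k).strip(): str(v).strip() for k, v in label_map.items()}
    return {fwd.get(l, inv.get(l, l)): m for l, m in p.assignment.items()}
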