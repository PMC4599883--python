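#!/usr/bin/env python
"""Generate the synthetic study networks.

Builds two limb-like musculoskeletal networks (stand-ins for an upper- and
a lower-limb dataset: same body plan, different random muscle routing) and
a planted-partition benchmark, and writes them as adjacency CSVs with
metadata sidecars under results/data/. Every later analysis step reads
these files, so the whole analysis is reproducible from this script alone.
"""

from pathlib import Path

from anatomynet import io
from anatomynet.synth import LimbLikeSpec, PlantedPartitionSpec, limb_like_network, planted_partition_graph

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

for name, seed in [("limb_UL", 0), ("limb_LL", 1)]:
    net = limb_like_network(LimbLikeSpec(seed=seed))
    net.meta.update({"limb": name.split("_")[1], "condition": "synthetic-adult"})
    path = io.write_adjacency_csv(net, OUT / f"{name}.csv")
    skel = io.extract_subsystem(net, "skeletal")
    mus = io.extract_subsystem(net, "muscular")
    print(f"{name}: {net.n_nodes} elements / {net.n_edges} contacts "
          f"(skeletal {skel.n_nodes}/{skel.n_edges}, muscular {mus.n_nodes}/{mus.n_edges}) -> {path.name}")

bench, truth = planted_partition_graph(PlantedPartitionSpec(seed=1))
io.write_adjacency_csv(bench, OUT / "planted_benchmark.csv")
(OUT / "planted_benchmark_truth.csv").write_text(
    "label,module\n" + "\n".join(f"{l},{m}" for l, m in sorted(truth.assignment.items())) + "\n"
)
print(f"planted benchmark: {bench.n_nodes} nodes / {bench.n_edges} edges, "
      f"4 planted modules (ground-truth Q={truth.q:.3f})")
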