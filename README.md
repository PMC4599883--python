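# anatomynet

Anatomical network analysis of musculoskeletal systems.

Morphologists studying modularity and integration need to compare body
parts built from very different tissues — bones, cartilages and muscles —
on an equal footing. This package does that by modeling an anatomical
system as an undirected, unweighted network: nodes are anatomical parts,
edges are their physical contacts (articulations between bones, fusions
and shared tendons between muscles, bone–muscle attachments). The topology
of that network, not the geometry of the parts, is what gets quantified
and compared, which makes upper-vs-lower-limb, newborn-vs-adult and
normal-vs-pathological comparisons direct and quantitative.

## What it computes

**Global parameters.** For a network with `N` nodes and `K` edges:
density `D = 2K/(N(N−1))`; mean clustering coefficient
`C = (1/N) Σᵢ 2τᵢ/(kᵢ(kᵢ−1))` (nodes with degree < 2 contribute 0);
mean shortest path length `L` over reachable pairs; the diameter; and
degree heterogeneity `H = σ_k/μ_k`.

**Small-world test.** `C` and `L` are compared with the means over an
ensemble (default 10,000) of uniform random graphs with the same `N` and
`K`; the size-corrected criterion is

```
swi = (C/C_rand) / (L/L_rand)  ≥  0.012 · N^1.11
```

**Hierarchy test.** Log–log least-squares fits of the degree distribution
`P(k) = n_k/N` and the clustering-by-degree profile `C(k)`; a hierarchical
verdict requires both fits to reach a configurable R² (default 0.7) with a
negative `C(k)` slope.

**Connectivity modules.** A from-scratch 3-step walktrap: communities are
agglomerated by minimizing the Ward-style cost
`Δσ(C₁,C₂) = (1/n)·|C₁||C₂|/(|C₁|+|C₂|)·Σ_k (P^t_{C₁k} − P^t_{C₂k})²/d_k`
built from t-step random-walk transition probabilities, merging only
edge-adjacent communities. Every cut level of the resulting dendrogram is
scored with Newman's modularity
`Q = (1/2K) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2K] δ(mᵢ,mⱼ)` and the max-Q partition is
returned (isolated parts stay singleton modules). `python-igraph`'s
walktrap is used in the test suite as an independent cross-check, never as
the implementation.

**Partition comparison.** Co-classification similarity (optimal one-to-one
module matching on the overlap contingency table; matched elements /
common elements), normalized mutual information (1 = identical), and a
proximal-vs-distal comparison of sub-network parameter vectors. Cross-limb
comparisons take an explicit serial-correspondence label map
(humerus↔femur, …) — never fuzzy name matching.

**Synthetic generators.** `planted_partition_graph` (ground-truth modules
for recovery benchmarks) and `limb_like_network` (sparse tree-like
skeleton, near-empty muscular layer, attachment-driven triangles in the
musculoskeletal layer) make the full pipeline testable without any data
download.

## Worked example

```python
from anatomynet import (LimbLikeSpec, limb_like_network, extract_subsystem,
                        basic_params, detect_modules)

limb = limb_like_network(LimbLikeSpec(seed=0))
skel = extract_subsystem(limb, "skeletal")
print(basic_params(skel))
# NetworkParams(N=34, K=38, D=0.0677..., C=0.1196..., L=5.4135...,
#               diameter=12.0, H=0.3921...)
dend, part = detect_modules(limb)
print(part.n_modules, round(part.q, 3))
# 11 0.529
```

The skeletal layer is sparse (`D ≈ 0.07`) and weakly clustered; adding the
40 muscles and their attachments raises mean clustering from 0.120 to
0.242 and yields 11 musculoskeletal modules at `Q ≈ 0.53` — bones and
muscles grouped together by shared attachment neighborhoods, the module
structure the method is designed to expose.

The `analysis/` scripts run the same pipeline as a narrative: generate the
synthetic limbs (`01`), tabulate parameters (`02`), run the null-model
verdicts (`03`), detect modules (`04`) and compare limbs (`05`), writing
tables under `results/`. The command-line interface does the same for any
adjacency CSV: `anatomynet analyze mynet.csv --seed 1`.

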