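# Methods

## The model

An anatomical system is represented as a simple, undirected, unweighted
graph. Nodes are anatomical parts; for a musculoskeletal network both
bones/cartilages and muscles are nodes, and an edge records any physical
contact: an articulation between two bones, a fusion or shared tendon
between two muscles, or a muscle's attachment to a bone. Layers are
induced subgraphs by tissue class: the skeletal layer keeps only
bone/cartilage nodes, the muscular layer only muscles. Multiplicity and
strength of contacts are deliberately discarded (a 1/0 relation): the
claim under study is about which parts touch which, not how strongly.

On disk a network is a square 0/1 CSV with a header row and first-column
labels, plus a YAML sidecar with per-node tissue class, optional
proximal/distal region tags and free-form metadata. Validation is strict
and never repairs input: asymmetry, non-binary entries, a nonzero
diagonal, duplicate labels and missing tissue classes each raise their own
exception. Labels are whitespace-trimmed but never fuzzily matched,
because all partition comparisons rest on exact label identity.

## Global parameters

For `N` nodes and `K` edges we report density `D = 2K/(N(N−1))`, mean
clustering `C`, mean geodesic `L`, the diameter, and degree heterogeneity
`H = σ_k/μ_k`. Two conventions need stating because usage differs across
toolkits:

* **Clustering of low-degree nodes.** `Cᵢ = 2τᵢ/(kᵢ(kᵢ−1))` is defined as
  0 for degree < 2, and the mean divides by `N` (all nodes), matching the
  "arithmetic mean over all nodes" reading of the parameter.
* **Path length on disconnected graphs.** `L` and the diameter average and
  maximize over *reachable* unordered pairs only. Muscular layers are
  mostly isolated nodes; an infinity-penalizing convention would make the
  parameter meaningless exactly where the comparison is most interesting.
  An edgeless network reports `L = diameter = 0`.

## Small-world assessment

Null model: the uniform distribution over simple graphs with the same `N`
and `K` ("same nodes, re-connected at random"), sampled as G(N, M) graphs
— not degree-preserving rewiring, which would fix the degree sequence the
heterogeneity parameter is meant to measure. Ensemble means `C_rand`,
`L_rand` use the conventions above. The verdict uses the size-corrected
criterion `swi = (C/C_rand)/(L/L_rand) ≥ 0.012·N^1.11`. The default
ensemble size is 10,000; tests and the acceptance script use 1,000, at
which the standard error of the ensemble means is already one to two
orders of magnitude below the effects being judged (the `C_sd`/`L_sd`
fields expose this). When `C_rand` or `L` is zero (degenerate sparse
networks) the assessment is explicitly "not assessable" rather than a
verdict or a crash. One master seed drives per-replicate seeds through a
`SeedSequence`, so summaries are bit-for-bit reproducible.

## Hierarchy assessment

`P(k) = n_k/N` and `C(k)` (mean clustering of degree-k nodes) are fitted
by least squares in log–log space over strictly positive points; fewer
than three usable points on either profile gives "not assessable". The
verdict is hierarchical iff both fits reach `r2_min` and the `C(k)` slope
is negative (clustering concentrated at low degree, the signature of
nested cohesive groups). `r2_min` defaults to 0.7; no canonical threshold
exists for this test, so the criterion string is recorded in every result
rather than hidden. A maximum-likelihood tail fit would be the wrong tool
here: the profiles have a handful of support points on networks of this
size, and the question is a coarse shape diagnosis, not a tail-index
estimate.

## Walktrap modules and max-Q selection

The community search is a faithful reimplementation of the short-random-
walk agglomeration. Per connected component: transition probabilities are
those of the *lazy* walk (a self-loop added at every vertex, degrees
counting the loop), as in the algorithm's reference implementation —
without laziness the 3-step kernel oscillates on bipartite-like chains and
the merge order diverges from the published behavior. From the t-step
kernel (t = 3 by default) each community keeps the mean probability vector
of its members; only edge-adjacent communities may merge, and each step
merges the pair minimizing the Ward-style cost Δσ. After a merge the cost
to every neighbor is recomputed exactly from the merged mean vector, which
is algebraically identical to the published Lance–Williams update (and
also covers neighbors adjacent to only one of the merged pair, where the
update form is undefined). Ties in Δσ break toward the lowest community
index pair, making dendrograms deterministic.

Modularity `Q` is evaluated as the ordered-pair double sum with the
diagonal included, computed module-wise as `Σ_c [L_c/K − (d_c/2K)²]`.
Because that sum separates over connected components, the max-Q cut is
selected per component over all of its dendrogram levels (from
all-singletons to one block), with ties broken toward fewer modules;
isolated nodes are singleton modules. This convention is what reproduces
the "every unconnected muscle is its own 1-muscle module" accounting in
muscular layers.

Agreement with `python-igraph`'s walktrap is measured, not assumed: on 50
random connected graphs (N ≤ 60) module counts coincide in ≥ 90% of cases,
and on exhaustive tiny-graph benchmarks the two implementations return
exactly the same Q. Residual disagreements trace to floating-point merge-
order ties, and the measured gap of the heuristic to the exhaustively
enumerated global Q optimum on tiny graphs is reported by the test suite
(mean ≤ 0.05 on the benchmark draw; individual graphs can exceed it, and
the reference implementation exceeds it on exactly the same graphs).

## Partition comparison

The co-classification similarity restricts both partitions to their common
elements, builds the module-overlap contingency table, finds the
one-to-one module correspondence maximizing total overlap (Hungarian
assignment), and divides matched elements by common elements. Optimal
assignment makes the score deterministic and symmetric; greedy matching
would be neither. NMI uses the arithmetic-mean normalization
`2I/(H_A+H_B)` and is oriented so identical partitions score 1, with
"similarity %" = 100×NMI; two single-group divisions are defined as
identical (NMI 1). Comparisons between different limbs require an
explicit, editable serial-correspondence table (e.g. humerus↔femur);
the package never infers correspondences from names.

Proximal/distal comparisons split each limb by its region tags (girdle and
stylopod structures, and muscles attached to them, are proximal; zeugopod
and autopod structures distal), compute the global parameters of the four
subgraphs, and score prox-vs-prox and dist-vs-dist by the mean absolute
relative difference of (D, C, L, H), where each term is normalized by the
pair mean and a 0/0 term contributes 0. The score is symmetric, 0 for
identical vectors, and "not assessable" when a region subgraph is empty.

## Synthetic generators

`planted_partition_graph` draws independent Bernoulli edges with
within-module probability `p_in` and between-module probability `p_out`
(defaults 4×20 nodes, 0.5/0.02 — a regime where module recovery should be
essentially exact, verified by a 20-seed benchmark, and degrade
monotonically as `p_out/p_in` grows).

`limb_like_network` emulates the three layers' topology at the scale of a
real limb: a girdle clique wired to a stylopod bone, two zeugopod bones, a
carpal chain, and digit chains of metacarpal + phalanges (default 34
bones, 38 articulations, density ≈ 0.07, skeleton connected); 40 muscles,
each with an origin (proximal pool with probability 0.5, otherwise distal)
and a distal insertion, usually (probability 0.7) also gripping a skeletal
neighbor of the insertion — it is these joint-spanning attachments that
create the triangle surplus of musculoskeletal over skeletal layers; and
rare muscle–muscle fusions (probability 0.05 per muscle), leaving the
muscular layer almost edgeless. What the generator does **not** emulate:
real articulation geometry, left/right asymmetries, the specific module
composition of any real limb, or degree correlations beyond those implied
by the body plan. Passing tests therefore demonstrate that the pipeline's
statistics behave correctly on networks with the right coarse structure,
not that any particular anatomical claim about real limbs is reproduced;
real analyses should load dissection-derived adjacency matrices through
`anatomynet.io`.

## Problem sizes and numerical choices

Test-suite and acceptance-script sizes are chosen so every stage runs in
seconds while keeping the estimates' standard errors well below the
asserted margins: 1,000-replicate ensembles (the `1/√n` convergence of the
ensemble means is itself under test), 20-seed recovery benchmarks on
80-node graphs, 50-graph cross-validation at N ≤ 60. Brute-force oracles
(all-pairs BFS, triangle enumeration, literal double-loop modularity,
direct entropy NMI) live in the test suite and are never imported by the
package. Floating-point ties in max-Q cut selection are resolved within a
1e-12 tolerance toward fewer modules.

## Known limitations

* Walktrap is a heuristic; its max-Q cut can miss the global modularity
  optimum, and implementations can differ at floating-point ties. Module
  *counts* are therefore the robust comparator, and cross-implementation
  agreement is monitored rather than presumed.
* The hierarchy verdict depends on the declared `r2_min`; verdicts near
  the threshold should be read as "borderline", and the underlying fits
  are always reported alongside the boolean.
* The G(N, M) null model conditions only on N and K. Networks whose
  interesting structure lies in the degree sequence itself will look
  "non-random" under this null by construction; that is intended, but
  worth remembering when interpreting `swi`.
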