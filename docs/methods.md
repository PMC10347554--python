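# Methods

## The graph class

A *mitochondria-like graph* is an undirected, simple, planar graph in
which every node has degree 1 or 3, possibly disconnected.  Degree-1
nodes are tubule tips, degree-3 nodes are Y-junctions.  Degree-2 nodes
have no biological interpretation and degree ≥ 4 junctions are treated as
transient, so neither is a member of the class; both remain representable
in `MLGraph` because rewriting passes through them internally.  Planarity
reflects the cortical tethering of budding-yeast mitochondria: the
network lives on (a patch of) the sphere.  Edge lengths, where present,
are tubule lengths in micrometres and are strictly positive; isomorphism
is always decided on the unweighted graph.

Immediate consequences used throughout: Σ deg = 2|E| (so n₁ + 3n₃ = 2|E|
and |V| is even because all degrees are odd); the Euler relation
|V| − |E| + |F| − C = 1 with the outer face counted (χ = |V| − |E| + |F| = 2
for one component on the sphere).  The face-count bound
|E| ≤ 3|V| − 3 − 3C requires every face to be bounded by at least three
edges; it fails for the two-node tubule (|E| = 1 > 0), the usual |V| ≥ 3
caveat of the planar edge bound.  The validator therefore checks degrees,
simplicity, parity and planarity, not the edge bound.

The dispersion fraction α is the share of degree-1 nodes whose sole
neighbor is also degree-1, i.e. tips sitting on isolated two-node
tubules; α := 0 when there are no tips (no tips means no tip adjacency,
and it avoids 0/0).

### Canonical certificates

Certificates must be exact: equal iff isomorphic.  1-WL hashing cannot
promise this for regular graphs, and cubic graphs are regular, so the
package implements individualization–refinement canonical labeling per
connected component (1-WL color refinement; branch on the first
non-singleton cell; keep the minimum adjacency code over branches) and
joins sorted component codes.  Tests cross-check certificate equality
against VF2 isomorphism on all class pairs up to 6 nodes and against
adversarial regular pairs (triangular prism vs K₃,₃).  Planarity is
decided by the left–right test; a brute-force Wagner-minor oracle (no K₅
or K₃,₃ minor) confirms it on graphs of ≤ 6 nodes in the test suite.

## Morphological operations

Seven guarded rewriting rules, each returning *applied* with a result
that is again mitochondria-like, or *rejected* with a named reason.
Type 1 moves keep the component count; Type 2 fission splits one
component, Type 2 fusion joins two.

* **Fission** severs an edge and caps both stumps with new tips
  (Δn₁ = +2).  The break sits at a configurable fraction of the edge
  length (default midpoint).
* **Tip–tip fusion** deletes two tips and joins their anchors
  (Δn₁ = −2).  Rejected when the tips are adjacent (the product would be
  the excluded toroidal "donut"), when the anchors are already joined
  (parallel edge), or when the product is non-planar.  The two consumed
  tip edges concatenate, so length is conserved.
* **Tip–side fusion** turns a tip into a junction planted in the middle
  of a target edge (Δn₁ = −1, Δn₃ = +1).  The target may be neither the
  tip's own edge nor any edge at its anchor — the |E|−1 / |E|−3
  eligible-edge bookkeeping of the rate equation — and the product must
  stay planar.  The target's length splits at the new junction.
* **Outgrowth** subdivides an edge with a new junction and hangs a new
  tip on it (Δn₁ = Δn₃ = +1); always planar-safe.  The new tip edge
  defaults to 0.5 µm, the minimal tubule unit (the diameter at which
  tubules revert to spheroids).
* **Resorption** removes a pendant tip whose neighbor is a junction and
  smooths the resulting degree-2 node into a through-edge
  (Δn₁ = Δn₃ = −1).  Rejected when smoothing would create a parallel
  edge (pendant on a triangle) and when the neighbor is itself a tip
  (isolated tubules belong to mitophagy).  The pendant tubule is
  *absorbed*: the smoothed edge carries the sum of all three former
  lengths, so total length is conserved.
* **Mitophagy** deletes a component that is a single two-tip tubule
  (Δn₁ = −2); nothing else is degradable, and deleting the last tubule
  leaves the (valid) empty graph.
* **Vertex flip** (T1 transition) lets two adjacent junctions exchange
  one neighbor each; both candidate exchanges are returned, each guarded
  for simplicity and planarity; (n₁, n₃, |E|) never change.

Fission/tip–tip fusion and outgrowth/resorption are mutually inverse up
to isomorphism; mitophagy has no single-step inverse.  Junction fission
(breaking a Y into a tip and a tubule) is excluded for lack of biological
evidence.  The planarity guard on fusion and flips is a modeling choice:
the product of a physically tethered network cannot leave the surface, so
moves whose product is non-planar are simply unavailable.

`enumerate_moves` lists every distinct legal application and aggregates
by (operation, resulting isomorphism class); the multiplicity of an entry
counts distinct applications landing in the same class (e.g. fission of
the six equivalent edges of K₄ gives one entry of multiplicity 6).

## Enumeration and counting

Connected representatives on n nodes are generated exhaustively: for each
split of n into tips and junctions with an even stub total, all labeled
simple graphs realizing the degree sequence are built by recursive
saturation of the lowest-index node (each labeled graph exactly once),
filtered for connectivity and planarity, and deduplicated by certificate.
The default refusal threshold is n = 12.

Totals over possibly-disconnected graphs follow from connected counts via
a partition sum: each partition K of n contributes
∏_k multichoose(connected(k), m(k,K)) over its distinct part sizes, the
combinations-with-replacement accounting for identical components
appearing in duplicate.  The inner count is deliberately read as the
*connected* count (the self-referential reading would double-count); the
reading is validated by exact agreement with direct exhaustive generation
of the disconnected graphs for n ∈ {2, 4, 6, 8}: counts 1, 3, 8, 28
(connected: 1, 2, 5, 17).  The empty graph counts as 1 (empty product).

Growth bounds as printed: upper 30.061^n per vertex from
information-theoretic planar-graph counting; lower
1.255·2.48^n/n^2.5 + 0.009099·7.5036^n/n^2.5 assembled from asymptotics
of connected cubic outerplanar graphs and of unrooted degree-1/3 trees.
**The lower expression is asymptotic only**: at small n it exceeds the
true count (n = 2: 1.46 vs 1; n = 8: 515 vs 28), so the package reports
it verbatim but does not assert it as a finite-n bound.  The upper bound
holds at every n we can test: 28^{1/8} ≈ 1.52 « 30.061.

## Kinetics

Process rates β_{X,Y} (contribution of process X to degree-Y nodes), with
k's the per-unit-time rate constants:

```
β_fis,1 = 2 k_fis |E|
β_ttf,1 = -(1/2) k_tt [ αn₁(αn₁-2) + 2α(1-α)n₁²
            + (1/2) Σ_{v∈L(G)} ( 2(1-α)n₁ - 2 - Σ_{u∈N₂(v)∪N₃(v)} (3-deg u) ) ]
β_tsf,1 = -k_ts [ αn₁(|E|-1) + (1-α)n₁(|E|-3) ]
        = -(1/2) k_ts n₁ [ n₁ + 3n₃ + 4α - 6 ]          (identical forms)
β_tsf,3 = -β_tsf,1
β_out,1 = β_out,3 = k_out |E|
β_res,1 = β_res,3 = -k_res (1-α) n₁
β_aut,1 = -2 k_aut α
```

dn₁/dt sums the six degree-1 terms; dn₃/dt = β_tsf,3 + β_out,3 + β_res,3.
Fusions are second order (they need partners); everything else is at most
first order.  The leaf-neighborhood sum in β_ttf subtracts fusion
partners that would create loops or parallel edges within 2–3 hops of
each tip.  Two evaluation routes exist: the graph route computes the sum
exactly; the continuum route, which only sees (n₁, n₃, α), sets the
neighborhood correction to zero — exact for fully dispersed graphs, a
mean-field approximation otherwise.  The mean-field tip-pair counting of
β_ttf does not coincide with the exact count of legal unordered tip-pair
fusions (for two isolated tubules the formula gives rate 2·k while 4
legal pairs exist); `tt_fusion_pair_count` exposes the exact count so the
discrepancy can be measured per graph rather than silently "fixed".
Mitophagy is modeled at constant rate −2 k_aut α as printed, not scaled
by the number of isolated tubules.

Rate constants have no canonical values; every API takes a `RateModel`
(defaults 1.0).  `k_flip` exists for stochastic simulation only — flips
conserve (n₁, n₃) and never enter the node-count kinetics.

### Steady-state relation and model selection

Setting dn₁/dt = dn₃/dt = 0 reduces the balance to
a₀n₁ + a₁n₃ + a₂ = b₀n₁² + b₁n₁n₃ + b₂n₁, i.e.
n₃ = (−b₀n₁² + (a₀−b₂)n₁ + a₂) / (b₁n₁ − a₁).  Positive large-n₁ scaling
of n₃ rules out the full rational form, leaving the quadratic law
(b₁ = 0) and the linear law (b₀ = b₁ = 0).  Only the polynomial n₃(n₁) is
identified by regression; the (aᵢ, bⱼ) are a gauge, normalized here as
a₁ = 1, a₀ = 0 (so b₀ = quadratic coefficient, b₂ = slope,
a₂ = −intercept, b₁ = 0).

`SteadyStateModel.fit()` fits the linear law by OLS and the quadratic law
under its positivity constraint on the leading coefficient.  The
constraint is a single bound, so the constrained optimum is the exact KKT
solution: the unconstrained OLS quadratic if its leading coefficient is
non-negative, else the linear fit (boundary active).  The quadratic
coefficient counts as *collapsed* — and the linear law is selected — when
the boundary is active, when |q₂|·max(n₁)²/max|n₃| < 1e-8, or when q₂ is
not significantly positive (one-sided z ≤ 2 using the OLS standard
error).  The significance clause is this package's operationalization of
"the quadratic coefficient tends to zero": under linear truth the
sampling noise puts a small positive q₂ in about half of datasets, and a
pure magnitude threshold would mistake that noise for curvature.  On
linearly generated data the linear law is selected in ≥ 95% of
replicates with nominal slope coverage; on data generated with a genuine
quadratic term the quadratic is selected and its coefficient recovered.
Inference for a selected quadratic reuses the (coincident) unconstrained
OLS fit.

### Stochastic simulation and state space

`gillespie_trajectory` simulates the jump process exactly: every legal
application of an active operation is a reaction channel with propensity
equal to its rate constant, waiting times are exponential in the total
propensity.  `build_state_space` closes the move relation
breadth-first over isomorphism classes from seed graphs, truncated at a
node bound (the untruncated space is infinite); transitions are directed
(operations are not self-inverse) and aggregated per (source, target,
operation) with multiplicities, rate weight = constant × multiplicity.
Structure-dependent rates are evaluated on each source state's
representative.  Stationary laws solve πQ = 0 (generator rows sum to
zero; residual ‖πQ‖∞ < 1e-10 asserted); reducible chains are restricted
to the recurrent class containing the seed, or the unique terminal class
reachable from it (with mitophagy active the empty graph is absorbing and
receives all mass).  Whether the truncated space is strongly connected is
reported as a diagnostic, not asserted — reachability of the whole class
is an open question.

## Persistent homology

Filtration: every node is a ball of radius ε; an edge enters when ε
reaches half its weight; the flag (clique) complex of the present edges
is taken at every scale.  Modes: `weighted` (tubule lengths, µm),
`unweighted` (all edges at ε = 0.5 — coarse by construction, retained for
completeness), `geodesic` (complete graph on shortest-path distances;
infinite pairs never enter, so components stay separate).  A 3-cycle is
filled by its triangle the instant it forms, so H₁ counts only cycles of
≥ 4 edges; simplices are built through dimension 3 (tetrahedra), enough
for H₂ in geodesic mode and never beyond.

Computation is standard boundary-matrix reduction over GF(2) with columns
as bitmask integers; zero-persistence pairs are discarded; essential
classes carry infinite death, and the number of essential H₀ bars equals
the component count.  The test suite checks the reduction against an
independent rank-based oracle (persistent Betti numbers by GF(2) rank,
bars by inclusion–exclusion on the value grid) on every class up to 8
nodes with random lengths, and against the circuit-rank identity
(|E| − |V| + C retained H₁ bars) on triangle-free graphs.

Bottleneck distance: minimal max-cost perfect matching between two
diagrams with diagonal projections, computed exactly by binary search
over candidate costs (all point–point and point–diagonal distances) with
Hopcroft–Karp feasibility.  The ground metric defaults to *euclidean*,
matching the verbal definition of the pipeline being reproduced; the
conventional Chebyshev (L∞) metric is also provided.  They differ by
exactly √2 on diagonal projections: a single point (b, d) against the
empty diagram costs |d−b|/√2 euclidean and (d−b)/2 Chebyshev.  Essential
bars are truncated at a cap before matching (the heatmap pipeline
requires finite distances); the cap defaults to 1.1 × the largest finite
coordinate across the diagrams being compared (shared across a whole
cohort in `cohort_comparison` so its distances are mutually comparable)
and is configurable.

## Synthetic data

`generate_population` evolves each network independently from a single
two-node tubule by the Gillespie process and records the endpoint, then
draws edge lengths log-normally (defaults µ_log = ln 1.0 µm,
σ_log = 0.5 — no length distribution is canonical; log-normal is chosen
for positivity and right skew).  Defaults: t_max = 1.5, node cap 16,
population 50.

* `wildtype` rates (k_fis 0.8, k_tt 0.5, k_ts 0.5, k_out 0.9, k_res 0.3,
  k_aut 0.05, k_flip 0.1): all processes active; same-component fusions
  create cycles, and ≥ 20% (in practice ~60–80%) of endpoints are cyclic.
* `dko` rates (only outgrowth 1.0 and resorption 0.3): the fission–fusion
  double-knockout condition; every endpoint is a tree.  Mitophagy is also
  disabled: without fission a single-component tree never fragments into
  the isolated two-node tubules mitophagy consumes, so a nonzero rate
  could only ever delete the entire network.

What the generator does *not* emulate: spatial embedding in a cell,
microscopy segmentation noise, degree-2 skeleton artifacts, correlated
rates, or volume conservation.  Passing population-level tests therefore
demonstrates that the *pipeline* separates cycle-rich from tree-like
populations under controlled conditions, not that it will separate any
two real strains.

`generate_n1n3_data` draws n₁ uniformly over a positive range (default
2–40), places n₃ on a chosen steady-state law plus Gaussian noise and
floors at zero.

## Problem sizes and numerical conventions

Exhaustive enumeration is exercised to n = 8 (28 classes; ~1 minute);
the refusal threshold is n = 12.  Population tests use 50 graphs per
style for composition statistics (200 for the cross-seed stability check
on the fast tree-like style) and 20 + 20 for the cohort comparison.
Model-selection replication uses 50 datasets of 200 points.  Stationary
residual tolerance 1e-10; generator row sums 1e-12; length conservation
1e-9; the two printed tip–side forms agree to 1e-12.  Ties in the
filtration are broken by (value, dimension, vertex tuple), which is
immaterial for the diagram.  All randomness flows through explicit seeds;
populations are reproducible from a single integer.

## Known limitations

* The state space is truncated by node count; stationary laws are for the
  truncated chain, not the infinite process.
* Bottleneck matching is exact but O(candidates · matching); diagrams
  with thousands of points would need the usual geometric accelerations.
* The unweighted filtration collapses all edges to one scale and is
  correspondingly uninformative; prefer geodesic mode for unweighted
  input.
* Embedded-graph equality (isotopy), Wasserstein distances, persistence
  vineyards, and hypergraph/pseudograph representations (e.g. toroidal
  "donut" mitochondria) are out of scope.
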