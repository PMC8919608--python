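# Methods

## Problem setting

A tumor's clonal decomposition inferred from one mutation feature class
is a partition of its cells; decompositions from two feature classes
(SNV clones `Π1`, CNA clones `Π2`) are both coarsenings of the true
clonal partition, so the true clones can be represented as pairs
`Π ⊆ Π1 × Π2`. Consistency of integrated proportions `U` with the input
proportion matrices `U1`, `U2` means both marginals match exactly, per
sample and per clone. PCI asks for the smallest consistent `Π`; PCTI
additionally takes per-feature clone trees and asks, over all
*refinements* of the two trees, for the proportions minimizing the total
L1 correction `J(U, U1, U2)`. Refinements are trees on paired clones in
which every edge changes exactly one coordinate, and every input edge is
realized exactly once; consequently a refinement always has
`n1 + n2 − 1` vertices and root `(r(T1), r(T2))`.

Inputs are taken at face value as already-deconvolved clone proportions;
nothing here re-estimates clones from reads, VAFs or copy-number
segments.

## Exact solvers

Both problems are solved as mixed-integer linear programs with the HiGHS
branch-and-bound solver (`scipy.optimize.milp`), with a default relative
MIP gap of 0 — the PCI objective is a small integer and the PCTI
objective a small sum of fractions, so exact optimality is cheap at the
instance sizes deconvolution produces (tens of clones, ≤ ~10 samples).

**PCI.** Binary `x[i,j]` selects pair `(i,j)`; continuous
`u[p,i,j] ∈ [0,1]` with `u[p,i,j] ≤ x[i,j]` and exact marginal
equalities `Σ_j u[p,i,j] = u1[p,i]`, `Σ_i u[p,i,j] = u2[p,j]`; objective
`min Σ x`. The marginal equalities imply unit row sums, and feasibility
is guaranteed (the full pair set with greedy mass-matching proportions
is always consistent).

**PCTI.** The same `x` and `u`, now with explicit unit-row-sum
constraints and correction variables `c1[p,i], c2[p,j] ≥ ±(marginal −
input)` bounding the absolute deviations from both sides; objective
`min Σ c`. Refinement is enforced through continuous `z` variables
linearizing the products `z1[e,j] = x[i,j]·x[i',j]` for each edge
`e = (i,i')` of `T1` (three inequalities per product; binary `x` forces
`z` integral) with `Σ_j z1[e,j] = 1`, and symmetrically for `T2`. Two
additional constraints complete the characterization: `Σ x = n1 + n2 − 1`
and `x[r(T1), r(T2)] = 1`. Without them the edge-realization constraints
admit spurious selections — an extra pair that is isolated from every
realized edge, or a vertex set whose realized edges form a tree missing
the root pair. With them, a feasible `x` has `n1 + n2 − 1` selected
vertices carrying `(n1 − 1) + (n2 − 1)` distinct realized edges; a cycle
would traverse some input edge in two different contexts, violating the
exactly-once constraints, so the realized edges form a spanning tree of
the selection, and orienting it away from the root pair projects onto
each input tree's own orientation. Solver outputs are therefore
reconstructed from the `z` values and re-checked post hoc
(`check_refinement`, and `J` recomputed from `U` within `1e-5`); a
violation raises rather than returning a silently wrong answer.

No warm start is supplied to the MILP; at the exercised scales the solver
finishes in milliseconds without one.

## Oracles and polynomial building blocks

* *Fixed clone set feasibility*: with one sample, the question "does a
  consistent `U` exist on this pair set?" is a maximum-flow problem
  (source → `Π1` clones → `Π2` clones → sink, outer arcs capacitated by
  the input proportions); feasible iff the flow value is 1, and the pair
  arc flows are the proportions. Capacities are scaled to integers
  (×10⁹) so the flow computation is exact. With several samples the
  constraints separate, so each sample is an independent LP with exact
  marginal equalities — the multi-sample coupling only matters when the
  clone set itself is being chosen. A property test confirms flow and LP
  agree on single-sample feasibility.
* *PCI brute force*: enumerate pair subsets by increasing size from the
  support bound, skipping subsets that fail to cover every supported
  input clone, testing each with the feasibility routine. Guarded to
  `n1·n2 ≤ 20` pairs.
* *PCTI brute force*: a refinement is determined by assigning each `T1`
  edge the `Π2`-context `j` in which it occurs and each `T2` edge its
  `Π1`-context; an assignment is valid iff the implied vertices are
  distinct and every created vertex's parent exists. Enumerating
  assignments (guarded at 12 combined edges / 5·10⁶ combinations) yields
  each refinement exactly once; each is scored by a per-sample LP
  minimizing `J` with the pair set fixed. The minimum and the number of
  co-optimal refinements are reported — solution multiplicity is real
  and grows as samples decrease.

Both MILPs are tested for exact agreement with these oracles on 50
random instances each (`n1, n2 ≤ 4`).

## Candidate-tree selection

When one feature's tree is not provided upstream, all rooted labeled
trees on its clone set (`k^(k−2)` by Cayley's formula, generated from
Prüfer sequences and oriented away from the declared root) are
integrated one by one, keeping the tree with the smallest `J` and
reporting ties. Rooted labeled trees on the clones are the natural
candidate space here because refinement is defined on vertex-labeled
clone trees; leaf-labeled binary trees with unlabeled internal vertices
would not compose with the refinement definition. Ties are common at low
sample counts and are surfaced rather than broken silently.

## Simulator

Ground truth is a random paired clone tree grown from the root `(1,1)`:
the pooled `n1 − 1` SNV events and `n2 − 1` CNA events are applied in a
uniformly random order, each attaching a new vertex to a parent chosen
uniformly among existing vertices (label = parent's label with the
event's coordinate overwritten; distinct event values make labels
automatically unique). Collapsing the other feature's edges yields the
input trees. Proportions are per-sample symmetric Dirichlet draws
(concentration 1 by default — uniform on the simplex, the standard
choice for simulating clone fractions); the inputs are their exact
marginals, perturbed by convex mixing: `(1 − h)·row + h·fresh Dirichlet
draw`. The mixing reading of the noise model keeps rows on the simplex
and makes `h = 0` exactly noise-free and `h = 1` pure noise; the noise
function is pluggable should a different error model be wanted. One
seeded generator drives tree, proportions and noise jointly, so bundles
are bit-reproducible from `(config, seed)`.

What the simulator does *not* emulate: read-count sampling noise
(errors enter proportions directly, not through coverage), mutation-level
miscalling or misclustering (clone identities are never wrong, only
proportions), and sample-specific error levels. Passing recovery tests
therefore demonstrates correctness of the integration machinery under
calibrated proportion error, not robustness to upstream deconvolution
failure modes.

The 3-partition reductions double as adversarial generators: a multiset
`A` of `3q` integers in `(B/4, B/2)` summing to `Bq` maps to a
single-sample PCI instance (`u1 = a_i/(Bq)`, `u2 = 1/q`) whose optimum
is `3q` iff `A` partitions into `q` triples summing to `B`, and to a
PCTI instance (zero-proportion normal clone, star trees) with an
error-free `4q + 1`-clone refinement iff solvable. The test suite uses a
hand-built solvable/unsolvable pair at `q = 2`.

## Numerical choices and conventions

* Fractions are compared with absolute tolerance `1e-6` throughout; row
  sums may deviate by `1e-6` (optionally renormalized) since real tables
  carry rounding error.
* MILP binaries are thresholded at 0.5; solutions are re-validated at
  `1e-5` before being returned.
* Greedy trivial-solution order defaults to row-major over `Π1 × Π2`
  and is a parameter (the construction is order-invariant in
  consistency, not in the resulting `U`).
* Clone labels are opaque; the root/normal clone is whatever the tree
  declares, with no positional convention. `|` is reserved for
  serialized paired labels `i|j`.
* Zero-proportion input clones are retained (they simply need no pair);
  they do not enter the support bound.
* Ties among co-optimal MILP solutions resolve to an arbitrary optimum;
  tests compare cardinality/objective, never the witness.

## Evaluation

Clone recall `|Π ∩ Π*| / |Π*|` (exact label matching, asymmetric) and
parent-child distance `|E Δ E*| / |E ∪ E*|` on ordered edge sets
(symmetric, 0 iff identical). The bundled study in
`scripts/acceptance.py` runs 10 instances per configuration at
`n1 = n2 ∈ {3, 5}`, `m = 5`, `h ∈ {0, 0.05, 0.1}` and reports medians
per noise level, pooling the two clone counts. These sizes keep the
whole study under a minute while matching the clone/sample counts
reported in recent cancer genomics cohorts; recovery degrades with
fewer samples because the number of co-optimal solutions grows, which
the per-candidate tie reporting makes visible.

## Known limitations

* Exactly two feature classes; no three-way integration.
* The PCTI objective is unweighted L1; no likelihood model of
  proportion uncertainty.
* No enumeration of all co-optimal MILP solutions beyond the guarded
  brute-force oracle (`--enumerate` in the CLI).
* Proportion matrices with samples missing from one feature are
  rejected rather than aligned.
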