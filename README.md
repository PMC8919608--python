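# paction — parsimonious integration of SNV and CNA tumor clones

Bulk DNA sequencing of a tumor is a mixture of cell subpopulations
(*clones*), and deconvolution methods reliably recover clones defined by
**either** single-nucleotide variants (SNVs) **or** copy-number
aberrations (CNAs) — but rarely both at once. `paction` integrates two
such independently inferred clonal decompositions of the same samples
into one joint picture: a set of paired clones, their proportions, and
(when clone trees are available) a single refined clone tree, computed by
**exact** mixed-integer programming rather than heuristics. It is aimed
at cancer-genomics analysts who already have per-feature clone
proportions/trees from tools like PyClone, HATCHet or cluster-based
phylogeny methods and want a principled joint reconstruction.

## The model

Let `U1` (`m × n1`) and `U2` (`m × n2`) be proportion matrices over the
same `m` samples for SNV clones `Π1` and CNA clones `Π2` (nonnegative
entries, unit row sums). The true clones are pairs `Π ⊆ Π1 × Π2`; their
proportions `U` are *consistent* with the inputs when both marginals
match:

```
u1[p,i] = Σ_{(i,j) ∈ Π} u[p,(i,j)]      u2[p,j] = Σ_{(i,j) ∈ Π} u[p,(i,j)]
```

Two problems are solved exactly (both NP-hard, by reduction from
3-partition):

* **PCI** (parsimonious clone integration) — find the smallest `Π`
  admitting consistent proportions. The optimum lies between the support
  bound `max(S(U1), S(U2))` and `n1·n2` (the full pair set always works —
  a greedy mass-matching construction proves it).
* **PCTI** (parsimonious clone tree integration) — given clone trees
  `T1`, `T2`, find the *refinement* `T` (a tree on paired clones that
  collapses to `T1` when CNA-edges are contracted and to `T2` when
  SNV-edges are) and proportions `U` minimizing the total correction

  ```
  J(U, U1, U2) = Σ_p Σ_i |u1[p,i] − marginal1(U)[p,i]| + Σ_p Σ_j |u2[p,j] − marginal2(U)[p,j]|
  ```

  Every refinement has exactly `n1 + n2 − 1` clones and root
  `(r(T1), r(T2))`; `J = 0` iff the inputs need no correction. PCTI is
  the mode of choice for real data, whose proportions always carry error.

Both problems are encoded as MILPs (binary pair indicators `x[i,j]`,
per-sample masses `u[p,i,j] ≤ x[i,j]`, L1 corrections via two-sided
linear bounds, and refinement via linearized products
`z = x[i,j]·x[i',j]` forcing each input edge to be realized exactly once)
and solved with the HiGHS branch-and-bound solver. Brute-force oracles
(subset enumeration for PCI, refinement enumeration + LP scoring for
PCTI) cross-check the MILPs on small instances. A simulator, evaluation
metrics (clone recall, parent-child distance), 3-partition adversarial
instance generators, TSV I/O and a thin `paction` CLI complete the
toolkit.

## Worked example

`examples/integrate_trees.py` — two samples whose SNV (50/50, 20/80) and
CNA (30/70, 90/10) clone proportions cannot be reconciled exactly:

```
refined tree on 3 clones, total correction J = 0.400
  (1, 1) -> (2, 1)
  (1, 1) -> (1, 2)
exhaustive check: optimum J = 0.400 achieved by 2 of 3 refinements
```

The integrated tumor has 3 clones (`n1 + n2 − 1` with `n1 = n2 = 2`);
at least 0.4 of total clone mass (summed over both features and samples)
must be reassigned before the two inputs agree, and two of the three
possible refinements achieve that minimum — a reminder that with few
samples the optimum need not be unique. The other scripts in `examples/`
show proportion-only integration (`integrate_proportions.py`),
simulation and evaluation (`simulate_and_evaluate.py`), candidate-tree
selection when one feature has no tree (`select_candidate_tree.py`), and
the 3-partition hardness instances (`hardness_instances.py`).

The same workflows are available from the shell:

```sh
paction simulate --n1 3 --n2 3 -m 5 --h 0.05 --seed 7 -o sim/
paction pcti --tree1 sim/tree1.tsv --props1 sim/props1.tsv \
             --tree2 sim/tree2.tsv --props2 sim/props2.tsv -o out/
paction evaluate --truth sim/ --pred out/ -o report.json
```

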