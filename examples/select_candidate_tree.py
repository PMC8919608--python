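"""Pick a CNA clone tree when upstream analysis supplies none.

Copy-number callers often report clone proportions without a tree.  The
selection workflow enumerates candidate rooted trees on the CNA clones
(via Pruefer sequences), integrates each against the SNV tree, and keeps
the candidate with the smallest total correction J, reporting ties: with
few samples several trees can explain the data equally well.
"""

from paction import (
    SimulationConfig,
    enumerate_candidate_trees,
    select_best_input_tree,
    simulate_instance,
)

bundle = simulate_instance(SimulationConfig(n1=5, n2=4, m=5, h=0.05, seed=23))
candidates = enumerate_candidate_trees(list(bundle.T2.vertices), bundle.T2.root)
print(f"{len(candidates)} candidate trees on {bundle.T2.n_vertices} CNA clones")

result = select_best_input_tree(candidates, bundle.T1, bundle.U1, bundle.U2)
print(f"best correction J = {result.solution.total_correction:.3f}, "
      f"tied candidates: {list(result.tied_indices)}")
truth = [k for k, c in enumerate(candidates) if c.edge_set() == bundle.T2.edge_set()]
print(f"simulated true tree is candidate {truth[0]}; "
      f"among the minimizers: {truth[0] in result.tied_indices}")
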