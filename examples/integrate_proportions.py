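"""Integrate SNV and CNA clone proportions without trees (PCI).

Two deconvolution analyses of the same single tumor sample disagree on how
to partition the cells: the SNV analysis found two clones at 50/50, the
CNA analysis two clones at 60/40.  The integration finds the fewest paired
clones whose proportions marginalize exactly to both inputs.
"""

from paction import pci_brute_force, solve_pci, support, validate_proportion_matrix

U1 = validate_proportion_matrix([[0.5, 0.5]], clone_ids=["snv1", "snv2"])
U2 = validate_proportion_matrix([[0.6, 0.4]], clone_ids=["cna1", "cna2"])

solution = solve_pci(U1, U2)
print(f"support lower bound: {max(support(U1), support(U2))} clones")
print(f"optimal integration: {solution.n_clones} clones ({solution.status})")
for clone, value in zip(solution.proportions.clone_ids, solution.proportions.values[0]):
    print(f"  clone {clone}: proportion {value:.2f}")

oracle = pci_brute_force(U1, U2)
print(f"brute-force oracle agrees: minimum {oracle.n_clones} clones")

# Three clones are needed: no two pairs can cover both 50/50 and 60/40,
# so one SNV clone must be split across the two CNA backgrounds.
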