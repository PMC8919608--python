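"""Adversarial instances from 3-partition.

Both integration problems are NP-hard by reduction from 3-partition.  The
reductions double as sharp test instances: a solvable 3-partition multiset
maps to a PCI instance whose minimum is exactly 3q (and a PCTI instance
with an error-free refinement), while an unsolvable multiset forces an
extra clone (and a strictly positive correction).
"""

from paction import (
    ThreePartitionInstance,
    pcti_brute_force,
    reduce_3partition_to_pci,
    reduce_3partition_to_pcti,
    solve_pci,
)

solvable = ThreePartitionInstance(
    A=(11, 14, 15, 12, 13, 15), B=40, q=2, known_partition=(1, 1, 1, 2, 2, 2)
)
unsolvable = ThreePartitionInstance(A=(11, 11, 11, 19, 14, 14), B=40, q=2)

for name, inst in [("solvable", solvable), ("unsolvable", unsolvable)]:
    U1, U2 = reduce_3partition_to_pci(inst)
    n = solve_pci(U1, U2).n_clones
    T1, V1, T2, V2 = reduce_3partition_to_pcti(inst)
    oracle = pcti_brute_force(T1, V1, T2, V2)
    print(
        f"{name}: PCI minimum = {n} (3q = {3 * inst.q}); "
        f"PCTI optimum J = {oracle.total_correction:.3f} on {oracle.tree.n_vertices} clones"
    )
# The solvable instance partitions {11,14,15} / {12,13,15}; the unsolvable
# multiset has no triple summing to 40, so integration must pay for it.
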