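"""Exact parsimonious clone integration (PCI) by mixed-integer programming.

PCI: given proportion matrices ``U1`` (clones Pi1) and ``U2`` (clones Pi2)
over the same samples, find the smallest pair set ``Pi`` in ``Pi1 x Pi2``
admitting proportions ``U`` whose marginals equal ``U1`` and ``U2``
exactly.  The problem is NP-hard already for one sample (by reduction from
3-partition), so it is solved with a MILP: binary selection indicators
``x[i,j]``, continuous masses ``u[p,i,j] <= x[i,j]`` with exact marginal
equalities, objective ``min sum x``.  A subset-enumeration brute force
serves as an independent oracle on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (
    PciSolution,
    ProportionMatrix,
    ValidationError,
    consistency_error,
    consistent_proportions_for_clone_set,
    support,
)
from .options import SolverError, SolverOptions, milp_options

__all__ = ["solve_pci", "pci_brute_force", "BruteForceResult"]

#: post-hoc consistency recheck tolerance for MILP solutions
RECHECK_TOL = 1e-5


def solve_pci(
    U1: ProportionMatrix,
    U2: ProportionMatrix,
    options: SolverOptions | None = None,
) -> PciSolution:
    """Minimum-cardinality consistent clone integration.

    Returns a :class:`PciSolution` whose clone count lies between
    ``max(S(U1), S(U2))`` and ``n1 * n2`` and whose proportions have zero
    consistency error.  Among co-optimal clone sets an arbitrary optimum is
    returned.
    """
    options = options or SolverOptions()
    if U1.sample_ids != U2.sample_ids:
        raise ValidationError("U1 and U2 must share the same labeled samples")
    m = U1.n_samples
    n1, n2 = U1.n_clones, U2.n_clones
    npairs = n1 * n2
    pairs = list(itertools.product(range(n1), range(n2)))

    # variables: x[0:npairs] binary, then u[p, i, j] row-major
    nvar = npairs + m * npairs

    def uvar(p: int, k: int) -> int:
        return npairs + p * npairs + k

    rows, cols, data, lo, hi = [], [], [], [], []
    r = 0
    # u[p,i,j] - x[i,j] <= 0
    for p in range(m):
        for k in range(npairs):
            rows += [r, r]
            cols += [uvar(p, k), k]
            data += [1.0, -1.0]
            lo.append(-np.inf)
            hi.append(0.0)
            r += 1
    # sum_j u[p,i,j] = u1[p,i]
    for p in range(m):
        for i in range(n1):
            for j in range(n2):
                rows.append(r)
                cols.append(uvar(p, i * n2 + j))
                data.append(1.0)
            lo.append(U1.values[p, i])
            hi.append(U1.values[p, i])
            r += 1
    # sum_i u[p,i,j] = u2[p,j]
    for p in range(m):
        for j in range(n2):
            for i in range(n1):
                rows.append(r)
                cols.append(uvar(p, i * n2 + j))
                data.append(1.0)
            lo.append(U2.values[p, j])
            hi.append(U2.values[p, j])
            r += 1

    A = sparse.csr_array((data, (rows, cols)), shape=(r, nvar))
    c = np.zeros(nvar)
    c[:npairs] = 1.0
    integrality = np.zeros(nvar)
    integrality[:npairs] = 1
    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.array(lo), np.array(hi)),
        integrality=integrality,
        bounds=Bounds(0, 1),
        options=milp_options(options),
    )
    if res.x is None:
        raise SolverError(f"MILP returned no incumbent (status {res.status}: {res.message})")
    optimal = res.status == 0

    x = res.x[:npairs] > 0.5
    selected = [
        (U1.clone_ids[i], U2.clone_ids[j]) for k, (i, j) in enumerate(pairs) if x[k]
    ]
    values = np.zeros((m, len(selected)))
    col = 0
    for k, (i, j) in enumerate(pairs):
        if x[k]:
            values[:, col] = [max(res.x[uvar(p, k)], 0.0) for p in range(m)]
            col += 1
    U = ProportionMatrix(U1.sample_ids, tuple(selected), values)
    err = consistency_error(selected, U, U1, U2)
    if err > RECHECK_TOL:
        raise SolverError(f"solver reported success but consistency error is {err:.3g}")
    lower = max(support(U1), support(U2))
    if optimal and not lower <= len(selected) <= n1 * n2:
        raise SolverError(f"optimal clone count {len(selected)} violates bounds [{lower}, {n1 * n2}]")
    return PciSolution(
        frozenset(selected), U, optimal=optimal, status="optimal" if optimal else "incumbent"
    )


@dataclass(frozen=True)
class BruteForceResult:
    """Minimum clone count with one feasible witness."""

    n_clones: int
    clones: frozenset
    proportions: ProportionMatrix


def pci_brute_force(
    U1: ProportionMatrix,
    U2: ProportionMatrix,
    max_pairs: int = 20,
    tolerance: float = 1e-6,
) -> BruteForceResult:
    """Exhaustive PCI oracle: smallest feasible pair subset by direct enumeration.

    Iterates subset sizes upward from the support lower bound, testing each
    candidate subset with :func:`consistent_proportions_for_clone_set`.
    Only subsets covering every supported input clone are tested (an
    unsupported clone needs no pair).  Guarded to ``n1*n2 <= max_pairs``.
    """
    if U1.sample_ids != U2.sample_ids:
        raise ValidationError("U1 and U2 must share the same labeled samples")
    n1, n2 = U1.n_clones, U2.n_clones
    if n1 * n2 > max_pairs:
        raise ValueError(
            f"{n1 * n2} candidate pairs exceed the enumeration guard ({max_pairs}); use solve_pci"
        )
    all_pairs = list(itertools.product(range(n1), range(n2)))
    sup1 = {i for i in range(n1) if U1.values[:, i].sum() > 0}
    sup2 = {j for j in range(n2) if U2.values[:, j].sum() > 0}
    lower = max(len(sup1), len(sup2))

    for size in range(max(lower, 1), n1 * n2 + 1):
        for subset in itertools.combinations(all_pairs, size):
            if {i for i, _ in subset} < sup1 or {j for _, j in subset} < sup2:
                continue
            labeled = [(U1.clone_ids[i], U2.clone_ids[j]) for i, j in subset]
            U = consistent_proportions_for_clone_set(labeled, U1, U2, tolerance=tolerance)
            if U is not None:
                return BruteForceResult(size, frozenset(labeled), U)
    raise SolverError("no feasible subset found; the full pair set should always be feasible")
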