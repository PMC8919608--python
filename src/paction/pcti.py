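"""Exact parsimonious clone tree integration (PCTI).

PCTI: given clone trees ``T1``/``T2`` with proportions ``U1``/``U2`` for
two mutation feature classes, find the refined clone tree ``T`` (a tree on
paired clones that collapses back to ``T1`` and ``T2``), its pair set
``Pi`` and proportions ``U`` minimizing the total correction

    J(U, U1, U2) = sum_p sum_i |u1[p,i] - marginal1(U)[p,i]|
                 + sum_p sum_j |u2[p,j] - marginal2(U)[p,j]|.

Any refinement has exactly ``n1 + n2 - 1`` clones and is rooted at the
pair of input roots, so the tree only constrains which pairs may be
selected while J measures how far the inputs are from a consistent
integration (J = 0 iff no correction is needed).  The MILP linearizes the
absolute values with correction variables and encodes refinement through
product variables ``z`` that force every input edge to be realized exactly
once.  A refinement-enumeration oracle (over the assignments of input
edges to the opposite feature's clones) provides an independent check on
small instances, and powers the candidate-input-tree selection workflow
used when one feature's clone tree is unknown.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Hashable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model import (
    CloneTree,
    PctiSolution,
    ProportionMatrix,
    ValidationError,
    check_refinement,
    consistency_error,
)
from .options import SolverError, SolverOptions, milp_options

__all__ = [
    "solve_pcti",
    "enumerate_refinements",
    "score_refinement",
    "pcti_brute_force",
    "PctiBruteForceResult",
    "select_best_input_tree",
    "TreeSelectionResult",
    "enumerate_candidate_trees",
]

RECHECK_TOL = 1e-5
COOPT_TOL = 1e-6


def _check_instance(T1: CloneTree, U1: ProportionMatrix, T2: CloneTree, U2: ProportionMatrix) -> None:
    if U1.sample_ids != U2.sample_ids:
        raise ValidationError("U1 and U2 must share the same labeled samples")
    if T1.vertices != set(U1.clone_ids):
        raise ValidationError("vertex set of T1 does not equal the clone set of U1")
    if T2.vertices != set(U2.clone_ids):
        raise ValidationError("vertex set of T2 does not equal the clone set of U2")


def solve_pcti(
    T1: CloneTree,
    U1: ProportionMatrix,
    T2: CloneTree,
    U2: ProportionMatrix,
    options: SolverOptions | None = None,
) -> PctiSolution:
    """Refinement-constrained integration minimizing the total correction J.

    The MILP uses binary pair indicators ``x[i,j]``, per-sample pair masses
    ``u[p,i,j] <= x[i,j]`` summing to 1, correction magnitudes ``c`` bounding
    the marginal deviations from both sides, and continuous ``z`` variables
    linearizing ``x[i,j]*x[i',j]`` so that each edge of ``T1`` (resp. ``T2``)
    is realized in exactly one context of the other feature.  Selecting
    exactly ``n1 + n2 - 1`` pairs including the root pair then makes feasible
    ``x`` coincide with refinement vertex sets.  The returned tree always
    passes :func:`~paction.model.check_refinement`.
    """
    options = options or SolverOptions()
    _check_instance(T1, U1, T2, U2)
    m = U1.n_samples
    n1, n2 = U1.n_clones, U2.n_clones
    npairs = n1 * n2
    e1 = list(T1.edges)
    e2 = list(T2.edges)
    i_of = {c: i for i, c in enumerate(U1.clone_ids)}
    j_of = {c: j for j, c in enumerate(U2.clone_ids)}

    def xvar(i: int, j: int) -> int:
        return i * n2 + j

    off_u = npairs
    off_c1 = off_u + m * npairs
    off_c2 = off_c1 + m * n1
    off_z1 = off_c2 + m * n2
    off_z2 = off_z1 + len(e1) * n2
    nvar = off_z2 + n1 * len(e2)

    def uvar(p: int, i: int, j: int) -> int:
        return off_u + p * npairs + xvar(i, j)

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    r = 0

    def add_row(terms: list[tuple[int, float]], lb: float, ub: float) -> None:
        nonlocal r
        for col, coef in terms:
            rows.append(r)
            cols.append(col)
            data.append(coef)
        lo.append(lb)
        hi.append(ub)
        r += 1

    for p in range(m):
        for i in range(n1):
            for j in range(n2):
                add_row([(uvar(p, i, j), 1.0), (xvar(i, j), -1.0)], -np.inf, 0.0)
        add_row([(uvar(p, i, j), 1.0) for i in range(n1) for j in range(n2)], 1.0, 1.0)
    # correction variables bound |marginal - input| from both sides
    for p in range(m):
        for i in range(n1):
            terms = [(uvar(p, i, j), 1.0) for j in range(n2)]
            add_row([(off_c1 + p * n1 + i, 1.0)] + [(v, -a) for v, a in terms], -U1.values[p, i], np.inf)
            add_row([(off_c1 + p * n1 + i, 1.0)] + terms, U1.values[p, i], np.inf)
        for j in range(n2):
            terms = [(uvar(p, i, j), 1.0) for i in range(n1)]
            add_row([(off_c2 + p * n2 + j, 1.0)] + [(v, -a) for v, a in terms], -U2.values[p, j], np.inf)
            add_row([(off_c2 + p * n2 + j, 1.0)] + terms, U2.values[p, j], np.inf)
    # z[e,j] = x[i,j] * x[i',j] for T1 edges e=(i,i'); realized in exactly one context j
    for a, (pi, ci) in enumerate(e1):
        i, ii = i_of[pi], i_of[ci]
        for j in range(n2):
            zv = off_z1 + a * n2 + j
            add_row([(zv, 1.0), (xvar(i, j), -1.0)], -np.inf, 0.0)
            add_row([(zv, 1.0), (xvar(ii, j), -1.0)], -np.inf, 0.0)
            add_row([(zv, 1.0), (xvar(i, j), -1.0), (xvar(ii, j), -1.0)], -1.0, np.inf)
        add_row([(off_z1 + a * n2 + j, 1.0) for j in range(n2)], 1.0, 1.0)
    for b, (pj, cj) in enumerate(e2):
        j, jj = j_of[pj], j_of[cj]
        for i in range(n1):
            zv = off_z2 + b * n1 + i
            add_row([(zv, 1.0), (xvar(i, j), -1.0)], -np.inf, 0.0)
            add_row([(zv, 1.0), (xvar(i, jj), -1.0)], -np.inf, 0.0)
            add_row([(zv, 1.0), (xvar(i, j), -1.0), (xvar(i, jj), -1.0)], -1.0, np.inf)
        add_row([(off_z2 + b * n1 + i, 1.0) for i in range(n1)], 1.0, 1.0)
    # refinement vertex count (n1 + n2 - 1 pairs) and the root pair
    add_row([(xvar(i, j), 1.0) for i in range(n1) for j in range(n2)], n1 + n2 - 1, n1 + n2 - 1)

    lb = np.zeros(nvar)
    ub = np.ones(nvar)
    lb[xvar(i_of[T1.root], j_of[T2.root])] = 1.0
    c = np.zeros(nvar)
    c[off_c1:off_z1] = 1.0
    integrality = np.zeros(nvar)
    integrality[:npairs] = 1
    A = sparse.csr_array((data, (rows, cols)), shape=(r, nvar))
    res = milp(
        c=c,
        constraints=LinearConstraint(A, np.array(lo), np.array(hi)),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options=milp_options(options),
    )
    if res.x is None:
        raise SolverError(f"MILP returned no incumbent (status {res.status}: {res.message})")
    optimal = res.status == 0

    x = res.x[:npairs] > 0.5
    selected = [
        (U1.clone_ids[i], U2.clone_ids[j])
        for i in range(n1)
        for j in range(n2)
        if x[xvar(i, j)]
    ]
    edges = []
    for a, (pi, ci) in enumerate(e1):
        j = int(np.argmax(res.x[off_z1 + a * n2 : off_z1 + (a + 1) * n2]))
        edges.append(((pi, U2.clone_ids[j]), (ci, U2.clone_ids[j])))
    for b, (pj, cj) in enumerate(e2):
        i = int(np.argmax(res.x[off_z2 + b * n1 : off_z2 + (b + 1) * n1]))
        edges.append(((U1.clone_ids[i], pj), (U1.clone_ids[i], cj)))
    tree = CloneTree.from_edges(edges, root=(T1.root, T2.root)) if edges else CloneTree.single_vertex(
        (T1.root, T2.root)
    )
    check = check_refinement(tree, T1, T2)
    if not check:
        raise SolverError(f"solver tree fails refinement check: {check.violations}")
    values = np.zeros((m, len(selected)))
    for col, (ci, cj) in enumerate(selected):
        for p in range(m):
            values[p, col] = max(res.x[uvar(p, i_of[ci], j_of[cj])], 0.0)
    U = ProportionMatrix(U1.sample_ids, tuple(selected), values)
    J = consistency_error(selected, U, U1, U2)
    if abs(J - float(res.fun)) > RECHECK_TOL:
        raise SolverError(f"objective {res.fun:.6g} disagrees with recomputed correction {J:.6g}")
    return PctiSolution(
        frozenset(selected), tree, U, J, optimal=optimal, status="optimal" if optimal else "incumbent"
    )


def _bfs_vertices(T: CloneTree) -> list:
    order = [T.root]
    queue = [T.root]
    while queue:
        v = queue.pop(0)
        for c in sorted(T.children(v), key=str):
            order.append(c)
            queue.append(c)
    return order


def enumerate_refinements(
    T1: CloneTree,
    T2: CloneTree,
    max_edges: int = 12,
    max_combinations: int = 5_000_000,
) -> list[CloneTree]:
    """All refinements of ``T1`` and ``T2``, by exhaustive context assignment.

    A refinement is determined by assigning to every edge of ``T1`` the
    second-feature clone ``j`` in whose context it occurs, and to every edge
    of ``T2`` the first-feature clone ``i``; an assignment is valid when the
    implied ``n1 + n2 - 1`` vertices are distinct and every created vertex's
    parent exists.  Distinct assignments yield distinct trees, so the output
    has no duplicates.  Guarded by total edge count and assignment count.
    """
    e1 = list(T1.edges)
    e2 = list(T2.edges)
    if len(e1) + len(e2) > max_edges:
        raise ValueError(
            f"{len(e1) + len(e2)} combined edges exceed the enumeration guard "
            f"({max_edges}); use solve_pcti"
        )
    v1 = _bfs_vertices(T1)
    v2 = _bfs_vertices(T2)
    n_comb = len(v2) ** len(e1) * len(v1) ** len(e2)
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} context assignments exceed the enumeration guard "
            f"({max_combinations}); use solve_pcti"
        )
    root = (T1.root, T2.root)
    out: list[CloneTree] = []
    for phi1 in itertools.product(v2, repeat=len(e1)):
        created1 = [((ci, j), (pi, j)) for (pi, ci), j in zip(e1, phi1)]
        for phi2 in itertools.product(v1, repeat=len(e2)):
            created2 = [((i, cj), (i, pj)) for (pj, cj), i in zip(e2, phi2)]
            vertices = {root}
            ok = True
            for v, _ in created1 + created2:
                if v in vertices:
                    ok = False
                    break
                vertices.add(v)
            if not ok:
                continue
            if any(parent not in vertices for _, parent in created1 + created2):
                continue
            edges = tuple((parent, v) for v, parent in created1 + created2)
            out.append(CloneTree(root, edges) if edges else CloneTree.single_vertex(root))
    return out


def score_refinement(
    T: CloneTree,
    U1: ProportionMatrix,
    U2: ProportionMatrix,
) -> tuple[float, ProportionMatrix]:
    """Minimal correction J achievable with the pair set of ``T`` fixed.

    Solves, independently per sample, the LP minimizing the L1 deviation of
    the marginals of ``U`` from ``U1`` and ``U2`` subject to ``U`` being a
    proportion matrix supported on ``V(T)``.
    """
    pairs = sorted(T.vertices, key=str)
    n = len(pairs)
    n1, n2 = U1.n_clones, U2.n_clones
    # variables per sample: u[0:n], c1[n:n+n1], c2[n+n1:n+n1+n2]
    nv = n + n1 + n2
    c = np.zeros(nv)
    c[n:] = 1.0
    a_rows = []
    lo, hi = [], []
    eq = np.zeros(nv)
    eq[:n] = 1.0
    for i, clone in enumerate(U1.clone_ids):
        row = np.zeros(nv)
        row[[k for k, (a, _) in enumerate(pairs) if a == clone]] = 1.0
        minus = row.copy()
        minus[n + i] = -1.0
        plus = -row
        plus[n + i] = -1.0
        a_rows += [minus, plus]
    for j, clone in enumerate(U2.clone_ids):
        row = np.zeros(nv)
        row[[k for k, (_, b) in enumerate(pairs) if b == clone]] = 1.0
        minus = row.copy()
        minus[n + n1 + j] = -1.0
        plus = -row
        plus[n + n1 + j] = -1.0
        a_rows += [minus, plus]
    A_ub_base = np.array(a_rows)
    bounds = [(0, 1)] * n + [(0, None)] * (n1 + n2)

    total = 0.0
    rows_out = []
    for p in range(U1.n_samples):
        b_ub = []
        for i in range(n1):
            b_ub += [U1.values[p, i], -U1.values[p, i]]
        for j in range(n2):
            b_ub += [U2.values[p, j], -U2.values[p, j]]
        res = linprog(
            c,
            A_ub=A_ub_base,
            b_ub=np.array(b_ub),
            A_eq=eq[None, :],
            b_eq=[1.0],
            bounds=bounds,
            method="highs",
        )
        if not res.success:
            raise SolverError(f"refinement scoring LP failed: {res.message}")
        total += float(res.fun)
        rows_out.append(np.clip(res.x[:n], 0.0, None))
    U = ProportionMatrix(U1.sample_ids, tuple(pairs), np.vstack(rows_out))
    return total, U


@dataclass(frozen=True)
class PctiBruteForceResult:
    """Optimal refinement by exhaustive scoring, with co-optimum count."""

    tree: CloneTree
    proportions: ProportionMatrix
    total_correction: float
    n_cooptimal: int
    cooptimal_trees: tuple[CloneTree, ...]


def pcti_brute_force(
    T1: CloneTree,
    U1: ProportionMatrix,
    T2: CloneTree,
    U2: ProportionMatrix,
    max_edges: int = 12,
) -> PctiBruteForceResult:
    """Independent PCTI oracle: score every refinement, return the best.

    Co-optimal refinements (J within ``1e-6`` of the minimum) are counted
    and returned; the reported tree is the first optimum in enumeration
    order.
    """
    _check_instance(T1, U1, T2, U2)
    scored = [
        (T, *score_refinement(T, U1, U2))
        for T in enumerate_refinements(T1, T2, max_edges=max_edges)
    ]
    if not scored:
        raise SolverError("no refinement exists; inputs are not valid clone trees")
    best_J = min(J for _, J, _ in scored)
    coopt = [(T, J, U) for T, J, U in scored if J <= best_J + COOPT_TOL]
    tree, J, U = coopt[0]
    return PctiBruteForceResult(tree, U, J, len(coopt), tuple(t for t, _, _ in coopt))


@dataclass(frozen=True)
class TreeSelectionResult:
    """Outcome of selecting the best candidate input tree by smallest correction."""

    best_index: int
    best_tree: CloneTree
    solution: PctiSolution
    corrections: tuple[float, ...]
    tied_indices: tuple[int, ...]


def select_best_input_tree(
    candidates: Sequence[CloneTree],
    T1: CloneTree,
    U1: ProportionMatrix,
    U2: ProportionMatrix,
    options: SolverOptions | None = None,
) -> TreeSelectionResult:
    """Pick the second-feature clone tree with the smallest total correction.

    Mirrors the workflow used when one feature's clone tree is not provided
    by upstream analysis: each candidate tree is integrated against
    ``(T1, U1)`` and the candidate minimizing J is returned, reporting ties
    explicitly (first minimizer wins).
    """
    if not candidates:
        raise ValidationError("empty candidate tree list")
    for k, cand in enumerate(candidates):
        if cand.vertices != set(U2.clone_ids):
            raise ValidationError(f"candidate {k} vertex set does not equal the clone set of U2")
    solutions = [solve_pcti(T1, U1, cand, U2, options=options) for cand in candidates]
    js = tuple(sol.total_correction for sol in solutions)
    best = int(np.argmin(js))
    ties = tuple(k for k, j in enumerate(js) if j <= js[best] + COOPT_TOL)
    return TreeSelectionResult(best, candidates[best], solutions[best], js, ties)


def enumerate_candidate_trees(
    clone_ids: Sequence[Hashable],
    root_id: Hashable,
    cap: int = 10_000,
    allow_truncation: bool = False,
) -> list[CloneTree]:
    """All rooted labeled trees on the clone set with the given root.

    Generated via Pruefer sequences (``k**(k-2)`` labeled trees on ``k``
    vertices, each oriented away from the root).  Raises when the count
    exceeds ``cap`` unless ``allow_truncation`` is set, in which case the
    list is truncated with a warning.
    """
    clone_ids = list(dict.fromkeys(clone_ids))
    if root_id not in clone_ids:
        raise ValidationError(f"root {root_id!r} is not among the clones")
    k = len(clone_ids)
    if k == 1:
        return [CloneTree.single_vertex(root_id)]
    n_trees = k ** (k - 2)
    if n_trees > cap and not allow_truncation:
        raise ValueError(
            f"{n_trees} rooted labeled trees on {k} clones exceed cap {cap}; "
            "pass allow_truncation=True to take the first trees only"
        )
    out: list[CloneTree] = []
    for seq in itertools.product(range(k), repeat=max(k - 2, 0)):
        g = nx.from_prufer_sequence(list(seq))
        directed = nx.bfs_tree(g, source=clone_ids.index(root_id))
        edges = tuple((clone_ids[p], clone_ids[c]) for p, c in directed.edges)
        out.append(CloneTree.from_edges(edges, root=root_id))
        if len(out) >= cap:
            warnings.warn(
                f"candidate tree enumeration truncated at cap {cap} of {n_trees} trees",
                stacklevel=2,
            )
            break
    return out
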