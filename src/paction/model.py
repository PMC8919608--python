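"""Core domain types and consistency arithmetic for clone integration.

A tumor's clonal composition is described by a *proportion matrix*: an
``m x n`` matrix ``U`` with one row per sample and one column per clone,
nonnegative entries and unit row sums.  Two independent clusterings of the
same tumor cells -- e.g. SNV clones and CNA clones -- yield two proportion
matrices ``U1`` (clones ``Pi1``) and ``U2`` (clones ``Pi2``).  The true
clones are pairs ``(i, j)`` in ``Pi1 x Pi2``, and their proportions ``U``
must *marginalize* to ``U1`` and ``U2``: summing ``U`` over all pairs with
first coordinate ``i`` recovers column ``i`` of ``U1``, and likewise for
the second coordinate.  This module provides those types, the projection
and consistency arithmetic, refinement checking for clone trees, and the
polynomial-time building blocks (support bound, greedy trivial solution,
max-flow / LP feasibility of a fixed pair set) used by the exact solvers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ProportionMatrix",
    "CloneTree",
    "PciSolution",
    "PctiSolution",
    "RefinementCheck",
    "ValidationError",
    "validate_proportion_matrix",
    "project_proportions",
    "consistency_error",
    "check_refinement",
    "support",
    "greedy_trivial_solution",
    "consistent_proportions_for_clone_set",
]

#: absolute tolerance used for all fraction comparisons
FRACTION_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


@dataclass(frozen=True)
class ProportionMatrix:
    """Samples-by-clones matrix of clonal fractions with unit row sums.

    Parameters
    ----------
    sample_ids
        Unique sample labels, one per row.
    clone_ids
        Unique clone labels, one per column.  For integrated solutions the
        labels are ``(i, j)`` pairs.
    values
        ``(m, n)`` array of fractions in ``[0, 1]``.
    """

    sample_ids: tuple[Hashable, ...]
    clone_ids: tuple[Hashable, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(len(self.sample_ids), len(self.clone_ids))
        )
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "clone_ids", tuple(self.clone_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def column(self, clone: Hashable) -> np.ndarray:
        return self.values[:, self.clone_ids.index(clone)]

    def restrict(self, clones: Sequence[Hashable]) -> "ProportionMatrix":
        """Sub-matrix over the given clones (order preserved as given)."""
        idx = [self.clone_ids.index(c) for c in clones]
        return ProportionMatrix(self.sample_ids, tuple(clones), self.values[:, idx])


def validate_proportion_matrix(
    raw,
    sample_ids: Sequence[Hashable] | None = None,
    clone_ids: Sequence[Hashable] | None = None,
    tolerance: float = FRACTION_TOL,
    renormalize: bool = False,
) -> ProportionMatrix:
    """Validate (and optionally renormalize) a table of clone fractions.

    ``raw`` may be a nested list / array, or a pandas DataFrame in which
    case row and column labels are taken from its index and columns.
    Rows whose sums deviate from 1 by at most ``tolerance`` are accepted
    (and divided by their sum when ``renormalize`` is true); larger
    deviations raise :class:`ValidationError` naming the sample.
    """
    import pandas as pd

    if isinstance(raw, pd.DataFrame):
        sample_ids = tuple(raw.index) if sample_ids is None else tuple(sample_ids)
        clone_ids = tuple(raw.columns) if clone_ids is None else tuple(clone_ids)
        values = raw.to_numpy(dtype=float)
    else:
        values = np.asarray(raw, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"expected a 2-d table, got shape {values.shape}")
        m, n = values.shape
        sample_ids = tuple(range(1, m + 1)) if sample_ids is None else tuple(sample_ids)
        clone_ids = tuple(range(1, n + 1)) if clone_ids is None else tuple(clone_ids)

    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample labels")
    if len(set(clone_ids)) != len(clone_ids):
        raise ValidationError("duplicate clone labels")
    if values.shape != (len(sample_ids), len(clone_ids)):
        raise ValidationError(
            f"table shape {values.shape} does not match {len(sample_ids)} samples x {len(clone_ids)} clones"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite entry in proportion matrix")
    if np.any(values < 0):
        p, c = np.argwhere(values < 0)[0]
        raise ValidationError(f"negative proportion for sample {sample_ids[p]!r}, clone {clone_ids[c]!r}")

    row_sums = values.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > tolerance
    if np.any(bad):
        p = int(np.argmax(bad))
        raise ValidationError(
            f"row for sample {sample_ids[p]!r} sums to {row_sums[p]:.6g}, "
            f"deviating from 1 by more than tolerance {tolerance:g}"
        )
    if renormalize:
        values = values / row_sums[:, None]
    return ProportionMatrix(tuple(sample_ids), tuple(clone_ids), values)


@dataclass(frozen=True)
class CloneTree:
    """Rooted clone tree: vertices are clone labels, edges point parent to child.

    For integrated (paired) clone trees the vertex labels are ``(i, j)``
    tuples; the type is otherwise identical.
    """

    root: Hashable
    edges: tuple[tuple[Hashable, Hashable], ...]

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[Hashable, Hashable]], root: Hashable | None = None
    ) -> "CloneTree":
        """Build and validate a tree from a parent->child edge list.

        If ``root`` is omitted it is inferred as the unique vertex that
        never appears as a child.
        """
        edges = tuple((p, c) for p, c in edges)
        if not edges:
            if root is None:
                raise ValidationError("an edgeless tree needs an explicit root")
            return cls(root, ())
        children = [c for _, c in edges]
        if len(set(children)) != len(children):
            dup = next(c for c in children if children.count(c) > 1)
            raise ValidationError(f"vertex {dup!r} has more than one parent")
        vertices = {v for e in edges for v in e}
        roots = vertices - set(children)
        if root is None:
            if len(roots) != 1:
                raise ValidationError(f"cannot infer a unique root (candidates: {sorted(map(str, roots))})")
            root = next(iter(roots))
        elif root not in vertices:
            raise ValidationError(f"declared root {root!r} is not a vertex")
        elif root in children:
            raise ValidationError(f"declared root {root!r} has a parent")
        tree = cls(root, edges)
        # connectivity + acyclicity: every vertex must be reachable from the root
        if len(tree._reachable()) != len(vertices):
            raise ValidationError("edge list contains a cycle or a disconnected component")
        return tree

    @classmethod
    def single_vertex(cls, label: Hashable) -> "CloneTree":
        return cls(label, ())

    def _reachable(self) -> set:
        kids: dict = {}
        for p, c in self.edges:
            kids.setdefault(p, []).append(c)
        seen = {self.root}
        stack = [self.root]
        while stack:
            for c in kids.get(stack.pop(), ()):
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    @property
    def vertices(self) -> frozenset:
        return frozenset({self.root} | {v for e in self.edges for v in e})

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def parent(self, v: Hashable) -> Hashable | None:
        for p, c in self.edges:
            if c == v:
                return p
        return None

    def children(self, v: Hashable) -> tuple:
        return tuple(c for p, c in self.edges if p == v)

    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_node(self.root)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class PciSolution:
    """Integrated clone set and consistent proportions (no tree)."""

    clones: frozenset
    proportions: ProportionMatrix
    optimal: bool = True
    status: str = "optimal"

    @property
    def n_clones(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class PctiSolution:
    """Integrated clones, refined clone tree, proportions and total correction J."""

    clones: frozenset
    tree: CloneTree
    proportions: ProportionMatrix
    total_correction: float
    optimal: bool = True
    status: str = "optimal"

    @property
    def n_clones(self) -> int:
        return len(self.clones)


def project_proportions(
    clones: Iterable[tuple],
    U: ProportionMatrix,
    feature: int,
    target_clone_ids: Sequence[Hashable] | None = None,
) -> ProportionMatrix:
    """Marginalize paired-clone proportions onto one feature.

    Column ``i`` of the result is the sum of ``U``'s columns over all pairs
    whose ``feature`` coordinate equals ``i``.  ``target_clone_ids`` fixes
    the output columns (clones absent from every pair get a zero column);
    by default the distinct projected labels are used in order of first
    appearance in ``U.clone_ids``.
    """
    if feature not in (1, 2):
        raise ValueError("feature must be 1 or 2")
    k = feature - 1
    clones = set(clones)
    if set(U.clone_ids) != clones:
        raise ValidationError("U's clone axis does not match the paired clone set")
    if target_clone_ids is None:
        target_clone_ids = tuple(dict.fromkeys(pair[k] for pair in U.clone_ids))
    out = np.zeros((U.n_samples, len(target_clone_ids)))
    pos = {label: t for t, label in enumerate(target_clone_ids)}
    for col, pair in enumerate(U.clone_ids):
        if pair[k] in pos:
            out[:, pos[pair[k]]] += U.values[:, col]
        else:
            raise ValidationError(f"pair {pair!r} projects onto {pair[k]!r}, absent from the target clones")
    return ProportionMatrix(U.sample_ids, tuple(target_clone_ids), out)


def consistency_error(
    clones: Iterable[tuple],
    U: ProportionMatrix,
    U1: ProportionMatrix,
    U2: ProportionMatrix,
) -> float:
    """Total correction J: entrywise L1 distance of both marginals of U from U1 and U2.

    Zero exactly when ``U`` is consistent with ``U1`` and ``U2``.
    """
    if U.sample_ids != U1.sample_ids or U.sample_ids != U2.sample_ids:
        raise ValidationError("sample sets of U, U1 and U2 must be identical")
    p1 = project_proportions(clones, U, 1, target_clone_ids=U1.clone_ids)
    p2 = project_proportions(clones, U, 2, target_clone_ids=U2.clone_ids)
    return float(np.abs(p1.values - U1.values).sum() + np.abs(p2.values - U2.values).sum())


@dataclass(frozen=True)
class RefinementCheck:
    """Result of a refinement check; ``violations`` lists failed conditions."""

    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


def check_refinement(T: CloneTree, T1: CloneTree, T2: CloneTree) -> RefinementCheck:
    """Check that paired tree ``T`` is a refinement of ``T1`` and ``T2``.

    A refinement realizes every edge of ``T1`` exactly once (as an edge of
    ``T`` changing only the first coordinate), every edge of ``T2`` exactly
    once (second coordinate), changes exactly one coordinate along each of
    its own edges, and is rooted at the pair of input roots.
    """
    violations: list[str] = []
    if T.root != (T1.root, T2.root):
        violations.append(f"root {T.root!r} differs from (r(T1), r(T2)) = {(T1.root, T2.root)!r}")
    e1 = T1.edge_set()
    e2 = T2.edge_set()
    for (i, j), (ii, jj) in T.edges:
        if j == jj and (i, ii) in e1:
            continue
        if i == ii and (j, jj) in e2:
            continue
        violations.append(f"condition (iii): edge {((i, j), (ii, jj))!r} matches no input edge")
    for (i, ii) in e1:
        realized = [j for (a, j), (b, jj) in T.edges if j == jj and (a, b) == (i, ii)]
        if len(realized) != 1:
            violations.append(f"condition (i): edge {(i, ii)!r} of T1 realized {len(realized)} times")
    for (j, jj) in e2:
        realized = [i for (i, a), (ii, b) in T.edges if i == ii and (a, b) == (j, jj)]
        if len(realized) != 1:
            violations.append(f"condition (ii): edge {(j, jj)!r} of T2 realized {len(realized)} times")
    return RefinementCheck(not violations, tuple(violations))


def support(U: ProportionMatrix) -> int:
    """Number of clones with nonzero proportion in at least one sample.

    This is S(U), a lower bound on the number of integrated clones: every
    supported input clone must appear in at least one selected pair.
    """
    return int(np.count_nonzero(U.values.sum(axis=0) > 0))


def greedy_trivial_solution(
    U1: ProportionMatrix,
    U2: ProportionMatrix,
    order: Sequence[tuple] | None = None,
) -> PciSolution:
    """Consistent proportions on the full pair set by greedy mass matching.

    Visiting pairs ``(i, j)`` in the given order (default: row-major over
    ``Pi1 x Pi2``), each pair receives, per sample, the minimum of the
    remaining unassigned masses of ``i`` in ``U1`` and ``j`` in ``U2``;
    both remainders are then decremented.  The result is always consistent
    with ``U1`` and ``U2``, whatever the order.
    """
    if U1.sample_ids != U2.sample_ids:
        raise ValidationError("U1 and U2 must share the same samples")
    pairs = (
        tuple(order)
        if order is not None
        else tuple(itertools.product(U1.clone_ids, U2.clone_ids))
    )
    if set(pairs) != set(itertools.product(U1.clone_ids, U2.clone_ids)) or len(pairs) != (
        U1.n_clones * U2.n_clones
    ):
        raise ValidationError("order must be a permutation of all pairs in Pi1 x Pi2")
    rem1 = U1.values.copy()
    rem2 = U2.values.copy()
    idx1 = {c: k for k, c in enumerate(U1.clone_ids)}
    idx2 = {c: k for k, c in enumerate(U2.clone_ids)}
    values = np.zeros((U1.n_samples, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        take = np.minimum(rem1[:, idx1[i]], rem2[:, idx2[j]])
        values[:, col] = take
        rem1[:, idx1[i]] -= take
        rem2[:, idx2[j]] -= take
    U = ProportionMatrix(U1.sample_ids, pairs, values)
    return PciSolution(frozenset(pairs), U, optimal=False, status="trivial")


def _flow_feasible_single_sample(
    pairs: Sequence[tuple], u1_row: dict, u2_row: dict, tolerance: float
) -> np.ndarray | None:
    """Max-flow feasibility for one sample: source -> Pi1 -> Pi2 -> sink.

    Arc capacities are the input proportions on the outer arcs and 1 on the
    pair arcs; a consistent assignment exists iff the max flow saturates
    the unit total, and the flow on the pair arcs is that assignment.
    """
    g = nx.DiGraph()
    scale = 10**9  # integer capacities keep the flow computation exact
    for i, cap in u1_row.items():
        g.add_edge("s", ("L", i), capacity=int(round(cap * scale)))
    for j, cap in u2_row.items():
        g.add_edge(("R", j), "t", capacity=int(round(cap * scale)))
    for (i, j) in pairs:
        g.add_edge(("L", i), ("R", j), capacity=2 * scale)
    value, flow = nx.maximum_flow(g, "s", "t")
    if abs(value / scale - 1.0) > tolerance:
        return None
    return np.array([flow[("L", i)][("R", j)] / scale for (i, j) in pairs])


def _lp_feasible_single_sample(
    pairs: Sequence[tuple], u1_row: dict, u2_row: dict, tolerance: float
) -> np.ndarray | None:
    """LP feasibility for one sample: nonnegative pair masses with exact marginals."""
    n = len(pairs)
    labels1 = list(u1_row)
    labels2 = list(u2_row)
    a_eq = np.zeros((len(labels1) + len(labels2), n))
    b_eq = np.concatenate([[u1_row[i] for i in labels1], [u2_row[j] for j in labels2]])
    for col, (i, j) in enumerate(pairs):
        a_eq[labels1.index(i), col] = 1.0
        a_eq[len(labels1) + labels2.index(j), col] = 1.0
    res = linprog(c=np.zeros(n), A_eq=a_eq, b_eq=b_eq, bounds=(0, 1), method="highs")
    if not res.success:
        return None
    if np.abs(a_eq @ res.x - b_eq).max() > tolerance:
        return None
    return res.x


def consistent_proportions_for_clone_set(
    clones: Iterable[tuple],
    U1: ProportionMatrix,
    U2: ProportionMatrix,
    tolerance: float = FRACTION_TOL,
    method: str = "auto",
) -> ProportionMatrix | None:
    """Proportions over a fixed pair set consistent with ``U1``/``U2``, or None.

    With a single sample the question is a bipartite maximum-flow problem
    (source -> Pi1 clones -> Pi2 clones -> sink, pair arcs only for members
    of the clone set); a consistent matrix exists iff the flow value is 1.
    With several samples the constraints are separable, so each sample is
    solved as an independent linear feasibility program with exact marginal
    equalities.  ``method`` may force ``"flow"`` (m=1 only) or ``"lp"``.
    """
    if U1.sample_ids != U2.sample_ids:
        raise ValidationError("U1 and U2 must share the same samples")
    pairs = tuple(dict.fromkeys(clones))
    allowed = set(itertools.product(U1.clone_ids, U2.clone_ids))
    if not set(pairs) <= allowed:
        raise ValidationError("clone set contains pairs outside Pi1 x Pi2")
    if method not in ("auto", "flow", "lp"):
        raise ValueError(f"unknown method {method!r}")
    if method == "flow" and U1.n_samples > 1:
        raise ValueError("the flow construction handles a single sample only")
    use_flow = method == "flow" or (method == "auto" and U1.n_samples == 1)

    rows = []
    for p in range(U1.n_samples):
        u1_row = dict(zip(U1.clone_ids, U1.values[p]))
        u2_row = dict(zip(U2.clone_ids, U2.values[p]))
        solve = _flow_feasible_single_sample if use_flow else _lp_feasible_single_sample
        row = solve(pairs, u1_row, u2_row, tolerance)
        if row is None:
            return None
        rows.append(row)
    return ProportionMatrix(U1.sample_ids, pairs, np.vstack(rows))
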