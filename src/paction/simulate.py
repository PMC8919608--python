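"""Ground-truth instance simulation and hardness-reduction generators.

The simulator mirrors the three-step procedure used to benchmark clone
integration: (1) grow a random paired clone tree by uniform-parent
attachment, labeling each edge with a distinct SNV-side or CNA-side event;
(2) collapse the tree to the two per-feature input trees; (3) draw clone
proportions from a symmetric Dirichlet and perturb each feature's
projected proportions by convex mixing with a fresh Dirichlet draw at
noise level ``h`` (``h = 0``: inputs are exact marginals of the truth;
``h = 1``: inputs carry no signal).

It also builds adversarial instances from 3-partition, the NP-complete
problem underlying the hardness of both integration problems: a solvable
3-partition instance maps to a PCI instance whose minimum is ``3q`` and a
PCTI instance admitting a zero-correction refinement on ``4q + 1``
clones, while an unsolvable one does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import CloneTree, ProportionMatrix, ValidationError, project_proportions

__all__ = [
    "SimulationConfig",
    "SimulationBundle",
    "ThreePartitionInstance",
    "simulate_clone_tree",
    "collapse_to_feature_tree",
    "simulate_proportions",
    "add_noise",
    "simulate_instance",
    "reduce_3partition_to_pci",
    "reduce_3partition_to_pcti",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated instance.

    ``n1``/``n2`` are the per-feature clone counts, ``m`` the number of
    samples, ``h`` in [0, 1] the noise level (fraction of each input row
    replaced by an independent Dirichlet draw), ``concentration`` the
    symmetric Dirichlet parameter (1 = uniform over the simplex).
    """

    n1: int
    n2: int
    m: int
    h: float = 0.0
    seed: int = 0
    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1 or self.m < 1:
            raise ValidationError("n1, n2 and m must all be at least 1")
        if not 0.0 <= self.h <= 1.0:
            raise ValidationError("noise level h must lie in [0, 1]")
        if self.concentration <= 0:
            raise ValidationError("Dirichlet concentration must be positive")


@dataclass(frozen=True)
class SimulationBundle:
    """Ground truth plus the derived (possibly noisy) solver inputs."""

    config: SimulationConfig
    true_clones: frozenset
    true_tree: CloneTree
    true_proportions: ProportionMatrix
    T1: CloneTree
    U1: ProportionMatrix
    T2: CloneTree
    U2: ProportionMatrix


def simulate_clone_tree(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Random paired clone tree by uniform-parent growth.

    Starting from the root clone ``(1, 1)``, the pooled ``n1 - 1``
    first-feature events (values ``2..n1``) and ``n2 - 1`` second-feature
    events (``2..n2``) are applied in uniformly random order; each event
    attaches a new vertex to a parent chosen uniformly among existing
    vertices, overwriting the event's coordinate of the parent's label.
    Returns ``(clones, tree)`` with ``n1 + n2 - 1`` vertices.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    events = [(1, v) for v in range(2, config.n1 + 1)] + [(2, v) for v in range(2, config.n2 + 1)]
    order = rng.permutation(len(events))
    vertices: list[tuple] = [(1, 1)]
    edges: list[tuple] = []
    for k in order:
        feature, value = events[k]
        parent = vertices[int(rng.integers(len(vertices)))]
        child = (value, parent[1]) if feature == 1 else (parent[0], value)
        edges.append((parent, child))
        vertices.append(child)
    tree = CloneTree.from_edges(edges, root=(1, 1)) if edges else CloneTree.single_vertex((1, 1))
    return frozenset(vertices), tree


def collapse_to_feature_tree(T: CloneTree, feature: int) -> CloneTree:
    """Collapse a paired clone tree onto one feature.

    Contracts every edge along which the *other* feature changes; the
    surviving edges, with vertices renamed to their ``feature`` coordinate,
    form the per-feature clone tree.
    """
    if feature not in (1, 2):
        raise ValueError("feature must be 1 or 2")
    k = feature - 1
    edges = []
    for (p, c) in T.edges:
        if p[k] != c[k]:
            edges.append((p[k], c[k]))
    labels = {v[k] for v in T.vertices}
    if not edges:
        return CloneTree.single_vertex(T.root[k])
    seen = [c for _, c in edges]
    if len(set(seen)) != len(seen) or len({v for e in edges for v in e}) != len(labels):
        raise ValidationError("contraction did not yield a clone tree; invalid paired tree")
    return CloneTree.from_edges(edges, root=T.root[k])


def simulate_proportions(
    clones: Sequence, m: int, concentration: float = 1.0, rng: np.random.Generator | None = None
) -> ProportionMatrix:
    """Per-sample clone proportions from a symmetric Dirichlet distribution."""
    rng = np.random.default_rng() if rng is None else rng
    clones = tuple(clones)
    values = rng.dirichlet([concentration] * len(clones), size=m)
    return ProportionMatrix(tuple(range(1, m + 1)), clones, values)


def add_noise(
    U: ProportionMatrix, h: float, rng: np.random.Generator, concentration: float = 1.0
) -> ProportionMatrix:
    """Perturb proportions by convex mixing with a fresh Dirichlet draw.

    Each row becomes ``(1 - h) * row + h * Dirichlet(concentration)``; rows
    stay on the simplex, and ``h = 0`` returns the input unchanged.
    """
    if not 0.0 <= h <= 1.0:
        raise ValidationError("noise level h must lie in [0, 1]")
    if h == 0.0:
        return U
    noise = rng.dirichlet([concentration] * U.n_clones, size=U.n_samples)
    return ProportionMatrix(U.sample_ids, U.clone_ids, (1.0 - h) * U.values + h * noise)


def simulate_instance(config: SimulationConfig) -> SimulationBundle:
    """Full three-step simulation; identical configs yield identical bundles."""
    rng = np.random.default_rng(config.seed)
    clones, tree = simulate_clone_tree(config, rng)
    T1 = collapse_to_feature_tree(tree, 1)
    T2 = collapse_to_feature_tree(tree, 2)
    order = sorted(clones, key=str)
    U = simulate_proportions(order, config.m, config.concentration, rng)
    U1 = project_proportions(clones, U, 1, target_clone_ids=tuple(range(1, config.n1 + 1)))
    U2 = project_proportions(clones, U, 2, target_clone_ids=tuple(range(1, config.n2 + 1)))
    U1 = add_noise(U1, config.h, rng, config.concentration)
    U2 = add_noise(U2, config.h, rng, config.concentration)
    return SimulationBundle(config, clones, tree, U, T1, U1, T2, U2)


@dataclass(frozen=True)
class ThreePartitionInstance:
    """3-partition instance: split multiset A of 3q integers into q triples summing to B."""

    A: tuple[int, ...]
    B: int
    q: int
    known_partition: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", tuple(self.A))
        if len(self.A) != 3 * self.q:
            raise ValidationError(f"A must contain 3q = {3 * self.q} elements, got {len(self.A)}")
        if any(not (self.B / 4 < a < self.B / 2) for a in self.A):
            raise ValidationError("every element must lie strictly inside (B/4, B/2)")
        if sum(self.A) != self.B * self.q:
            raise ValidationError(f"elements must sum to B*q = {self.B * self.q}, got {sum(self.A)}")
        if self.known_partition is not None:
            sigma = tuple(self.known_partition)
            object.__setattr__(self, "known_partition", sigma)
            if len(sigma) != 3 * self.q or any(not 1 <= g <= self.q for g in sigma):
                raise ValidationError("known_partition must map each of the 3q elements to a group in [q]")
            for g in range(1, self.q + 1):
                if sum(a for a, gg in zip(self.A, sigma) if gg == g) != self.B:
                    raise ValidationError(f"known_partition group {g} does not sum to B")


def reduce_3partition_to_pci(instance: ThreePartitionInstance):
    """PCI instance whose minimum clone count is 3q iff the instance is solvable.

    One sample; first-feature clones ``1..3q`` with proportions ``a_i/(Bq)``,
    second-feature clones ``1..q`` with uniform proportions ``1/q``.
    """
    A, B, q = instance.A, instance.B, instance.q
    U1 = ProportionMatrix((1,), tuple(range(1, 3 * q + 1)), np.array([[a / (B * q) for a in A]]))
    U2 = ProportionMatrix((1,), tuple(range(1, q + 1)), np.full((1, q), 1.0 / q))
    return U1, U2


def reduce_3partition_to_pcti(instance: ThreePartitionInstance):
    """PCTI instance with a zero-correction refinement on 4q+1 clones iff solvable.

    Extends the PCI reduction with a zero-proportion normal clone ``0`` on
    both sides and star trees rooted at it.
    """
    A, B, q = instance.A, instance.B, instance.q
    U1 = ProportionMatrix(
        (1,), tuple(range(0, 3 * q + 1)), np.array([[0.0] + [a / (B * q) for a in A]])
    )
    U2 = ProportionMatrix((1,), tuple(range(0, q + 1)), np.array([[0.0] + [1.0 / q] * q]))
    T1 = CloneTree.from_edges([(0, i) for i in range(1, 3 * q + 1)], root=0)
    T2 = CloneTree.from_edges([(0, j) for j in range(1, q + 1)], root=0)
    return T1, U1, T2, U2
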