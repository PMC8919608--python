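"""Evaluation statistics for integrated clone sets and refined clone trees."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .model import CloneTree, ValidationError

__all__ = ["clone_recall", "parent_child_distance", "EvaluationReport"]


def clone_recall(predicted: Iterable[tuple], truth: Iterable[tuple]) -> float:
    """Fraction of ground-truth paired clones recovered: ``|P ∩ T| / |T|``.

    Identity is exact label equality of both coordinates.  Not symmetric
    in its arguments (precision would divide by ``|P|`` instead).
    """
    truth = set(truth)
    if not truth:
        raise ValidationError("ground-truth clone set is empty")
    return len(set(predicted) & truth) / len(truth)


def parent_child_distance(T: CloneTree, T_star: CloneTree) -> float:
    """Normalized symmetric difference of parent-child edge sets.

    ``|E Δ E*| / |E ∪ E*|`` over ordered (parent, child) pairs: 0 iff the
    edge sets coincide, 1 iff they are disjoint.  Two edgeless trees are at
    distance 0 when their roots agree (identical single-vertex trees).
    """
    e = T.edge_set()
    es = T_star.edge_set()
    if not e and not es:
        if T.root != T_star.root:
            raise ValidationError("edgeless trees with different roots are incomparable")
        return 0.0
    return len(e ^ es) / len(e | es)


@dataclass(frozen=True)
class EvaluationReport:
    """Summary of one solver run against simulated ground truth."""

    clone_recall: float
    parent_child_distance: float | None
    total_correction: float | None
    solver_status: str
    wall_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.clone_recall <= 1.0:
            raise ValidationError("clone recall must lie in [0, 1]")
        if self.parent_child_distance is not None and not 0.0 <= self.parent_child_distance <= 1.0:
            raise ValidationError("parent-child distance must lie in [0, 1]")
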