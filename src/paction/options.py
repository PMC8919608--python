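"""Solver configuration shared by the PCI and PCTI mixed-integer programs."""

from __future__ import annotations

from dataclasses import dataclass


class SolverError(RuntimeError):
    """Raised when the MILP backend fails or returns an inconsistent solution."""


@dataclass(frozen=True)
class SolverOptions:
    """Options for the exact solvers.

    Parameters
    ----------
    backend
        MILP backend; only ``"highs"`` (branch-and-bound, via SciPy) is
        built in.
    time_limit
        Wall-clock limit in seconds; on timeout the incumbent is returned
        and flagged non-optimal.
    mip_gap
        Relative optimality gap; 0 (exact) by default since both
        objectives are either small integers or small sums of fractions.
    threads
        Advisory; the built-in backend is single-threaded.
    seed
        Advisory random seed for backends that accept one.
    """

    backend: str = "highs"
    time_limit: float = 600.0
    mip_gap: float = 0.0
    threads: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.time_limit <= 0:
            raise ValueError("time_limit must be positive")
        if self.mip_gap < 0:
            raise ValueError("mip_gap must be nonnegative")


def milp_options(options: SolverOptions) -> dict:
    """Translate :class:`SolverOptions` into SciPy ``milp`` keyword options."""
    if options.backend != "highs":
        raise ValueError(f"unknown MILP backend {options.backend!r}; available: 'highs'")
    return {
        "time_limit": options.time_limit,
        "mip_rel_gap": options.mip_gap,
        "presolve": True,
    }
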