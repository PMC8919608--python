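"""Readers and writers for the TSV dialects and solution serialization.

Proportion matrices are tab-separated tables whose first column is
``sample`` and whose remaining headers are clone labels; entries are
decimal fractions.  Clone trees are two-column ``parent<TAB>child`` edge
lists with the root inferred as the unique vertex that is never a child
(single-vertex trees are a one-line file holding just the label).  Paired
clones serialize as ``i|j``, so ``|`` is forbidden in clone labels.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Hashable

import pandas as pd

from .model import (
    CloneTree,
    PciSolution,
    PctiSolution,
    ProportionMatrix,
    ValidationError,
    consistency_error,
    project_proportions,
    validate_proportion_matrix,
)

__all__ = [
    "read_proportion_matrix",
    "write_proportion_matrix",
    "read_clone_tree",
    "write_clone_tree",
    "parse_paired_label",
    "format_paired_label",
    "write_solution",
    "read_paired_clone_tree",
    "RunManifest",
]

#: significant digits used for all fraction serialization (lossless round trip)
DIGITS = 12


class ParseError(ValidationError):
    """Raised on malformed input files; the message names the file and line."""


def _check_label(label: str, path) -> str:
    if "|" in label:
        raise ParseError(f"{path}: clone label {label!r} contains the reserved character '|'")
    return label


def read_proportion_matrix(
    path, tolerance: float = 1e-6, renormalize: bool = False
) -> ProportionMatrix:
    """Read and validate a samples-by-clones proportion table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: unreadable TSV ({exc})") from exc
    if df.columns.empty or df.columns[0] != "sample":
        raise ParseError(f"{path}: first column header must be 'sample', got {list(df.columns)[:1]!r}")
    clones = [_check_label(c, path) for c in df.columns[1:]]
    if not clones:
        raise ParseError(f"{path}: no clone columns")
    samples = df["sample"].tolist()
    try:
        values = df[df.columns[1:]].astype(float).to_numpy()
    except ValueError as exc:
        for line, row in enumerate(df[df.columns[1:]].itertuples(index=False), start=2):
            for v in row:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(f"{path}: non-numeric entry {v!r} on line {line}") from exc
        raise ParseError(f"{path}: non-numeric entry ({exc})") from exc
    try:
        return validate_proportion_matrix(
            values, sample_ids=samples, clone_ids=clones, tolerance=tolerance, renormalize=renormalize
        )
    except ParseError:
        raise
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_proportion_matrix(U: ProportionMatrix, path, label=str) -> None:
    """Write a proportion matrix in the standard TSV dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample\t" + "\t".join(label(c) for c in U.clone_ids) + "\n")
        for p, sid in enumerate(U.sample_ids):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.{DIGITS}g}" for v in U.values[p]) + "\n")


def read_clone_tree(path) -> CloneTree:
    """Read a parent->child edge list; the root is the vertex with no parent."""
    path = Path(path)
    edges = []
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty tree file")
    if len(lines) == 1 and "\t" not in lines[0]:
        return CloneTree.single_vertex(_check_label(lines[0], path))
    for ln_no, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {ln_no}: expected 'parent<TAB>child', got {ln!r}")
        edges.append((_check_label(fields[0], path), _check_label(fields[1], path)))
    try:
        return CloneTree.from_edges(edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_clone_tree(T: CloneTree, path, label=str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if not T.edges:
            fh.write(label(T.root) + "\n")
        else:
            for p, c in T.edges:
                fh.write(f"{label(p)}\t{label(c)}\n")


def format_paired_label(pair: tuple) -> str:
    return f"{pair[0]}|{pair[1]}"


def parse_paired_label(text: str) -> tuple[str, str]:
    parts = text.split("|")
    if len(parts) != 2:
        raise ParseError(f"paired clone label {text!r} is not of the form 'i|j'")
    return parts[0], parts[1]


def read_paired_clone_tree(path) -> CloneTree:
    """Read a clone tree whose vertices are serialized paired labels ``i|j``."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty tree file")
    if len(lines) == 1 and "\t" not in lines[0]:
        return CloneTree.single_vertex(parse_paired_label(lines[0]))
    edges = []
    for ln_no, ln in enumerate(lines, start=1):
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}: line {ln_no}: expected 'parent<TAB>child', got {ln!r}")
        edges.append((parse_paired_label(fields[0]), parse_paired_label(fields[1])))
    try:
        return CloneTree.from_edges(edges)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


@dataclass
class RunManifest:
    """Machine-readable record of one solver run."""

    command: str
    parameters: dict
    input_checksums: dict = field(default_factory=dict)
    seed: int | None = None
    backend: str = "highs"
    objective: float | None = None
    status: str = "optimal"
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_solution(
    solution: PciSolution | PctiSolution,
    out_dir,
    U1: ProportionMatrix | None = None,
    U2: ProportionMatrix | None = None,
    manifest: RunManifest | None = None,
) -> list[Path]:
    """Serialize a solution into a directory (deterministic file set).

    Writes ``clones.txt`` (one ``i|j`` label per line, sorted),
    ``proportions.tsv``, ``tree.tsv`` for tree-aware solutions, a
    per-feature ``corrections.tsv`` when the inputs are supplied, and
    ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    clones_path = out_dir / "clones.txt"
    clones_path.write_text(
        "".join(format_paired_label(c) + "\n" for c in sorted(solution.clones, key=str))
    )
    written.append(clones_path)

    props_path = out_dir / "proportions.tsv"
    write_proportion_matrix(solution.proportions, props_path, label=format_paired_label)
    written.append(props_path)

    if isinstance(solution, PctiSolution):
        tree_path = out_dir / "tree.tsv"
        write_clone_tree(solution.tree, tree_path, label=format_paired_label)
        written.append(tree_path)

    if U1 is not None and U2 is not None:
        rows = []
        for feature, U_in in ((1, U1), (2, U2)):
            proj = project_proportions(
                solution.proportions.clone_ids, solution.proportions, feature, U_in.clone_ids
            )
            for p, sid in enumerate(U_in.sample_ids):
                for k, clone in enumerate(U_in.clone_ids):
                    rows.append(
                        {
                            "feature": feature,
                            "sample": sid,
                            "clone": clone,
                            "input": U_in.values[p, k],
                            "integrated": proj.values[p, k],
                            "correction": abs(proj.values[p, k] - U_in.values[p, k]),
                        }
                    )
        corr_path = out_dir / "corrections.tsv"
        pd.DataFrame(rows).to_csv(corr_path, sep="\t", index=False, float_format=f"%.{DIGITS}g")
        written.append(corr_path)

    if manifest is None:
        objective = (
            solution.total_correction
            if isinstance(solution, PctiSolution)
            else float(solution.n_clones)
        )
        manifest = RunManifest(
            command="write_solution", parameters={}, objective=objective, status=solution.status
        )
    if manifest.objective is None and U1 is not None and U2 is not None:
        manifest.objective = consistency_error(
            solution.proportions.clone_ids, solution.proportions, U1, U2
        )
    manifest_path = out_dir / "manifest.json"
    manifest.write(manifest_path)
    written.append(manifest_path)
    return written
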