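import numpy as np
import pytest

from paction import CloneTree, ProportionMatrix, ThreePartitionInstance


def random_proportions(m: int, n: int, rng, labels=None, concentration: float = 1.0):
    """Random valid proportion matrix: Dirichlet rows on the n-simplex."""
    labels = tuple(labels) if labels is not None else tuple(range(1, n + 1))
    return ProportionMatrix(tuple(range(1, m + 1)), labels, rng.dirichlet([concentration] * n, size=m))


def random_clone_tree(n: int, rng, labels=None) -> CloneTree:
    """Random rooted tree on n labeled clones by uniform-parent attachment."""
    labels = list(labels) if labels is not None else list(range(1, n + 1))
    if n == 1:
        return CloneTree.single_vertex(labels[0])
    edges = []
    for v in range(1, n):
        parent = labels[int(rng.integers(v))]
        edges.append((parent, labels[v]))
    return CloneTree.from_edges(edges, root=labels[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def solvable_q2():
    """3-partition instance with a valid partition {11,14,15} / {12,13,15}."""
    return ThreePartitionInstance(A=(11, 14, 15, 12, 13, 15), B=40, q=2, known_partition=(1, 1, 1, 2, 2, 2))


@pytest.fixture(scope="session")
def unsolvable_q2():
    """3-partition instance where no triple sums to 40."""
    return ThreePartitionInstance(A=(11, 11, 11, 19, 14, 14), B=40, q=2)
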