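import numpy as np
import pytest

from phewasrank.containers import (
    DirectedDependencyNetwork,
    DrugTargetTable,
    GeneScoreTable,
    RankedGeneList,
)


@pytest.fixture
def triangle_network():
    """A -> B, A -> C, B -> C: one dangling node (C), one hub source (A)."""
    return DirectedDependencyNetwork.from_edges([("A", "B"), ("A", "C"), ("B", "C")])


@pytest.fixture
def small_scores():
    return GeneScoreTable(("A", "B", "C"), (0.1, 0.316227766, 0.562341325))


@pytest.fixture
def ranked_ten():
    entries = tuple((k + 1, f"g{k:02d}", float(10 - k)) for k in range(10))
    return RankedGeneList(entries)


@pytest.fixture
def drug_table():
    records = (
        ("D1", "G1"),
        ("D1", "G2"),
        ("D2", "G2"),
        ("D3", "G3"),
    )
    return DrugTargetTable(records, {"D1": True, "D2": False, "D3": True})


def random_network(rng: np.random.Generator, n_max: int = 200):
    """Random directed network (no self-loops, no duplicates) for property tests."""
    n = int(rng.integers(2, n_max + 1))
    nodes = tuple(f"n{k:03d}" for k in range(n))
    density = rng.uniform(0.5, 3.0)  # expected out-degree
    n_edges = int(min(n * density, n * (n - 1)))
    edges = set()
    while len(edges) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.add((nodes[i], nodes[j]))
    return DirectedDependencyNetwork(nodes, frozenset(edges))
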