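"""In-memory containers for the prioritization pipeline.

Gene identifiers are opaque, case-sensitive string tokens throughout: no
symbol normalization is attempted. Every container validates its own
invariants on construction so downstream code can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

__all__ = [
    "GeneScoreTable",
    "DirectedDependencyNetwork",
    "RankedGeneList",
    "GeneSetCollection",
    "DrugTargetTable",
    "ContingencyTable2x2",
]


@dataclass
class GeneScoreTable:
    """Per-gene association p-values and derived initial scores.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene tokens.
    p_values : sequence of float
        Association p-values, already clamped into ``(0, 1]``.
    f : sequence of float, optional
        Initial propagation scores (``-log(p)``); filled by
        :func:`phewasrank.rank.initial_scores`. ``None`` until scored.
    """

    gene_ids: Tuple[str, ...]
    p_values: Tuple[float, ...]
    f: Tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g) for g in self.gene_ids)
        self.p_values = tuple(float(p) for p in self.p_values)
        if len(self.gene_ids) != len(self.p_values):
            raise ValueError("gene_ids and p_values length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene_id(s): {dupes[:5]}")
        for g, p in zip(self.gene_ids, self.p_values):
            if not (0.0 < p <= 1.0):
                raise ValueError(f"p-value for {g} outside (0, 1]: {p}")
        if self.f is not None:
            self.f = tuple(float(x) for x in self.f)
            if len(self.f) != len(self.gene_ids):
                raise ValueError("f length mismatch")
            if any(x < 0 for x in self.f):
                raise ValueError("initial scores must be non-negative")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def p_of(self) -> Dict[str, float]:
        return dict(zip(self.gene_ids, self.p_values))

    def f_of(self) -> Dict[str, float]:
        if self.f is None:
            raise ValueError("initial scores not yet computed")
        return dict(zip(self.gene_ids, self.f))

    def to_frame(self) -> pd.DataFrame:
        data = {"gene_id": self.gene_ids, "p_value": self.p_values}
        if self.f is not None:
            data["f"] = self.f
        return pd.DataFrame(data)


@dataclass
class DirectedDependencyNetwork:
    """Directed, unweighted gene-dependency network.

    An edge ``(i, j)`` means gene *j* depends on gene *i*: during
    propagation node *i* distributes its score equally among its
    out-neighbors. Self-loops and duplicate edges are rejected here
    (readers drop/dedupe before construction).
    """

    nodes: Tuple[str, ...]
    edges: FrozenSet[Tuple[str, str]]

    def __post_init__(self) -> None:
        self.nodes = tuple(str(n) for n in self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        self.edges = frozenset((str(a), str(b)) for a, b in self.edges)
        node_set = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a}, {b}) references unknown node")
        self._out_degree = {n: 0 for n in self.nodes}
        for a, _ in self.edges:
            self._out_degree[a] += 1

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def out_degree(self, node: str) -> int:
        return self._out_degree[node]

    def out_degrees(self) -> Dict[str, int]:
        return dict(self._out_degree)

    def subgraph(self, keep: Iterable[str]) -> "DirectedDependencyNetwork":
        """Induced subnetwork on ``keep`` (order of ``self.nodes`` retained)."""
        keep = set(keep)
        nodes = tuple(n for n in self.nodes if n in keep)
        edges = frozenset((a, b) for a, b in self.edges if a in keep and b in keep)
        return DirectedDependencyNetwork(nodes, edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[str, str]],
        nodes: Iterable[str] | None = None,
    ) -> "DirectedDependencyNetwork":
        """Build from an edge iterable; nodes default to those appearing in edges."""
        edge_set = frozenset((str(a), str(b)) for a, b in edges if a != b)
        if nodes is None:
            seen: List[str] = []
            for a, b in sorted(edge_set):
                for n in (a, b):
                    if n not in seen:
                        seen.append(n)
            nodes = seen
        return cls(tuple(nodes), edge_set)


@dataclass
class RankedGeneList:
    """Genes sorted by score, best first; ranks are 1..K contiguous."""

    entries: Tuple[Tuple[int, str, float], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(r), str(g), float(s)) for r, g, s in self.entries)
        for idx, (r, _, s) in enumerate(entries):
            if r != idx + 1:
                raise ValueError("ranks must be 1..K contiguous")
            if idx > 0 and s > entries[idx - 1][2]:
                raise ValueError("scores must be non-increasing with rank")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def gene_ids(self) -> Tuple[str, ...]:
        return tuple(g for _, g, _ in self.entries)

    @property
    def scores(self) -> Tuple[float, ...]:
        return tuple(s for _, _, s in self.entries)

    def rank_of(self) -> Dict[str, int]:
        return {g: r for r, g, _ in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rank", "gene_id", "score"])


@dataclass
class GeneSetCollection:
    """Named gene sets (disease references, pathway collections)."""

    sets: Dict[str, FrozenSet[str]]

    def __post_init__(self) -> None:
        clean: Dict[str, FrozenSet[str]] = {}
        for name, members in self.sets.items():
            members = frozenset(str(g) for g in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = members
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> FrozenSet[str]:
        return self.sets[name]

    def names(self) -> List[str]:
        return sorted(self.sets)


@dataclass
class DrugTargetTable:
    """Agent-to-target-gene links with per-agent clinical-support flags."""

    records: Tuple[Tuple[str, str], ...]
    support: Dict[str, bool]

    def __post_init__(self) -> None:
        records = tuple((str(a), str(g)) for a, g in self.records)
        if len(set(records)) != len(records):
            raise ValueError("duplicate (agent, target) pairs")
        self.records = records
        agents = {a for a, _ in records}
        self.support = {str(a): bool(v) for a, v in self.support.items()}
        missing = agents - set(self.support)
        if missing:
            raise ValueError(f"agents without support flag: {sorted(missing)[:5]}")

    @property
    def agents(self) -> List[str]:
        return sorted({a for a, _ in self.records})

    def targets_of(self, agent: str) -> FrozenSet[str]:
        return frozenset(g for a, g in self.records if a == agent)

    def targets_by_agent(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for a, g in self.records:
            out.setdefault(a, set()).add(g)
        return out

    def all_targets(self) -> FrozenSet[str]:
        return frozenset(g for _, g in self.records)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = strategy/comparison arm, columns = in/out of reference.

    Layout::

        a  b      (arm 1: in-reference, not-in-reference)
        c  d      (arm 2: in-reference, not-in-reference)
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> Tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)
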