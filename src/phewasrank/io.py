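"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialect: UTF-8, tab-separated, ``#``-prefixed comment lines ignored. A
single header row is auto-detected in numeric-column files when the
numeric field does not parse. GMT follows the usual convention
(name, description, member genes).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, FrozenSet, List, Set, Tuple

from .containers import (
    DirectedDependencyNetwork,
    DrugTargetTable,
    GeneScoreTable,
    GeneSetCollection,
    RankedGeneList,
)

logger = logging.getLogger(__name__)

DEFAULT_P_MIN = 1e-300


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


def _data_lines(path) -> List[Tuple[int, List[str]]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line.split("\t")))
    return out


def read_gene_scores(path, p_min: float = DEFAULT_P_MIN) -> GeneScoreTable:
    """Read a two-column (gene_id, p_value) TSV into a :class:`GeneScoreTable`.

    ``p = 0`` is clamped up to ``p_min`` so that ``-log p`` stays finite;
    negative p-values or p > 1 are rejected, as are duplicate gene ids.
    """
    lines = _data_lines(path)
    genes: List[str] = []
    pvals: List[float] = []
    for idx, (lineno, fields) in enumerate(lines):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        gene, p_str = fields[0].strip(), fields[1].strip()
        try:
            p = float(p_str)
        except ValueError:
            if idx == 0:  # header row
                continue
            raise ParseError(f"{path}:{lineno}: p-value {p_str!r} is not numeric")
        if p < 0 or p > 1:
            raise ParseError(f"{path}:{lineno}: p-value {p} outside [0, 1]")
        genes.append(gene)
        pvals.append(max(p, p_min))
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene_id(s): {dupes[:5]}")
    return GeneScoreTable(tuple(genes), tuple(pvals))


def write_gene_scores(table: GeneScoreTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tp_value\n")
        for g, p in zip(table.gene_ids, table.p_values):
            fh.write(f"{g}\t{p!r}\n")


def read_edge_list(path) -> DirectedDependencyNetwork:
    """Read a two-column (source, target) TSV edge list.

    Duplicate edges are collapsed; self-loops are dropped with a warning
    (score propagation splits a node's score among its out-neighbors, a
    semantics that is ill-posed for self-dependency).
    """
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty edge list")
    edges: Set[Tuple[str, str]] = set()
    nodes: List[str] = []
    seen: Set[str] = set()
    for lineno, fields in lines:
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty node id")
        if a == b:
            logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
            continue
        edges.add((a, b))
        for n in (a, b):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    return DirectedDependencyNetwork(tuple(nodes), frozenset(edges))


def write_edge_list(net: DirectedDependencyNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: Dict[str, FrozenSet[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 gene"
            )
        name = fields[0].strip()
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = frozenset(g.strip() for g in fields[2:] if g.strip())
        if not members:
            raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_drug_targets(path) -> DrugTargetTable:
    """Read a 3-column (agent_id, target_gene_id, supported in {0,1}) TSV.

    An agent's clinical-support flag is the OR over its rows.
    """
    records: List[Tuple[str, str]] = []
    support: Dict[str, bool] = {}
    header_skipped = False
    for idx, (lineno, fields) in enumerate(_data_lines(path)):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        agent, gene, flag = (f.strip() for f in fields[:3])
        if flag not in ("0", "1"):
            if idx == 0 and not header_skipped:
                header_skipped = True
                continue
            raise ParseError(f"{path}:{lineno}: support flag must be 0 or 1, got {flag!r}")
        pair = (agent, gene)
        if pair not in records:
            records.append(pair)
        support[agent] = support.get(agent, False) or flag == "1"
    return DrugTargetTable(tuple(records), support)


def write_drug_targets(table: DrugTargetTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("agent_id\ttarget_gene_id\tsupported\n")
        for a, g in sorted(table.records):
            fh.write(f"{a}\t{g}\t{int(table.support[a])}\n")


def read_ranked(path) -> RankedGeneList:
    """Read a (rank, gene_id, score) TSV back into a :class:`RankedGeneList`."""
    entries = []
    for idx, (lineno, fields) in enumerate(_data_lines(path)):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            rank = int(fields[0])
        except ValueError:
            if idx == 0:
                continue
            raise ParseError(f"{path}:{lineno}: rank {fields[0]!r} is not an integer")
        entries.append((rank, fields[1].strip(), float(fields[2])))
    return RankedGeneList(tuple(entries))


def write_ranked(ranked: RankedGeneList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene_id\tscore\n")
        for rank, gene, score in ranked.entries:
            fh.write(f"{rank}\t{gene}\t{score!r}\n")
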