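"""Candidate-agent prediction from a prioritized gene set.

An agent is predicted when at least one of its known targets falls in
the query gene set; predictions are then scored by the fraction backed
by clinical evidence, and two strategies' support rates are compared
with the same uncorrected chi-squared test used for gene enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Set, Tuple

from .containers import ContingencyTable2x2, DrugTargetTable
from .enrich import Chi2Result, chi2_2x2

__all__ = [
    "AgentPrediction",
    "predict_agents",
    "clinical_support_rate",
    "compare_support",
]


@dataclass(frozen=True)
class AgentPrediction:
    agent_id: str
    hit_targets: FrozenSet[str]
    supported: bool


def predict_agents(gene_set: Set[str], table: DrugTargetTable) -> List[AgentPrediction]:
    """Agents with >= 1 target inside ``gene_set``, in lexicographic order."""
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    out: List[AgentPrediction] = []
    for agent, targets in sorted(table.targets_by_agent().items()):
        hits = frozenset(targets & gene_set)
        if hits:
            out.append(AgentPrediction(agent, hits, table.support[agent]))
    return out


def clinical_support_rate(predictions: List[AgentPrediction]) -> Tuple[int, int, float]:
    """(n_supported, n_total, percentage to 2 decimals) over predicted agents."""
    if not predictions:
        raise ValueError("no predicted agents")
    n_total = len(predictions)
    n_supported = sum(p.supported for p in predictions)
    return n_supported, n_total, round(100.0 * n_supported / n_total, 2)


def compare_support(a: Tuple[int, int], b: Tuple[int, int]) -> Chi2Result:
    """Chi-squared comparison of two (n_supported, n_total) support rates."""
    (sa, na), (sb, nb) = a, b
    if na <= 0 or nb <= 0:
        raise ValueError("both totals must be positive")
    if sa > na or sb > nb:
        raise ValueError("supported count exceeds total")
    table = ContingencyTable2x2(sa, na - sa, sb, nb - sb)
    return chi2_2x2(table)
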