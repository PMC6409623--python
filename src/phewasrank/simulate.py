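"""Seeded generators for every input the pipeline consumes.

The simulator plants a known set of disease genes and threads that
ground truth through every generated table: disease genes receive
enriched (small) association p-values, the directed network mixes
preferentially inside the disease module, the reference database is a
noisy read-out of the planted set, and clinically supported agents
preferentially target disease genes. Each stage is a pure function of
(config, seed), so identical configs reproduce byte-identical outputs.

Default parameters describe the regime the package is benchmarked in:
2000 genes, a 5% planted disease module, Beta(0.2, 1) disease p-values,
preferential attachment with 5 out-edges per node and a homophily
multiplier of 8 on disease-disease attachment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from .containers import (
    DirectedDependencyNetwork,
    DrugTargetTable,
    GeneScoreTable,
    GeneSetCollection,
)
from .depnet import ExpressionMatrix, PhenotypeVector

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_gene_scores",
    "simulate_network",
    "simulate_reference_db",
    "simulate_drug_targets",
    "simulate_expression",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    n_genes : size of the gene universe.
    pi_disease : fraction of genes planted as disease genes.
    beta_a : Beta(a, 1) shape for disease-gene p-values; a < 1 pushes
        mass toward 0 (stronger association signal).
    m_edges : out-edges drawn by each non-root node during attachment.
    homophily : multiplier (>= 1) on attachment weight when both
        endpoints are disease genes; 1 means no module structure.
    n_agents : number of chemical agents.
    targets_per_agent : distinct targets drawn per agent.
    support_fraction : fraction of agents flagged clinically supported.
    support_enrichment : weight multiplier (>= 1) on disease genes when a
        supported agent draws its targets; unsupported agents draw
        uniformly.
    db_sensitivity / db_fpr : probabilities that a disease / null gene
        enters the reference database.
    """

    n_genes: int = 2000
    pi_disease: float = 0.05
    beta_a: float = 0.2
    m_edges: int = 5
    homophily: float = 8.0
    n_agents: int = 300
    targets_per_agent: int = 3
    support_fraction: float = 0.15
    support_enrichment: float = 8.0
    db_sensitivity: float = 0.8
    db_fpr: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not (0 < self.pi_disease < 1):
            raise ValueError("pi_disease must be in (0, 1)")
        if not (0 < self.beta_a <= 1):
            raise ValueError("beta_a must be in (0, 1]")
        if self.m_edges < 1 or self.m_edges >= self.n_genes:
            raise ValueError("m_edges must satisfy 1 <= m_edges < n_genes")
        if self.homophily < 1:
            raise ValueError("homophily must be >= 1")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (1 <= self.targets_per_agent <= self.n_genes):
            raise ValueError("targets_per_agent must be in [1, n_genes]")
        if not (0 <= self.support_fraction <= 1):
            raise ValueError("support_fraction must be in [0, 1]")
        if self.support_enrichment < 1:
            raise ValueError("support_enrichment must be >= 1")
        for name in ("db_sensitivity", "db_fpr"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth carried across generation stages."""

    disease_genes: FrozenSet[str]
    gene_ids: Tuple[str, ...]


def _gene_ids(n: int) -> Tuple[str, ...]:
    width = len(str(n))
    return tuple(f"G{k:0{width}d}" for k in range(1, n + 1))


def simulate_gene_scores(config: SimulationConfig) -> Tuple[GeneScoreTable, SyntheticTruth]:
    """Gene-level p-values with a disease-enriched small-p subpopulation.

    Disease genes draw p ~ Beta(beta_a, 1); null genes draw p ~ U(0, 1).
    A small floor keeps every p strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_disease = round(config.pi_disease * config.n_genes)
    disease = frozenset(rng.choice(genes, size=n_disease, replace=False).tolist())
    p = rng.uniform(size=config.n_genes)
    is_disease = np.array([g in disease for g in genes])
    p[is_disease] = rng.beta(config.beta_a, 1.0, size=int(is_disease.sum()))
    p = np.clip(p, 1e-300, 1.0)
    table = GeneScoreTable(genes, tuple(p.tolist()))
    return table, SyntheticTruth(disease, genes)


def simulate_network(
    truth: SyntheticTruth, config: SimulationConfig
) -> DirectedDependencyNetwork:
    """Directed homophilous preferential-attachment network.

    Nodes arrive in a random order; each non-root node draws ``m_edges``
    distinct out-neighbors among earlier nodes with weight proportional
    to ``(in_degree + 1) * homophily`` when both endpoints are disease
    genes, else ``(in_degree + 1)``. The first ``m_edges`` nodes are
    roots with no out-edges. Gives heavy-tailed in-degrees and, for
    homophily > 1, a planted disease module.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    genes = truth.gene_ids
    n = len(genes)
    m = config.m_edges
    order = rng.permutation(n)
    is_disease = np.array([genes[i] in truth.disease_genes for i in order])
    in_deg = np.zeros(n)
    edges: Set[Tuple[str, str]] = set()
    for k in range(m, n):
        w = in_deg[:k] + 1.0
        if is_disease[k] and config.homophily > 1:
            w = np.where(is_disease[:k], w * config.homophily, w)
        targets = rng.choice(k, size=m, replace=False, p=w / w.sum())
        for t in targets:
            edges.add((genes[order[k]], genes[order[t]]))
            in_deg[t] += 1
    return DirectedDependencyNetwork(genes, frozenset(edges))


def simulate_reference_db(
    truth: SyntheticTruth, config: SimulationConfig, set_name: str = "disease_reference"
) -> GeneSetCollection:
    """Noisy reference database: Bernoulli read-out of the planted set.

    Disease genes enter with probability ``db_sensitivity``; null genes
    with probability ``db_fpr``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    members = set()
    for g in truth.gene_ids:
        prob = config.db_sensitivity if g in truth.disease_genes else config.db_fpr
        if rng.uniform() < prob:
            members.add(g)
    if not members:
        # degenerate parameter corner (sensitivity = fpr = 0)
        return GeneSetCollection({})
    return GeneSetCollection({set_name: frozenset(members)})


def simulate_drug_targets(
    truth: SyntheticTruth, config: SimulationConfig
) -> DrugTargetTable:
    """Agent-target table with support labels tied to the planted module.

    A ``support_fraction`` of agents is flagged clinically supported;
    those draw their ``targets_per_agent`` distinct targets with weight
    ``support_enrichment`` on disease genes, while unsupported agents
    draw uniformly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = np.array(truth.gene_ids)
    is_disease = np.array([g in truth.disease_genes for g in genes])
    n_supported = round(config.support_fraction * config.n_agents)
    width = len(str(config.n_agents))
    records: List[Tuple[str, str]] = []
    support: Dict[str, bool] = {}
    w_supported = np.where(is_disease, config.support_enrichment, 1.0)
    w_supported = w_supported / w_supported.sum()
    for k in range(config.n_agents):
        agent = f"D{k + 1:0{width}d}"
        supported = k < n_supported
        p = w_supported if supported else None
        targets = rng.choice(genes, size=config.targets_per_agent, replace=False, p=p)
        support[agent] = supported
        records.extend((agent, t) for t in sorted(targets))
    return DrugTargetTable(tuple(records), support)


def simulate_expression(
    truth: SyntheticTruth,
    config: SimulationConfig,
    n_samples: int = 100,
    effect: float = 2.0,
    chain_length: int = 3,
) -> Tuple[ExpressionMatrix, PhenotypeVector]:
    """Expression matrix with a phenotype-driven chain of disease genes.

    The phenotype is balanced binary. The first gene of a randomly chosen
    disease-gene chain is mean-shifted by ``effect`` in the poor-prognosis
    class; each later chain gene is regressed on its upstream neighbor
    (coefficient 0.8) plus unit noise. All other genes are standard
    normal, independent of the phenotype.
    """
    if n_samples < 16:
        raise ValueError("need n_samples >= 16")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = truth.gene_ids
    samples = tuple(f"S{k:04d}" for k in range(1, n_samples + 1))
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2 :] = 1
    labels = rng.permutation(labels)
    values = rng.normal(size=(len(genes), n_samples))
    disease_sorted = sorted(truth.disease_genes)
    chain_length = min(chain_length, len(disease_sorted))
    chain = rng.choice(disease_sorted, size=chain_length, replace=False)
    index = {g: i for i, g in enumerate(genes)}
    upstream = None
    for g in chain:
        i = index[g]
        if upstream is None:
            values[i] = rng.normal(size=n_samples) + effect * labels
        else:
            values[i] = 0.8 * values[upstream] + rng.normal(size=n_samples)
        upstream = i
    expr = ExpressionMatrix(genes, samples, values)
    pheno = PhenotypeVector(samples, labels)
    return expr, pheno
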