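"""Model / Results interface over the propagation engine.

`PheWASRank` couples a gene-score table with a directed dependency
network; `fit()` runs the damped propagation to its fixed point and
returns a `PheWASRankResults` carrying the converged scores, the
ranking, convergence diagnostics, and the downstream validation and
drug-prediction methods. Mirrors the model-then-results idiom of
statistical modelling packages: the model is immutable inputs plus
configuration, the results object owns everything derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .containers import (
    ContingencyTable2x2,
    DirectedDependencyNetwork,
    DrugTargetTable,
    GeneScoreTable,
    GeneSetCollection,
    RankedGeneList,
)
from .drugs import AgentPrediction, clinical_support_rate, predict_agents
from .enrich import (
    Chi2Result,
    EnrichmentRow,
    KSResult,
    chi2_2x2,
    ks_top_enrichment,
    over_representation,
    overlap_stats,
)
from .rank import (
    RankConfig,
    RankResult,
    generank_closed_form,
    generank_iterate,
    initial_scores,
    rank_genes,
    top_k,
)

__all__ = ["PheWASRank", "PheWASRankResults"]


class PheWASRank:
    """Network propagation model for PheWAS-derived gene scores.

    Parameters
    ----------
    scores : GeneScoreTable
        Gene association p-values; initial scores are (re)computed from
        them as ``-log_base(p)``.
    network : DirectedDependencyNetwork
        Directed gene-dependency network.
    config : RankConfig
        Damping weight d, convergence threshold, log base.
    universe : {"intersection", "network"}
        Gene universe for the fit. "intersection" (default) ranks the
        genes both scored and present in the network; "network" keeps
        every network node, giving unscored nodes f = 0.
    transpose : bool
        Reverse the stored edge orientation before propagating, for
        networks whose files encode dependency the other way round.
    """

    def __init__(
        self,
        scores: GeneScoreTable,
        network: DirectedDependencyNetwork,
        config: RankConfig = RankConfig(),
        universe: str = "intersection",
        transpose: bool = False,
    ):
        if universe not in ("intersection", "network"):
            raise ValueError("universe must be 'intersection' or 'network'")
        self.config = config
        self.universe = universe
        self.transpose = transpose
        self.scores = initial_scores(scores, config)
        scored = set(self.scores.gene_ids)
        if universe == "intersection":
            self.network = network.subgraph(scored & set(network.nodes))
        else:
            self.network = network
        if self.network.n_nodes == 0:
            raise ValueError("empty gene universe: no scored gene appears in the network")

    @classmethod
    def from_files(
        cls,
        scores_path,
        network_path,
        config: RankConfig = RankConfig(),
        **kwargs,
    ) -> "PheWASRank":
        """Build the model from a (gene, p) TSV and an edge-list TSV."""
        table = pio.read_gene_scores(scores_path, p_min=config.p_min)
        net = pio.read_edge_list(network_path)
        return cls(table, net, config, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        network: DirectedDependencyNetwork,
        config: RankConfig = RankConfig(),
        gene_col: str = "gene_id",
        p_col: str = "p_value",
        **kwargs,
    ) -> "PheWASRank":
        """Build the model from a DataFrame with gene-id and p-value columns."""
        p = frame[p_col].astype(float).clip(lower=config.p_min)
        table = GeneScoreTable(tuple(frame[gene_col].astype(str)), tuple(p))
        return cls(table, network, config, **kwargs)

    def initial_f(self) -> Dict[str, float]:
        """Initial scores restricted to the fit universe (missing nodes get 0)."""
        f = self.scores.f_of()
        return {n: f.get(n, 0.0) for n in self.network.nodes}

    def fit(self, method: str = "iterate") -> "PheWASRankResults":
        """Run the propagation to its fixed point.

        method : {"iterate", "direct"}
            "iterate" applies the update until the one-norm residual
            falls below epsilon (the production path); "direct" solves
            the equivalent sparse linear system exactly.
        """
        f = self.initial_f()
        if method == "iterate":
            result = generank_iterate(self.network, f, self.config, self.transpose)
        elif method == "direct":
            scores = generank_closed_form(
                self.network, f, self.config.d, self.transpose
            )
            result = RankResult(scores, 0, 0.0, True)
        else:
            raise ValueError("method must be 'iterate' or 'direct'")
        return PheWASRankResults(self, result)


@dataclass
class PheWASRankResults:
    """Fitted propagation scores with ranking, diagnostics and validation."""

    model: PheWASRank
    raw: RankResult

    def __post_init__(self) -> None:
        self.ranking: RankedGeneList = rank_genes(self.raw)

    # -- basic accessors -------------------------------------------------
    @property
    def scores(self) -> pd.Series:
        s = pd.Series(self.raw.scores, name="score")
        return s.sort_values(ascending=False, kind="stable")

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def n_iterations(self) -> int:
        return self.raw.n_iterations

    def top(self, k: int = 100) -> Set[str]:
        """The top-k gene set of the fitted ranking."""
        return top_k(self.ranking, k)

    def to_frame(self) -> pd.DataFrame:
        return self.ranking.to_frame()

    # -- validation ------------------------------------------------------
    def overlap_with(self, reference: Set[str], k: Optional[int] = None) -> Tuple[int, float]:
        """Overlap count and percentage of the (top-k) ranked genes in a reference set."""
        genes = self.top(k) if k is not None else set(self.ranking.gene_ids)
        return overlap_stats(genes, reference)

    def enrichment_vs(
        self,
        other: Set[str],
        reference: Set[str],
        k: int = 100,
    ) -> Tuple[ContingencyTable2x2, Chi2Result]:
        """Chi-squared comparison of this fit's top-k against another gene set.

        Builds the 2x2 table (in/out of ``reference`` by strategy) for the
        fitted top-k versus ``other`` (e.g. the top-k of the raw ordering)
        and applies the uncorrected Pearson test.
        """
        mine = self.top(k)
        a, _ = overlap_stats(mine, reference)
        c, _ = overlap_stats(other, reference)
        table = ContingencyTable2x2(a, len(mine) - a, c, len(other) - c)
        return table, chi2_2x2(table)

    def ks_enrichment(self, targets: Set[str], two_sided: bool = False) -> KSResult:
        """KS test of whether ``targets`` crowd the top of the fitted ranking."""
        return ks_top_enrichment(self.ranking, targets, two_sided=two_sided)

    def over_representation(
        self,
        collections: GeneSetCollection,
        k: int = 100,
        cutoff: float = 0.05,
    ) -> List[EnrichmentRow]:
        """Hypergeometric ORA of the top-k set against gene-set collections.

        The universe defaults to all ranked genes (the analysis universe).
        """
        return over_representation(
            self.top(k), set(self.ranking.gene_ids), collections, cutoff
        )

    # -- drug prediction -------------------------------------------------
    def predict_agents(
        self, table: DrugTargetTable, k: int = 100
    ) -> List[AgentPrediction]:
        """Agents with >= 1 target among the top-k ranked genes."""
        return predict_agents(self.top(k), table)

    def support_rate(
        self, table: DrugTargetTable, k: int = 100
    ) -> Tuple[int, int, float]:
        """(n_supported, n_total, %) over agents predicted from the top-k set."""
        return clinical_support_rate(self.predict_agents(table, k))

    # -- presentation ----------------------------------------------------
    def summary(self, k: int = 10) -> str:
        """Plain-text fit summary: configuration, convergence, top genes."""
        cfg = self.model.config
        lines = [
            "PheWAS-Rank propagation results",
            "=" * 34,
            f"genes ranked:     {len(self.ranking)}",
            f"network edges:    {self.model.network.n_edges}",
            f"d (network wt):   {cfg.d}",
            f"epsilon:          {cfg.epsilon:g}",
            f"iterations:       {self.raw.n_iterations}",
            f"final residual:   {self.raw.final_residual:.3g}",
            f"converged:        {self.raw.converged}",
            "",
            f"top {min(k, len(self.ranking))} genes:",
            "rank  gene_id          score",
        ]
        for rank, gene, score in self.ranking.entries[:k]:
            lines.append(f"{rank:>4}  {gene:<15}  {score:.6f}")
        return "\n".join(lines)

    def plot_rank_vs_initial(self, ax=None):
        """Scatter of propagated score against initial -log10 p per gene."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.model.initial_f()
        genes = list(self.raw.scores)
        ax.scatter(
            [f[g] for g in genes],
            [self.raw.scores[g] for g in genes],
            s=8,
            alpha=0.5,
        )
        ax.set_xlabel("initial score  $-\\log_{10} p$")
        ax.set_ylabel("propagated score $r$")
        ax.set_title(f"PheWAS-Rank (d = {self.model.config.d})")
        return ax

    def plot_ks_ecdf(self, targets: Set[str], ax=None):
        """Empirical CDFs of target vs background rank positions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        targets = set(targets)
        t_ranks = sorted(r for r, g, _ in self.ranking.entries if g in targets)
        b_ranks = sorted(r for r, g, _ in self.ranking.entries if g not in targets)
        n = len(self.ranking)
        for ranks, label in ((t_ranks, "drug targets"), (b_ranks, "background")):
            if ranks:
                xs = np.array(ranks)
                ax.step(xs, np.arange(1, xs.size + 1) / xs.size, where="post", label=label)
        ax.set_xlim(0, n)
        ax.set_xlabel("rank position")
        ax.set_ylabel("ECDF")
        ax.legend()
        return ax
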