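"""Validation statistics for a ranked gene list.

Covers the four checks the prioritization is judged by: 2x2 Pearson
chi-squared enrichment against a disease reference, raw overlap
fractions, one-sided Kolmogorov-Smirnov enrichment of drug targets at
the top of the list, and generic hypergeometric over-representation of
gene-set collections with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ContingencyTable2x2, GeneSetCollection, RankedGeneList

__all__ = [
    "Chi2Result",
    "KSResult",
    "EnrichmentRow",
    "chi2_2x2",
    "overlap_stats",
    "ks_top_enrichment",
    "over_representation",
    "bh_adjust",
]


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class KSResult:
    D: float
    p_value: float
    n_targets: int
    n_background: int


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    universe_size: int
    query_size: int
    p_raw: float
    p_adjust: float
    significant: bool


def chi2_2x2(table: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-squared test on a 2x2 table, no continuity correction.

    Statistic: ``N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``, 1 degree of
    freedom, two-sided p from the chi-squared survival function. A zero
    marginal leaves the test undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if any(m == 0 for m in table.marginals):
        raise ValueError("chi-squared test undefined: zero marginal")
    n = table.total
    stat = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    return Chi2Result(float(stat), float(stats.chi2.sf(stat, 1)), 1)


def overlap_stats(genes: Set[str], reference: Set[str]) -> Tuple[int, float]:
    """Overlap count and percentage (2 decimals) of ``genes`` in ``reference``."""
    if not genes:
        raise ValueError("empty gene set")
    count = len(set(genes) & set(reference))
    return count, round(100.0 * count / len(genes), 2)


def ks_top_enrichment(
    ranked: RankedGeneList,
    targets: Set[str],
    two_sided: bool = False,
) -> KSResult:
    """Two-sample KS test: are target genes enriched toward the top of the list?

    Compares the rank positions of targets against non-targets. The
    default one-sided alternative is that targets sit at stochastically
    smaller (better) ranks: ``D = sup_t [F_targets(t) - F_background(t)]``
    over rank cutoffs ``t``, with the asymptotic one-sided p-value
    ``exp(-2 D^2 n m / (n + m))``. ``two_sided=True`` switches to
    ``D = sup |difference|`` with the two-sided asymptotic distribution.
    """
    targets = set(targets)
    in_list = set(ranked.gene_ids)
    target_ranks = np.array(sorted(r for r, g, _ in ranked.entries if g in targets))
    bg_ranks = np.array(sorted(r for r, g, _ in ranked.entries if g not in targets))
    if target_ranks.size == 0:
        raise ValueError("no target genes present in the ranked list")
    if bg_ranks.size == 0:
        raise ValueError("no background (non-target) genes present in the ranked list")
    n, m = target_ranks.size, bg_ranks.size
    cutoffs = np.arange(1, len(ranked) + 1)
    f_t = np.searchsorted(target_ranks, cutoffs, side="right") / n
    f_b = np.searchsorted(bg_ranks, cutoffs, side="right") / m
    diff = f_t - f_b
    if two_sided:
        d_stat = float(np.abs(diff).max())
        p = float(stats.kstwobign.sf(d_stat * np.sqrt(n * m / (n + m))))
    else:
        d_stat = float(max(diff.max(), 0.0))
        p = float(min(1.0, np.exp(-2.0 * d_stat**2 * n * m / (n + m))))
    return KSResult(d_stat, p, n, m)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


def over_representation(
    query: Set[str],
    universe: Set[str],
    collections: GeneSetCollection,
    cutoff: float = 0.05,
) -> List[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each collection set.

    Each set is intersected with the universe first; the upper-tail
    hypergeometric p (P[overlap >= observed]) is BH-adjusted across the
    collection and compared to ``cutoff``. Rows are sorted by raw p then
    set name.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        stray = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {stray}")
    names = collections.names()
    rows_raw = []
    for name in names:
        members = set(collections[name]) & universe
        k = len(members & query)
        # P[X >= k] for X ~ Hypergeom(N=|universe|, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows_raw.append((name, k, len(members), p))
    p_adj = bh_adjust([p for _, _, _, p in rows_raw])
    rows = [
        EnrichmentRow(
            set_name=name,
            overlap=k,
            set_size=size,
            universe_size=len(universe),
            query_size=len(query),
            p_raw=p,
            p_adjust=float(pa),
            significant=bool(pa < cutoff),
        )
        for (name, k, size, p), pa in zip(rows_raw, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_raw, r.set_name))
    return rows
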