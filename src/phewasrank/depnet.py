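"""Directed gene-dependency network construction from expression + prognosis.

The dependency semantics is phenotype-anchored: gene *j* is said to
depend on gene *i* when (1) gene *j*'s expression carries significant
information about the binary prognosis phenotype (mutual information,
assessed by label permutation), and (2) conditioning on gene *i*'s
expression removes at least a fraction ``tau`` of that information
(relative drop of conditional vs marginal mutual information). This
two-condition rule is this package's own concretization of
phenotype-conditional-MI dependency inference; see docs/methods.md for
its assumptions and limitations.

All information measures are plug-in (maximum-likelihood) estimates in
nats on equal-frequency-discretized expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .containers import DirectedDependencyNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeVector",
    "DependencyConfig",
    "discretize",
    "mutual_information",
    "conditional_mutual_information",
    "mi_permutation_pvalue",
    "build_dependency_network",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression. Constant rows are dropped."""

    genes: Tuple[str, ...]
    samples: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(str(g) for g in self.genes)
        self.samples = tuple(str(s) for s in self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values shape does not match genes x samples")
        if np.isnan(self.values).any():
            raise ValueError("missing values not allowed")
        keep = [i for i in range(len(self.genes)) if len(np.unique(self.values[i])) >= 2]
        if len(keep) < len(self.genes):
            dropped = [self.genes[i] for i in range(len(self.genes)) if i not in set(keep)]
            logger.warning("dropping %d constant gene row(s): %s", len(dropped), dropped[:5])
            self.genes = tuple(self.genes[i] for i in keep)
            self.values = self.values[keep]


@dataclass
class PhenotypeVector:
    """Per-sample binary class labels (e.g. good vs poor prognosis)."""

    samples: Tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.samples = tuple(str(s) for s in self.samples)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (len(self.samples),):
            raise ValueError("labels length does not match samples")
        classes = np.unique(self.labels)
        if classes.size != 2:
            raise ValueError(f"phenotype must have exactly 2 classes, found {classes.size}")
        self.labels = (self.labels == classes[1]).astype(np.int64)


@dataclass(frozen=True)
class DependencyConfig:
    n_bins: int = 3
    alpha: float = 0.05
    tau: float = 0.5
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def discretize(x: Sequence[float], n_bins: int) -> np.ndarray:
    """Equal-frequency binning into labels 0..n_bins-1; ties go to the lower bin.

    When the vector has fewer distinct values than bins, the bin count
    collapses to the number of distinct values with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    n_distinct = len(np.unique(x))
    if n_distinct < n_bins:
        warnings.warn(
            f"only {n_distinct} distinct value(s) for {n_bins} bins; collapsing",
            UserWarning,
            stacklevel=2,
        )
        n_bins = max(n_distinct, 1)
    if n_bins == 1:
        return np.zeros(x.shape, dtype=np.int64)
    # rank-based equal-frequency assignment; average ranks send ties low
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=np.int64)
    ranks[order] = np.arange(x.size)
    # tie groups share the minimum rank of the group
    min_rank: Dict[float, int] = {}
    for idx in order:
        v = x[idx]
        if v not in min_rank:
            min_rank[v] = ranks[idx]
    tied = np.array([min_rank[v] for v in x])
    bins = (tied * n_bins) // x.size
    return np.minimum(bins, n_bins - 1).astype(np.int64)


def _check_lengths(*vecs: np.ndarray) -> None:
    lengths = {v.size for v in vecs}
    if len(lengths) != 1:
        raise ValueError(f"length mismatch: {sorted(lengths)}")


def mutual_information(a: Sequence[int], b: Sequence[int]) -> float:
    """Plug-in mutual information I(a; b) in nats."""
    a = np.asarray(a)
    b = np.asarray(b)
    _check_lengths(a, b)
    n = a.size
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa @ pb))
    return float(max(terms[mask].sum(), 0.0))


def conditional_mutual_information(
    a: Sequence[int], b: Sequence[int], c: Sequence[int]
) -> float:
    """Plug-in conditional mutual information I(a; b | c) in nats.

    Computed as the p(c)-weighted average of the within-stratum MI.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    c = np.asarray(c)
    _check_lengths(a, b, c)
    total = 0.0
    n = c.size
    for level in np.unique(c):
        mask = c == level
        total += (mask.sum() / n) * mutual_information(a[mask], b[mask])
    return float(max(total, 0.0))


def mi_permutation_pvalue(
    x: Sequence[int],
    labels: Sequence[int],
    n_perm: int,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Permutation p-value for MI(x; labels) under label shuffling.

    Returns (observed MI, p) with the add-one estimate
    ``p = (1 + #{MI_perm >= MI_obs}) / (1 + n_perm)``, which is exact-level
    (super-uniform) under the null.
    """
    x = np.asarray(x)
    labels = np.asarray(labels)
    obs = mutual_information(x, labels)
    hits = 0
    for _ in range(n_perm):
        hits += mutual_information(x, rng.permutation(labels)) >= obs
    return obs, (1 + hits) / (1 + n_perm)


def build_dependency_network(
    expr: ExpressionMatrix,
    pheno: PhenotypeVector,
    config: DependencyConfig = DependencyConfig(),
) -> DirectedDependencyNetwork:
    """Infer the directed dependency network from expression and prognosis.

    Edge i -> j is added when gene j's marginal MI with the phenotype is
    permutation-significant at ``config.alpha`` AND conditioning on gene
    i drops that MI by at least the fraction ``config.tau``:
    ``[MI(X_j; y) - CMI(X_j; y | X_i)] / MI(X_j; y) >= tau``.
    """
    if expr.samples != pheno.samples:
        raise ValueError("expression and phenotype sample ids disagree")
    y = pheno.labels
    counts = np.bincount(y)
    if counts.min() < 8:
        raise ValueError(
            f"underpowered: need >= 8 samples per class, got {counts.tolist()}"
        )
    rng = np.random.default_rng(config.seed)
    n_genes = len(expr.genes)
    disc = np.stack([discretize(expr.values[i], config.n_bins) for i in range(n_genes)])

    mi_y = np.zeros(n_genes)
    significant = np.zeros(n_genes, dtype=bool)
    for j in range(n_genes):
        mi_y[j], p = mi_permutation_pvalue(disc[j], y, config.n_perm, rng)
        significant[j] = p < config.alpha

    edges = set()
    for j in np.flatnonzero(significant):
        if mi_y[j] <= 0:
            continue
        for i in range(n_genes):
            if i == j:
                continue
            cmi = conditional_mutual_information(disc[j], y, disc[i])
            if (mi_y[j] - cmi) / mi_y[j] >= config.tau:
                edges.add((expr.genes[i], expr.genes[j]))
    logger.info(
        "dependency network: %d genes, %d significant, %d edges",
        n_genes,
        int(significant.sum()),
        len(edges),
    )
    return DirectedDependencyNetwork(expr.genes, frozenset(edges))
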