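"""GeneRank-style score propagation over a directed dependency network.

The engine blends per-gene evidence (``f``, the negative log association
p-value) with network structure through a damping weight ``d``::

    r_j = (1 - d) * f_j + d * sum_i  w_ij * r_i / deg_i

where ``w_ij = 1`` when gene *j* depends on gene *i* and ``deg_i`` is the
out-degree of *i*: each node splits its current score equally among its
out-neighbors. Dangling nodes (out-degree 0) contribute nothing — there is
no teleportation term. For ``d < 1`` the update is a contraction (the
column sums of the damped propagation matrix are at most ``d``), so the
fixed point exists, is unique, and equals the solution of the linear
system ``(I - d P^T) r = (1 - d) f`` with ``P`` the out-degree-normalized
adjacency matrix.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Set, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .containers import DirectedDependencyNetwork, GeneScoreTable, RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "RankConfig",
    "RankResult",
    "initial_scores",
    "generank_iterate",
    "generank_closed_form",
    "rank_genes",
    "top_k",
    "propagation_matrix",
]


@dataclass(frozen=True)
class RankConfig:
    """Propagation parameters.

    d : network weight in [0, 1); d=0.5 gives evidence and topology equal say.
    epsilon : one-norm convergence threshold on successive iterates.
    max_iter : iteration cap; non-convergence under it signals a fault.
    log_base : base of the -log(p) initial-score transform.
    p_min : floor applied to p-values before taking logs.
    """

    d: float = 0.5
    epsilon: float = 1e-5
    max_iter: int = 1000
    log_base: float = 10.0
    p_min: float = 1e-300

    def __post_init__(self) -> None:
        if not (0.0 <= self.d < 1.0):
            raise ValueError(f"d must be in [0, 1), got {self.d}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")
        if not (0.0 < self.p_min <= 1.0):
            raise ValueError("p_min must be in (0, 1]")


@dataclass
class RankResult:
    """Converged propagation scores plus iteration diagnostics."""

    scores: Dict[str, float]
    n_iterations: int
    final_residual: float
    converged: bool


def initial_scores(table: GeneScoreTable, config: RankConfig = RankConfig()) -> GeneScoreTable:
    """Attach initial scores ``f = -log_base(p)`` to a score table.

    p-values are floored at ``config.p_min`` first, so f is always finite
    and non-negative.
    """
    log_base = math.log(config.log_base)
    f = tuple(-math.log(max(p, config.p_min)) / log_base for p in table.p_values)
    return GeneScoreTable(table.gene_ids, table.p_values, f)


def propagation_matrix(net: DirectedDependencyNetwork, transpose: bool = False) -> sp.csr_matrix:
    """Out-degree-normalized adjacency ``P`` with ``P[i, j] = w_ij / deg_i``.

    Rows of dangling nodes are identically zero. With ``transpose=True``
    the edge orientation is reversed before normalization (for networks
    whose files encode dependency in the opposite direction).
    """
    index = {n: k for k, n in enumerate(net.nodes)}
    edges = net.edges
    if transpose:
        edges = frozenset((b, a) for a, b in edges)
    deg = np.zeros(net.n_nodes)
    for a, _ in edges:
        deg[index[a]] += 1
    rows, cols, vals = [], [], []
    for a, b in edges:
        i = index[a]
        rows.append(i)
        cols.append(index[b])
        vals.append(1.0 / deg[i])
    return sp.csr_matrix((vals, (rows, cols)), shape=(net.n_nodes, net.n_nodes))


def _aligned_f(net: DirectedDependencyNetwork, f: Mapping[str, float]) -> np.ndarray:
    missing = [n for n in net.nodes if n not in f]
    if missing:
        raise ValueError(
            f"initial scores missing for {len(missing)} network node(s), e.g. {missing[:3]}"
        )
    return np.array([float(f[n]) for n in net.nodes])


def generank_iterate(
    net: DirectedDependencyNetwork,
    f: Mapping[str, float],
    config: RankConfig = RankConfig(),
    transpose: bool = False,
) -> RankResult:
    """Fixed-point iteration of the propagation update, started at r = f.

    Stops when the one-norm of the update difference drops below
    ``config.epsilon`` or after ``config.max_iter`` sweeps. For d < 1 the
    iteration contracts geometrically, so failure to converge within the
    cap indicates an implementation fault and is flagged (``converged``
    False) with a warning rather than raised.
    """
    fv = _aligned_f(net, f)
    d = config.d
    if net.n_nodes == 0:
        return RankResult({}, 0, 0.0, True)
    P_T = propagation_matrix(net, transpose=transpose).T.tocsr()
    r = fv.copy()
    base = (1.0 - d) * fv
    residual = float("inf")
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        r_next = base + d * (P_T @ r)
        residual = float(np.abs(r_next - r).sum())
        r = r_next
        if residual < config.epsilon:
            break
    converged = residual < config.epsilon
    if not converged:
        warnings.warn(
            f"propagation did not converge in {config.max_iter} iterations "
            f"(residual {residual:.3g}); this should not happen for d < 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return RankResult(dict(zip(net.nodes, r.tolist())), n_iter, residual, converged)


def generank_closed_form(
    net: DirectedDependencyNetwork,
    f: Mapping[str, float],
    d: float,
    transpose: bool = False,
) -> Dict[str, float]:
    """Exact fixed point by direct sparse solve of ``(I - d P^T) r = (1-d) f``.

    Serves as the oracle for the iterative engine; unique for d < 1 since
    the spectral radius of ``d P^T`` is below 1.
    """
    if not (0.0 <= d < 1.0):
        raise ValueError(f"d must be in [0, 1), got {d}")
    if net.n_nodes == 0:
        return {}
    fv = _aligned_f(net, f)
    P_T = propagation_matrix(net, transpose=transpose).T.tocsc()
    A = sp.identity(net.n_nodes, format="csc") - d * P_T
    r = spla.spsolve(A, (1.0 - d) * fv)
    r = np.atleast_1d(r)
    return dict(zip(net.nodes, r.tolist()))


def rank_genes(result: RankResult | Mapping[str, float]) -> RankedGeneList:
    """Sort genes by propagation score, descending; ties broken by gene id.

    Lexicographic tie-breaking makes output files reproducible run-to-run.
    """
    scores = result.scores if isinstance(result, RankResult) else result
    for g, s in scores.items():
        if not math.isfinite(s):
            raise ValueError(f"non-finite score for {g}")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedGeneList(tuple((k + 1, g, s) for k, (g, s) in enumerate(ordered)))


def top_k(ranked: RankedGeneList, k: int) -> Set[str]:
    """The gene ids at ranks 1..min(k, K)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return {g for _, g, _ in ranked.entries[:k]}
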