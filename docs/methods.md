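# Methods

## Score propagation

The core operator re-scores gene *j* as
`r_j = (1−d)·f_j + d·Σ_i w_ij·r_i/deg_i`, with `f_j = −log_base(p_j)`
(base 10 by default; the base only rescales `f` and, by linearity of
the fixed point, leaves the ranking unchanged). The reading of the
directed adjacency is the PageRank-consistent one: `deg_i` is the
out-degree of gene *i* (row sum of `W`), so every gene splits its
current score equally among its out-neighbours, and the source of an
edge is the gene being depended upon. Verbal definitions of dependency
direction vary between data sources, so the engine accepts a
`transpose` option that reverses the stored orientation before
propagating; which orientation is right is a property of the network
file, not of the algorithm.

Choices a user may care about:

- **Dangling nodes** (out-degree 0) contribute nothing — there is no
  teleportation or re-normalization term. This keeps the update exactly
  as written; it also means `‖r‖₁ ≤ ‖f‖₁` holds only when every node
  has an out-neighbour.
- **Initialization** is `r⁰ = f`. The fixed point is unique for
  `d < 1` (the damped propagation matrix has column sums ≤ d, hence
  spectral radius < 1), so initialization affects only the iteration
  count. Convergence is declared when the one-norm of the update
  difference drops below `epsilon` (default 1e-5); the default
  `max_iter = 1000` is far beyond what the geometric contraction needs
  and failure to converge under it is flagged as a fault rather than
  silently accepted.
- **Exact solve.** `fit(method="direct")` solves
  `(I − d·Pᵀ)r = (1−d)f` sparsely; the iterative and direct paths agree
  to well below 1e-6 per component and the direct path doubles as the
  engine's oracle in the test suite (checked there against a dense
  `numpy.linalg.solve` written independently of the engine).
- **p-value floor.** `p = 0` is clamped to `p_min` (default 1e-300)
  so `f` stays finite; negative or >1 p-values are rejected as data
  errors rather than clamped.
- **Universe.** By default the model ranks the intersection of scored
  genes and network nodes; `universe="network"` keeps unscored nodes
  with `f = 0`. Ranking ties are broken lexicographically by gene id so
  output files are reproducible.
- **d.** Default 0.5 — evidence and topology weighted equally. `d = 0`
  reproduces the raw −log p ordering exactly, which the pipeline always
  evaluates as a comparison arm.

## Validation statistics

- **Chi-squared enrichment** of a gene set against a reference uses the
  uncorrected Pearson statistic `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` on
  the 2×2 strategy-by-membership table, df = 1, two-sided p. No Yates
  continuity correction is applied: the uncorrected test is the one
  whose p-values match the published breast-cancer worked examples this
  package reproduces in its tests, and the corrected test does not.
  Zero marginals make the test undefined and raise.
- **KS top-of-list enrichment** compares the rank positions of target
  genes against non-targets with a one-sided two-sample statistic
  `D = sup_t [F_targets(t) − F_background(t)]` and the asymptotic
  one-sided p `exp(−2D²nm/(n+m))`. One-sided on ranks was chosen
  because the scientific question is directional (targets *better*
  ranked); a two-sided variant is available by flag. D depends only on
  ranks, hence is invariant under any strictly monotone transform of
  the scores.
- **Over-representation** is the upper-tail hypergeometric test per
  gene set, Benjamini–Hochberg adjusted across the collection
  (step-up, via statsmodels). The default universe is the ranked list
  itself — the analysis universe — not the genome; this is the
  conservative choice when the scored genes are already a selected
  subpopulation, and it is configurable.
- **Percentages** are reported to 2 decimals, matching the convention
  of the published tables the reporting operations reproduce.

## Dependency-network inference

The network construction from expression + binary prognosis is this
package's own concretization of phenotype-anchored dependency
inference via conditional mutual information; the literature it
follows does not fix the statistic, thresholds or direction convention,
so equivalence with any particular published network is not claimed.
The rule: edge *i* → *j* (gene *j* depends on gene *i*) is added when

1. `MI(X_j; phenotype)` is significant at level `alpha` under `n_perm`
   phenotype-label permutations (expression correlation structure is
   preserved under this null), and
2. the relative information drop
   `[MI(X_j; y) − CMI(X_j; y | X_i)] / MI(X_j; y)` is at least `tau`
   (default 0.5): conditioning on gene *i* removes at least half of
   gene *j*'s phenotype information.

Estimators are plug-in (maximum-likelihood) on equal-frequency
discretized expression (default 3 bins, ties to the lower bin) — the
simplest estimator whose values an exhaustive contingency-table oracle
can verify. Known limitations: plug-in MI is positively biased at
small n (mitigated, not removed, by the permutation calibration); the
O(N²) pair tests carry no FDR control; ≥ 8 samples per class are
required or the construction refuses to run. Defaults
(`n_bins=3, alpha=0.05, tau=0.5, n_perm=1000`) were fixed once as
conventional choices for ~100-sample cohorts.

## Synthetic data

The generators emulate the pipeline's real inputs with planted ground
truth; all are pure functions of (config, seed) via per-stage
`SeedSequence` spawns, so every table is bit-reproducible.

- **Gene scores.** Disease genes draw `p ~ Beta(a, 1)` (default
  `a = 0.2`), null genes `p ~ U(0,1)` — the standard one-parameter
  enrichment model, with `a` the signal-strength dial
  (`a = 1` is exactly uniform). Default universe: 2000 genes, 5%
  disease.
- **Network.** Directed preferential attachment: nodes arrive in
  random order; each non-root draws `m_edges` (default 5, a realistic
  sparse mean out-degree for gene networks) distinct earlier nodes
  with weight ∝ (in-degree + 1), multiplied by `homophily` (default 8)
  when both endpoints are disease genes. This is the minimal generator
  giving both heavy-tailed degrees and a planted disease module — the
  structure propagation can exploit. The stored pairs run
  *dependent → anchor* (the new gene depends on the established genes
  it attaches to), the reverse of the engine's source-is-depended-upon
  convention, so ranking a simulated network propagates with
  `transpose=True`; the pipeline applies this automatically for
  simulation-driven runs. In the untransposed orientation the
  attachment hubs accumulate propagated score and drown the module
  signal in degree noise.
- **Reference database.** Bernoulli read-out of the planted set
  (sensitivity 0.8, false-positive rate 0.1 — a deliberately imperfect
  curated database).
- **Drug targets.** `n_agents` agents (default 300) each draw
  `targets_per_agent` (3) distinct targets; a `support_fraction`
  (0.15, near published clinical-support rates for repositioning
  candidates) of agents is flagged supported and draws targets with
  weight `support_enrichment` (8) on disease genes. The fraction
  parameter is required because the enrichment is defined relative to
  the supported subgroup.
- **Expression.** Balanced binary phenotype; a random chain of
  disease genes (default length 3) starts with a mean shift of
  `effect` in one class and continues by regression on the upstream
  gene (coefficient 0.8) plus unit noise; all other genes are standard
  normal.

What passing synthetic tests do **not** show: the generator has no
linkage-disequilibrium structure, no per-SNP layer, no realistic
pathway topology, and its disease module is a single homophilous
block; real PheWAS scores and dependency networks are messier, so
recovery margins measured here do not transfer quantitatively to real
cohorts.

## Benchmark problem sizes

The replicated recovery study runs 20 seeds per condition at 2000
genes — large enough for stable AUROC estimates while keeping the full
suite and the acceptance script in the seconds-to-minutes range.
Under these conditions the propagated ranking's mean planted-gene
AUROC exceeds the raw −log p ordering's when the network is
homophilous, and differs from it by less than 0.02 when homophily is
off (an uninformative network adds no information, only a small amount
of propagation noise); the margins themselves are computed fresh by
`scripts/acceptance.py` and the acceptance tests, not quoted here.

## Pipeline

`run_pipeline` executes simulate/load → rank (both arms) → validate →
predict, writes every intermediate table, and emits a JSON report with
SHA-256 fingerprints of the inputs plus a Markdown summary. Reports
contain no timing or environment fields, so identical config + seed
gives byte-identical reports, and re-running from the emitted
intermediate files reproduces every statistic exactly (tested).
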