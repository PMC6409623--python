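# phewasrank

Gene–disease associations recovered by phenome-wide association studies
(PheWAS) are individually weak: a genome-wide scan of electronic-record
phenotypes yields hundreds of candidate genes whose p-values rarely
survive scrutiny on their own. `phewasrank` strengthens those
candidates by propagating the association evidence over a **directed
gene-dependency network** — a network whose edge *i* → *j* records that
gene *j*'s phenotype-relevant behaviour depends on gene *i* — and then
uses the re-ranked gene list for disease-gene validation and drug
repositioning. It is aimed at computational biologists who have
gene-level association scores and a dependency (or other directed
regulatory) network and want a tested, reproducible prioritization
pipeline with built-in validation statistics and a fully synthetic
benchmark mode.

## The model

Each gene starts with evidence score $f_j = -\log_{10} p_j$ from its
association p-value. The propagated score is the fixed point of the
damped update

$$r_j^{(n)} = (1-d)\,f_j + d \sum_{i=1}^{N} \frac{w_{ij}\,r_i^{(n-1)}}{\deg_i},$$

where $w_{ij} \in \{0,1\}$ is the directed adjacency, $\deg_i$ is the
out-degree of gene $i$ (each gene splits its score equally among its
dependents; dangling genes contribute nothing), and $d \in [0,1)$
weights network topology against raw evidence — $d = 0.5$ gives both
equal say, $d = 0$ returns the raw $-\log p$ ordering. Iteration starts
at $r^{(0)} = f$ and stops when the one-norm of the update difference
falls below $\varepsilon$ (default $10^{-5}$); for $d<1$ the update is
a contraction, so the fixed point is unique and equals the solution of
$(I - dP^{\mathsf T})\,r = (1-d)f$ with $P$ the out-degree-normalized
adjacency (also available exactly via `fit(method="direct")`).

The ranked list is validated by (i) overlap and uncorrected Pearson
chi-squared enrichment of the top-k genes against a disease-gene
reference, (ii) a one-sided two-sample Kolmogorov–Smirnov test asking
whether known drug targets crowd the top of the list, and (iii)
hypergeometric over-representation of gene-set collections with
Benjamini–Hochberg FDR control. A drug-prediction step maps the top-k
genes to chemical agents (an agent is predicted when at least one of
its targets is in the set) and scores the fraction with clinical
support. An optional module infers the dependency network itself from
expression + binary prognosis data via conditional mutual information,
and a seeded synthetic-data module generates every input with planted
ground truth.

## Worked example

```python
from phewasrank import (PheWASRank, RankConfig, SimulationConfig,
                        simulate_gene_scores, simulate_network)

cfg = SimulationConfig(n_genes=2000, pi_disease=0.05, seed=1)
scores, truth = simulate_gene_scores(cfg)     # p-values, planted disease genes
network = simulate_network(truth, cfg)        # homophilous directed network

model = PheWASRank(scores, network, RankConfig(d=0.5), transpose=True)
results = model.fit()
print(results.summary(5))
```

```
PheWAS-Rank propagation results
==================================
genes ranked:     2000
network edges:    9975
d (network wt):   0.5
epsilon:          1e-05
iterations:       9
final residual:   3.89e-06
converged:        True

top 5 genes:
rank  gene_id          score
   1  G0873            6.166067
   2  G1661            4.809589
   3  G0067            4.083050
   4  G1090            3.915579
   5  G1449            3.822781
```

The same study as a one-shot pipeline (both the propagated and the raw
$-\log p$ arm, plus validation and drug prediction) runs from a YAML
config:

```bash
phewas-rank run --config config.yaml
```

and prints, for the config above (seed 1), a report including

```
| topk_overlap_rank_pct | 45.0 |   # top-100 genes in the disease reference
| topk_overlap_raw_pct  | 41.0 |   # same for the raw ordering
| ks_D                  | 0.13226666666666667 |
| ks_p                  | 0.016568256610852424 |
| agents_rank           | 54 |     # agents predicted from the top-100
| agents_rank_support_pct | 35.19 |
```

i.e. the propagated top-100 captures more reference disease genes than
the raw ordering, known drug targets are significantly shifted toward
the top of the propagated list (one-sided KS p ≈ 0.017), and about a
third of the predicted agents carry clinical support. Subcommands
`simulate`, `build-network`, `rank`, `validate` and `predict-drugs`
expose the individual stages.

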