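# connrep

**Test–retest reproducibility of functional connectome graph measures
across network-construction strategies.**

Resting-state fMRI connectomics offers a bewildering number of analysis
choices: how to denoise the BOLD signal, whether to use Pearson or partial
correlations, how to handle negative correlations, whether to threshold
into a binary graph or keep weights, and how fine a parcellation to use.
Each choice changes the graph measures computed downstream — so which
pipelines give measures a subject would reproduce if scanned again next
week?  `connrep` implements, end to end and fully tested, a
subject-level reproducibility analysis that answers this question: from
two-session parcel time series through quality control, denoising,
network construction, graph metrics with random-network normalization, to
reproducibility statistics and a nonparametric factorial comparison of
strategies.  A synthetic-cohort generator with known ground truth makes
every stage verifiable without any imaging data.

## The statistics at the core

For a graph measure *m* computed in sessions 1 and 2:

- **Test–retest variability** `TRT = 100·|m₂ − m₁| / ((m₁ + m₂)/2)` (%);
  0 means perfectly reproducible.
- **Hub co-occurrence** `Hc = 2|H₁ ∩ H₂| / (|H₁| + |H₂|)` — Dice overlap
  of the two sessions' hub sets (hub: a node in the top 20% by at least
  two of degree, low path length, low clustering, high betweenness).
- **Probabilistic scaled inclusivity**
  `pSI_i = (Σ_j P₁(i,j)·P₂(i,j))² / (Σ_j P₁(i,j) · Σ_j P₂(i,j))` — per-node
  agreement of two module co-assignment matrices, each estimated from 100
  runs of Newman's leading-eigenvector modularity algorithm.

Global measures (characteristic path length λ, clustering C, efficiency
E, betweenness BC) are normalized by the mean over 30 equivalent random
networks (same density for binary graphs; permuted weight multiset for
weighted graphs).  Strategy grids are compared with aligned-rank-transform
(ART) repeated-measures factorial ANOVA, Wilcoxon signed rank tests, and
Bonferroni correction over the four measures.

## Worked example

```python
import connrep as cr

spec = cr.CohortSpec(n_subjects=10, n_parcels=100, seed=7)
records, truth = cr.generate_cohort(spec)

grid = cr.StrategyGrid("2", denoising=("simple",),
                       correlation=("pearson",), sign_modes=("abs",),
                       network="weighted")
res = cr.run_analysis(records, grid, tr_seconds=3.0, seed=0)
trt = res["reproducibility"]
print(trt.groupby("measure")["value"].mean().round(2))
```

```
measure
betweenness_n    1.65
clustering_n     0.34
efficiency_n     1.23
lambda_n         1.85
Name: value, dtype: float64
```

These are mean TRT percentages over 10 synthetic subjects for the four
normalized global measures of weighted |r| networks under simple
denoising: each subject's normalized path length differs by about 1.9%
between sessions, clustering by well under 1% — weighted networks
reproduce global topology closely under these conditions, with
betweenness the least stable measure.

A command-line interface covers the same stages for on-disk cohorts:

```sh
connrep simulate --out cohort/
connrep qc --in cohort/ --tr 3.0 --out qc/
connrep analyze --analysis 1a --seed 0 --out results/
```

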