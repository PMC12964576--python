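# immunopanel

Prognostic gene-panel discovery for bulk tumor cohorts with matched
tumor/adjacent-normal expression, immune-cell deconvolution fractions,
and overall-survival follow-up. The package implements, as reusable and
tested components, a poor-survival discovery procedure of the kind used
in kidney renal clear cell carcinoma (KIRC) immunogenomics: patients are
stratified twice — by their 22-dimensional immune-cell infiltration
profile and by their immune-regulatory gene expression — the
poor-prognosis strata of the two views are intersected into a discovery
cohort, candidate genes are prioritized by an *immune gene index*, and a
multi-gene prognostic panel is assembled by differential expression,
immune-cell-type filtering, stepwise logistic selection, large-scale
random-combination benchmarking, frequency profiling, exhaustive subset
search, and leave-one-gene-out attribution.

Because the real cohorts behind such studies are access-controlled, the
package ships a synthetic-cohort generator with planted ground truth
(latent immune clusters, tumor/normal fold changes, survival-informative
genes, censoring), so that every stage can be validated by recovery of
known structure.

## The statistics at the core

* **Patient stratification.** Samples are clustered with Gaussian
  mixture models (components selected by BIC, or fixed, e.g. k = 5);
  survival differences across clusters are tested with the k-sample
  log-rank test on Kaplan-Meier curves.
* **Cumulative-SD cutoff.** To dichotomize a long-tailed infiltration
  variable, samples are sorted descending and the standard deviation of
  the first 3, 4, …, n samples is accumulated; the cutoff is placed at
  the largest single-step rise of this curve — the point where the
  accumulating prefix first absorbs the distant bulk — separating a
  high-infiltration tail from the rest. The full prefix-SD trace is
  returned for audit.
* **Immune gene index.** For cohort tumors, each gene g receives
  `index(g) = mean tumor expression(g) × FC(g)` with
  `FC = (mean tumor + ε) / (mean normal + ε)` on the linear FPKM scale;
  genes are ranked by descending index and the shortlist is cut at the
  last pronounced drop (consecutive-index ratio ≥ 1.3 by default).
* **Panel construction.** With vital status (alive/dead) as the binary
  response, logistic models are fit by maximum likelihood (batched
  Newton solver; ridge fallback on separation). Candidate refinement
  uses bidirectional AIC stepwise selection; random k-gene combinations
  from the candidate pool are benchmarked by in-sample AUC against
  positive-control (literature-prognostic analogue) and negative-control
  (no-signal) pools; genes are ranked by frequency among high-AUC
  combinations; all subsets of the top genes (≤ 20, i.e. ≤ 2²⁰ − 1
  models) are searched exhaustively; and the winning panel is attributed
  by leave-one-gene-out AUC deltas. AUC variance and model comparison
  use the DeLong estimator.

## Worked example

The gene index is a plain product, so reference values reproduce
exactly:

```python
>>> import pandas as pd
>>> from immunopanel.gene_index import rank_by_index
>>> table = pd.DataFrame({
...     "gene": ["LBP", "COL1A1", "FGA", "C3"],
...     "mean_tumor_expr": [102.86, 281.4, 119.28, 284.99],
...     "fold_change": [82.72, 16.56, 38.54, 12.39]})
>>> print(rank_by_index(table).to_string(index=False))
  gene  mean_tumor_expr  fold_change     index  rank
   LBP           102.86        82.72 8508.5792     1
COL1A1           281.40        16.56 4659.9840     2
   FGA           119.28        38.54 4597.0512     3
    C3           284.99        12.39 3531.0261     4
```

End-to-end on a synthetic cohort (300 patients, 2 000 genes, 10 000
random combinations per pool):

```bash
immunopanel run-all --synthetic demo/inputs \
    --n-patients 300 --n-genes 2000 --n-draws 10000 \
    --seed 23 --outdir demo/run
```

prints the per-stage timings and writes ten artifacts plus a manifest.
On this cohort the run reports (from `demo/run/`):

```
poor cohort size: 68
candidate          mean AUC 0.681
positive_control   mean AUC 0.585
negative_control   mean AUC 0.570
panel genes: G00000 G00007 G00008 G00014 G00016 G00035 G00037 G00050 G00055 G00189
in-sample AUC: 0.7664
```

The candidate pool (refined by stepwise selection from the upregulated,
immune-annotated genes of the poor cohort) clearly outperforms both
control pools, and the final panel is dominated by the generator's
planted survival-signal genes (`G00000`, `G00007`, `G00008`, `G00014`,
`G00016`). The leave-one-out table in `panel.json` ranks each panel
gene's AUC contribution; all reported AUCs are in-sample and labeled as
such. Every stage can also be run individually (`immunopanel --help`
lists `simulate`, `cluster-immune`, `screen-celltypes`, `cluster-genes`,
`cohort`, `index`, `de`, `stepwise`, `benchmark`, `frequency`,
`search-panel`, `loo`, `run-all`).

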