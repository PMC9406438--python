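# omicsurv

Multi-omics integration and survival-signature discovery for tumor
cohorts.

`omicsurv` is for biostatisticians and computational oncologists who have
three linked omics layers for one patient cohort — per-sample copy-number
segments, a gene-level methylation beta matrix, and a gene-level
expression matrix — plus survival follow-up, and who want to (i) discover
prognostic patient subgroups and (ii) distill a small multi-omics gene
signature that predicts them. Because a realistic cohort cannot ship in a
test suite, the package includes a first-class synthetic-cohort generator
with a planted two-cluster structure and truth manifest, so every stage is
verifiable end to end.

## The method

Starting from layers X⁽ᶜⁿᵃ⁾, X⁽ᵐᵉᵗʰ⁾, X⁽ᵉˣᵖʳ⁾ over a shared sample set:

1. **Reduction.** Segments are mapped to genes by overlap-length-weighted
   mean log2 ratio. Per-layer frequency filters keep CNA genes altered
   (|log2| ≥ 0.2) in ≥ 30% of samples, methylation genes with β ≥ 0.3 in
   ≥ 40% of samples, and expression genes with ≤ 50% null values. The
   survivors are concatenated into an integration table keyed by
   (gene, layer), z-standardized, and filtered to correlated *constructs*:
   keep feature j iff ∃ k ≠ j with |r(xⱼ, xₖ)| > 0.8.
2. **Clustering.** PCA on the integration table; k-means (k-means++, k = 2)
   on the first ten PC scores; quality via the average silhouette
   s̄ = mean (b − a)/max(a, b) in score space.
3. **Survival.** Kaplan–Meier per cluster with median/restricted-mean CIs;
   weighted log-rank tests with w(t) = 1, nₜ, √nₜ (log-rank, Breslow,
   Tarone–Ware); Cox PH (Efron ties) for hazard ratios HR = exp(β).
4. **Selection.** (a) keep features in the per-PC 90th |loading|
   percentile of exactly one PC; (b) keep the top features by cumulative
   random-forest Gini importance over bootstrap replicates; (c) rank by
   L1-logistic inclusion frequency over bootstrap refits (penalty by
   group-aware CV, one-SE rule) and keep the top nine.
5. **Evaluation.** Monte-Carlo SVM/RF classification (stratified splits,
   six-number summaries of accuracy/sensitivity/specificity), per-feature
   Mann–Whitney AUC with Youden-optimal cut-offs J = max(se + sp − 1), a
   binarized logistic model with OR_adj = exp(B), Nagelkerke R² and
   Hosmer–Lemeshow fit, Cox HRs for the retained predictors, and Fisher's
   exact test of cluster vs metastasis status.

Model assumptions, defaults and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```sh
omicsurv run -o runs/demo --seed 3
```

or equivalently in Python:

```python
from omicsurv import PipelineConfig, SimConfig, run_pipeline, report_tables

cfg = PipelineConfig(simulate=SimConfig(seed=3),
                     gini_n_boot=100, lasso_n_runs=100, mc_n_iter=100, seed=3)
run_pipeline(cfg, "runs/demo")
report_tables("runs/demo")
```

The run directory receives the generated cohort, per-stage artifacts and
`summary.json`. For this seed the summary reports:

```
clustering.silhouette_avg      0.172
clustering.ari_vs_truth        0.961
survival.median_gap_days       1454.7
survival.tests.logrank.p       0.000123
selection.planted_in_signature 9        (of 9 signature entries)
evaluation.signature_rf accuracy mean   0.990
logistic.accuracy              0.993    (null accuracy 0.578)
metastasis.fisher_p            0.418
```

Read: the clusterer recovers the planted patient partition almost exactly
(adjusted Rand index 0.96; the silhouette is modest because the noise
constructs add variance to the score space), the clusters differ in median
survival by about 4 years, all nine selected signature features are
planted ones, the signature separates the clusters almost perfectly in
held-out Monte-Carlo splits, and — as designed into the generator — the
clusters are unrelated to metastasis status. `omicsurv report runs/demo`
renders the survival, classification, AUC/cut-off and logistic-coefficient
tables as TSV.

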