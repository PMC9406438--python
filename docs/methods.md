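# Methods

`omicsurv` implements a multi-omics survival-signature discovery pipeline
for tumor cohorts: three omics layers are reduced to an integration table,
patients are clustered on principal-component scores, the clusters are
tested for a survival difference, a small multi-omics gene signature is
distilled through a three-stage selection cascade, and the signature is
evaluated as a predictor of cluster membership and survival. This note
records the model, the defaults, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Pipeline model

**Reduction.** Copy-number segments (1-based, fully-closed intervals, SEG
convention) are mapped to genes by overlap-length-weighted averaging of
segment log2 ratios over each gene interval; genes with no overlapping
segment are missing for that sample and imputed as 0 (copy-neutral) when
the integration table is built. Per-layer frequency filters then require a
CNA gene to be altered (|log2| ≥ 0.2) in ≥ 30% of samples, a methylation
gene to have beta ≥ 0.3 in ≥ 40% of samples, and an expression gene to
have ≤ 50% null values (missing or exactly zero — the natural reading of
"null" for RNA-seq). The surviving features are concatenated keyed by
(gene, layer), z-standardized so principal components are not dominated by
expression scale, and passed through a construct filter: a feature is kept
only if some *other* feature correlates with it at |Pearson r| > 0.8.
Absolute correlation is used because an anti-correlated partner is equally
strong evidence of a construct. Correlations are computed blockwise as
Z'Z/n on the z-scored matrix, so memory stays bounded for tens of
thousands of features; the operation is symmetric, hence idempotent.
Missing values are imputed before this step (CNA → 0, expression → gene
median), which on complete synthetic data is identical to pairwise-complete
correlation and keeps the blockwise matmul exact.

**Clustering.** PCA (centered; input already standardized) with the first
ten components, deterministic up to sign; signs are fixed by making each
loading column's largest-magnitude element positive. k-means with
k-means++ initialization, 25 restarts, best inertia kept; k = 2 by default
(a silhouette scan over k ∈ 2..6 is available as a diagnostic). Cluster 1
is always the larger cluster. The silhouette is computed with Euclidean
distance in the ten-dimensional score space — the space the clustering
actually used.

**Survival.** Kaplan–Meier curves per cluster with Greenwood confidence
bands; the median is the first time the curve reaches 0.5 (undefined
otherwise), its CI by Brookmeyer–Crowley band inversion; the mean is the
restricted mean up to the largest observed time with a Greenwood-style SE.
Group differences are tested with the weighted log-rank family: weights 1
(log-rank), number at risk (Breslow / generalized Wilcoxon) and the square
root of the number at risk (Tarone–Ware). Cox models maximize the partial
likelihood with the Efron tie correction and report coefficient, SE,
HR = exp(coef), Wald p and a global likelihood-ratio p. A hazard ratio
below one is also reported as its reciprocal fold-change, since tiny HRs
are most readable that way. These routines are thin surfaces over
lifelines; tests cross-check them against hand-built risk-set oracles and
the classical identity between the Cox score test and the log-rank
statistic.

**Selection.** Three stages, strictly filtering:

1. *Loadings*: for each of the first ten PCs, mark features whose
   |loading| reaches that PC's 90th percentile; keep features marked in
   exactly one PC. Absolute loadings are used — signed loadings would
   discard strong negative weights for no reason — which also makes the
   stage invariant to component sign flips.
2. *Gini importance*: over bootstrap replicates of the samples, fit a
   random forest (25 trees per replicate) on the cluster labels and
   accumulate each feature's mean-decrease-in-Gini importance. Two
   survivor rules are provided: an absolute cumulative-importance
   threshold (default 10,000 — note this scale is bound to
   n_boot × trees × data scale) and the recommended scale-free quantile
   rule keeping the top 15% of features, which mirrors the proportion the
   absolute rule produces at full scale.
3. *Stability selection*: per run, bootstrap-resample the samples and fit
   an L1-penalized logistic model; rank features by the fraction of runs
   in which they receive a nonzero coefficient and return the top
   `n_select` (default nine). Two design details matter here. CV folds
   used to pick the penalty are split by original sample identity, never
   by bootstrap row: duplicated samples leaking across folds otherwise
   let overfit penalties win even on pure noise. And the penalty follows
   the one-standard-error rule (strongest penalty within one SE of the
   best CV accuracy), the sparse choice standard in stability selection;
   with the plain CV optimum, noise features reach high inclusion
   frequencies and the null behavior of the stage is meaningless. Ties at
   the cut rank break by higher mean |coefficient| across runs, then
   lexicographically, so results are deterministic.

The selection RF is trained on cluster labels (the same dependent variable
the classification stage uses), not on survival directly.

**Evaluation.** Monte-Carlo assessment draws stratified train/test splits
(default test fraction 0.127 ≈ 52/410, matching the granularity of the
reported metric quantiles), fits an RBF-kernel SVM (features standardized
in-pipeline) or a 500-tree random forest, and summarizes accuracy,
sensitivity and specificity over iterations as min/Q1/median/mean/Q3/max.
Cluster 2 — the shorter-surviving subgroup — is the positive class.
Per-feature ROC analysis uses the Mann–Whitney AUC (orientation
auto-chosen so AUC ≥ 0.5, the direction reported), a Hanley–McNeil CI
(DeLong optional), and the Youden-optimal cut-off J = max(sens + spec − 1).
The signature logistic model binarizes each feature at its Youden cut-off
("above cut-off" indicators), removes the least-significant predictor
while any Wald p > 0.05, and reports B, SE, OR_adj = exp(B), Wald CIs,
overall and null (majority-class) accuracy at probability 0.5, Nagelkerke
R² = (1 − exp((2/n)(LL₀ − LL₁))) / (1 − exp((2/n)LL₀)) and the
Hosmer–Lemeshow p on ten risk deciles with g − 2 df. Complete separation —
expected when a CNA indicator splits the clusters perfectly — triggers a
ridge-penalized IRLS fallback (λ = 0.01, intercept unpenalized) whose SEs
come from the penalized Hessian and are flagged approximate. Fisher's
exact test (two-sided, point-probability rule) checks the
cluster–metastasis association, and a descriptive cross-omics table
reports each signature gene's mean CNA log2, mean beta and median
expression split by cluster.

## Synthetic cohort generator

The generator emulates the study conditions every stage is tested under:
410 samples, a 240/410 split into a longer- and a shorter-surviving
subgroup, per-cluster median survival 2900 vs 2064 days, 40% censoring,
and three linked layers over a shared 200-gene universe with five planted
genes per layer (disjoint across layers). Cluster 2 carries a coherent
multi-omic deficit: copy-number loss of 0.15 log2 units per unit effect
size, and a downward shift of `effect_size` latent standard deviations on
the logit (methylation) and log (expression) scales — loss, hypo-
methylation and under-expression in the poor-prognosis subgroup. Planted
genes within a layer share a latent construct factor (correlation 0.9) so
they form the correlated constructs the |r| > 0.8 filter is designed to
keep; 30% of the non-planted methylation/expression genes sit in
correlated noise blocks, a few copy-number regions are commonly altered
independently of cluster, and a fifth of the isolated expression genes
carry gene-level dropout, so each filter faces realistic distractors
rather than pure iid noise. Copy number is emitted as per-sample segments
(one per region), so gene-level values exist only after mapping. Survival
is exponential within cluster (scale = median/ln 2; the closed-form median
makes calibration checks analytic) with independent uniform administrative
censoring whose horizon is solved numerically so the expected censored
fraction matches the configured rate. The metastasis flag is Bernoulli
(rate 0.25) independent of cluster. One integer seed drives every stream
via named SeedSequence spawns; identical configs give byte-identical
files.

What the generator does *not* emulate: genome-wide breakpoint processes,
probe-level methylation structure, library-size or GC effects in
expression, covariates such as HPV status or stage, and any dependence of
censoring on cluster. Passing tests therefore demonstrate that the
pipeline recovers planted structure under its own model assumptions, not
that it would recover the real cohort's feature counts or genes.

## Numerical choices and degenerate inputs

- Effect sizes for methylation/expression are defined on the latent
  (logit/log) scale; AUC-type properties are invariant to these monotone
  transforms.
- Constant features correlate with nothing: the construct filter drops
  them with a warning rather than erroring.
- `n_components` above the achievable rank is reduced with a warning.
- All-censored survival input returns a curve with the median flagged
  undefined.
- Degenerate stability-selection resamples (one class) are redrawn and
  counted.
- An absolute Gini threshold above the maximum cumulative importance
  yields an empty survivor set with a warning, not an error.
- Constant ROC input returns AUC 0.5 with an undefined cut-off, flagged.

## Problem sizes used for verification

The test suite and the reproduction script scale the resampling counts to
desk size as their own study design: 200 importance-bootstrap replicates
and 200 stability runs (defaults: 5000/1000), 300 Monte-Carlo iterations
(default 5000), and 25 generator seeds for the parameter-recovery suite at
n = 400 with effect size 2. At these sizes clustering recovers the planted
partition (ARI ≥ 0.9) and at least 7 of 9 selected features are planted in
well over 80% of seeds.

## Known limitations

- The absolute Gini threshold's units are tied to the resampling scale;
  use the quantile mode when comparing across configurations.
- The ridge fallback for separated logistic models reports shrunken
  coefficients and approximate SEs; it is a reporting device, not
  inference under separation.
- The silhouette is computed in PC-score space; values are not comparable
  to silhouettes computed on raw features.
- Backward elimination inherits the usual caveats of stepwise selection;
  it is kept because the evaluated signature model is deliberately small.
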