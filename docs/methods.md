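# Methods

`mirta` analyzes paired bulk expression cohorts — a gene matrix and a miRNA
matrix over the same patients, on the log2-normalized scale (voom/rma or
similar applied upstream) — to find miRNA–target interactions and
miRNA-derived biomarkers. This note records the models, the defaults and the
numerical choices, and what the synthetic test bench does and does not show.

## Association model

miRNAs act by repressing their target mRNAs, so a direct interaction is
expected to appear as a **negative** association between miRNA and gene
expression across samples. Four correlation statistics are offered:

| method   | captures                | p-value                       |
|----------|-------------------------|-------------------------------|
| pearson  | linear association      | t reference, two-sided        |
| spearman | monotone (rank)         | t approximation, two-sided    |
| kendall  | monotone (pair-based)   | exact/normal, two-sided       |
| distance | arbitrary dependence    | seeded permutation, add-one   |

Distance correlation (double-centered distance matrices; in [0, 1], zero iff
independence in the population limit) is the nonlinear option; its p-value
uses 200 permutations by default. Pairwise-complete observations are used; at
least 4 complete pairs are required and constant vectors are rejected.

Regularized regression (Lasso, Ridge, Elastic Net with mixing parameter 0.5)
regresses each gene (response, standardized) on its candidate miRNAs
(predictors, standardized), so coefficients are comparable across miRNAs and
a negative coefficient supports repression after accounting for the other
candidates. The penalty weight is chosen by seeded 5-fold cross-validation
unless given explicitly.

**Voting.** Per method, pairs are ranked by strength of negative association
(most negative correlation or coefficient = rank 1; average ranks on ties).
The vote score is the mean rank across methods (Borda); the final vote rank
orders by score with a lexicographic (miRNA, gene) tie-break, making output
deterministic. The signless distance correlation ranks descending (strongest
dependence first) — it cannot distinguish repression from activation, which
is why the default method set is Pearson + Spearman.

**Empirical null.** To rule out chance correlations, each miRNA's observed
correlation is calibrated against its correlations with 1000 randomly drawn
genes that have *zero* support from all 40 prediction tools (seeded sampling
without replacement; if fewer than 1000 zero-evidence genes exist all are
used with a warning, and below 100 the null is refused as unreliable). The
empirical p uses the add-one estimator p = (1 + #{null ≤ observed}) /
(n_null + 1) on the negative tail by default (mirrored positive and
two-sided tails available), so p ≥ 1/(n_null+1) and never 0. The null uses
the same correlation statistic as the observed value.

**Per-patient gene-set targeting score.** For a miRNA m and gene set S,
score(s) = Σ_{g∈S} (support(m,g)/40) · z_g(s), where z_g is the gene's
expression standardized across samples. Genes without tool support contribute
nothing; the weight table is returned alongside the score. This weighted
z-score is one concrete, documented instantiation of "support-weighted
per-patient targeting" and is deliberately simple and replaceable; the weight
function is the only modeling choice in it.

## Target evidence layer

Evidence from 40 target-prediction tools, 5 of them experimental-evidence
databases, is consumed as a boolean (miRNA, gene) × tool matrix; the package
validates the counts (exactly 40 / exactly 5) but treats tool identities as
schema metadata — all tools count equally, and experimental support is
exposed as a filter rather than a weight. Consensus filtering keeps pairs
with support ≥ min_tools (default 5 of 40). Over-representation of a miRNA's
targets in a gene set is a one-sided hypergeometric test on the chosen
universe (recommended: all genes in the expression matrix, which avoids
annotation-coverage bias); the odds ratio uses a Haldane +0.5 correction when
a 2×2 cell is zero. Synthetic-lethal lookup joins consensus targets against
an unordered SL pair list and a user-supplied essential-gene set; results are
sorted by support, then ids.

## Survival analysis

Features are miRNAs, genes, or miRNA/gene ratios. On log2 data the ratio is
the *difference* of the two values (a quotient on the original scale), which
needs no pseudo-counts and concentrates opposing prognostic effects of a
miRNA and its target into one feature.

Kaplan–Meier analysis dichotomizes at a percentile (median default) or at the
**optimal** cutpoint: every admissible cutpoint between the 10th and 90th
percentile is scanned (groups below 10% of samples rejected) and the minimum
log-rank p is taken. Minimum-p scanning is anti-conservative, so the optimal
mode also reports a permutation-adjusted p: the same scan is repeated on
label-permuted survival data (200 permutations by default, seeded, add-one
estimator). The scan uses a vectorized observed-minus-expected lifetable
statistic identical to the standard log-rank chi-square (tested against
lifelines and a hand lifetable oracle). Hazard ratios for the chosen split
and for continuous features come from (unpenalized) proportional-hazards
fits on the standardized feature (HR per 1 sd); non-convergence yields a
flagged result rather than an exception.

**Presence ranking.** Prognostic feature selection fits three models per
cross-validation fold — ridge-penalized Cox regression (alpha = 0.1),
gradient-boosted survival trees (100 trees, depth 2) and a linear survival
SVM — and records the top-n features per (fold, model) by absolute
coefficient or impurity importance. A feature's *presence* is the fraction of
(fold × model) combinations containing it, a granularity of 1/(k·#models);
`mean_importance` averages importances max-normalized within each
(fold, model) fit, since Cox coefficients, impurity gains and SVM weights are
not on a common scale. Folds are drawn from a seeded permutation, so results
are bit-for-bit reproducible; all-censored training splits are skipped with a
warning. Presence is pooled across models, with a per-model breakdown
retained.

The survival network takes consensus-filtered, negatively correlated pairs as
edges, annotates nodes with their univariate Cox hazard direction, and flags
an edge `opposing_effect` when the miRNA and the gene have significant
(p < 0.05) hazard ratios on opposite sides of 1 — the expected signature of a
prognostically relevant repressive interaction.

## Classification

Predictive selection between two clinical levels mirrors the prognostic
route with stratified folds and three selectors: AdaBoost on depth-1 trees
(100 estimators), random-forest impurity importance (200 trees) and
L1-penalized logistic regression (standardized within the training split).
Classification (random forest, logistic regression, or linear SVM) is
evaluated by stratified k-fold CV; any standardization lives inside the
per-fold pipeline so test folds never inform the scaler. Out-of-fold
probabilities are pooled into one ROC curve and a confusion matrix at the
0.5 threshold; per-fold AUCs give the mean ± sd. The PCA projection (2
components, centered internally) uses a deterministic sign convention: the
largest-magnitude loading of each component is made positive.

## Synthetic cohorts

The generator emulates, on the log2 scale, everything the analyses consume:

- miRNA expression ~ Normal(8, 1); non-target genes ~ Normal(baseline, 1)
  with baselines uniform on [4, 10].
- **Planted regulations** (default 3, effect −0.8, noise sd 0.5): the target
  gene equals baseline + effect·(miRNA − 8) + Normal(0, noise_sd), so the
  population Pearson correlation is effect/√(effect² + noise_sd²) ≈ −0.85.
- **Evidence**: planted pairs get support 7 of 40 (always including one
  experimental source); decoy pairs (10 per miRNA) draw support from
  {1..4}; all other pairs are absent.
- **Survival**: exponential event times with log-hazard Σ β_f·z_f (defaults:
  first planted miRNA β = 1.0, its target β = −0.7 — the opposing-effect
  pattern); independent uniform administrative censoring with the scale
  chosen by bisection to hit the target censoring fraction (default 0.3).
- **Labels**: balanced binary groups; one non-planted miRNA shifted by 3
  log2 units (3 sd) in group 1. The shift is put on a non-planted miRNA so
  it cannot dilute a planted correlation.
- **Score**: an immunophenoscore-like vector = −z(designated non-planted
  miRNA) + Normal(0, 0.5).
- **SL pairs**: each planted target is wired to an essential partner, plus
  random filler pairs.

Everything is driven by one mandatory seed; identical seeds give
byte-identical fixture files.

What the bench does **not** emulate: count-level noise and library-size
effects (data are generated directly on the log2 scale), correlated
co-expression modules, confounding between regulation and outcome, batch
effects, non-proportional hazards, and miRNAs regulating many genes at once.
Passing recovery tests therefore demonstrates correctness of the estimators
and selection machinery under the linear-Gaussian, proportional-hazards
regime they assume — not performance on real cohorts.

## Test-bench conditions and problem sizes

Recovery checks use 100 seeded replicates each at the conditions above:
association voting on 200-sample cohorts with 3 planted pairs among ≥ 50
decoy pairs (Pearson + Spearman); prognostic presence on 250-sample cohorts
with one β = 1.0 feature among 30 noise features (5-fold, 3 models);
predictive presence on 160-sample cohorts with one +3 sd feature among 40
noise features (5-fold, 3 selectors). Empirical-p calibration draws the
observed statistic from the null population (2000 repetitions, null size
199) and checks uniformity by Kolmogorov–Smirnov. Negative controls permute
survival times, class labels, or sample order and require every planted
signal to fall back into the noise range.

## Degenerate inputs and edge cases

- Duplicate feature ids at read time collapse to the highest-mean row
  (deterministic probe-collapse heuristic; first occurrence wins ties).
- Missing values are tolerated at read; analyses use pairwise-complete
  observations; features > 20% missing are dropped with a warning.
- The differential-expression filter is Welch's t with Benjamini–Hochberg
  adjustment across tested features (|log2 FC| and q thresholds);
  normalization is assumed upstream.
- Zero-variance features are rejected wherever a correlation, z-score or
  Cox fit would be undefined; constant genes inside a gene-set score
  contribute 0.
- Sample matching uses the sorted intersection of ids (≥ 10 required), so
  every downstream computation is order-stable.
- Expression values are re-parsed with numpy's correctly-rounded float
  parser, so write→read round trips are exact.

## Known limitations

Per-analysis BH correction is intentional (matches interactive use) — q
values are not comparable across invocations. The regression step fits one
gene at a time and does not model transcription-factor co-regulation or
miRNA cooperativity. Multivariate adjusted Cox, competing risks and
time-dependent covariates are out of scope. The per-patient targeting score
is a pragmatic weighting, not a calibrated probabilistic model.
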