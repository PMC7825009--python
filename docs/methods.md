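# Methods

`metpath` turns a samples × metabolites intensity matrix into
personalized, pathway-level features and fits diagnostic and prognostic
models on either feature level. This note documents the models, the
numerical choices, and what the synthetic fixtures do and do not show.

## Preprocessing

Order is fixed: impute first, then normalize (the normalizations assume
a complete matrix).

**KNN imputation.** Features are treated as points in sample space (the
expression-array convention): the distance between two features is the
Euclidean distance over samples where both are observed, and a missing
entry is the unweighted mean of the `k` (default 10) nearest features
observed at that sample. Features missing in more than
`max_missing_frac` (default 0.5) of samples are too unreliable for
neighbour search and fall back to the per-sample mean. Observed entries
are never altered. This is implemented directly rather than through
`sklearn.impute.KNNImputer`, whose nan-Euclidean distance rescales by
the fraction of mutually observed coordinates and can therefore rank
neighbours differently.

**Normalization.**

- *standard*: per-feature z-score (n−1 denominator); zero-variance
  features are set to 0 with a warning.
- *quantile*: each sample's sorted values are replaced by the
  cross-sample rank means; ties receive the average of the tied
  positions' rank means, so tied values stay tied.
- *median-fold* (probabilistic quotient; the default): each sample is
  divided by the median of its fold changes against the per-feature
  median reference spectrum. Requires strictly positive intensities.

## Exploratory analysis

PCA and t-SNE are delegated to scikit-learn (`svd_solver="full"`;
t-SNE with a fixed `random_state` and one job is deterministic, and the
perplexity must satisfy perplexity < (n−1)/3). The source-of-variation
(SOV) screen regresses every metabolite on all listed clinical factors,
takes the Type-II ANOVA F statistic per factor (`statsmodels`
`anova_lm(typ=2)`; Type II matches the usual treatment of models
without interactions), and averages the per-metabolite F values into a
single score per factor — the arithmetic mean is a choice; the
aggregation is not canonical. The residual row has F = 1 by
definition, so a factor with mean F > 1 explains more variance per
degree of freedom than noise and is flagged as a confounder.
Continuous covariates enter untransformed with 1 df. SOV only flags
confounders; nothing downstream adjusts for them automatically.

## Pathway dysregulation scores (PDS)

For each pathway with at least `min_size` (default 3) mapped
metabolites:

1. Member columns are z-scored with the **control** mean and sd
   (deviation is measured from the normal reference, and positive
   rescaling of any metabolite cancels); metabolites with zero control
   sd are centered only.
2. The cloud is reduced to the smallest number of principal components
   explaining ≥ `var_frac` (default 0.85) of variance, capped at
   min(n−1, p, 5). Principal curves in the full metabolite space are
   unstable at metabolomics sizes; fitting in a low-dimensional leading
   subspace follows established practice for this transformation.
3. A Hastie–Stuetzle principal curve is fitted through the reduced
   cloud (below). Each sample's raw score is the arc-length distance
   from the curve start to its projection.
4. The curve is oriented so the control median lies at the near end
   ("start" is otherwise arbitrary), and scores are divided by the
   maximum sample distance, so every pathway column lies in [0, 1] and
   attains 1.

A pathway whose member columns (or reduced cloud) have zero variance is
skipped with a warning. With a single retained component the principal
curve is the line itself and the arc distance reduces to the min-max
scaled coordinate.

**Principal curve fitting.** Initialization is the first principal
component segment. Each iteration projects the points onto the current
polyline (ties between equidistant positions resolve to the smaller arc
length), smooths each coordinate against the arc-length parameter with
a lowess smoother (`statsmodels`, local regression, span 0.6, no
robustness iterations so exactly linear data are reproduced exactly),
and re-parameterizes by cumulative arc length. Convergence is declared
when the relative drop in total squared projection distance falls below
`tol` (1e-4) or after `max_iter` (50) iterations. An iteration that
would increase the criterion terminates the loop with the previous
curve, so the recorded criterion sequence is non-increasing. No
stability sub-sampling is performed; the hook is left for future work.

## Classification

Six classical algorithms run with scikit-learn defaults (GBM, LDA,
logistic regression, random forest, a single decision tree for
recursive partitioning, SVM) next to a bespoke feed-forward network.
The evaluation harness makes repeated stratified ~4:1 train/test
splits (default 10 repeats); training-side metrics are pooled
out-of-fold confusion counts from k-fold CV inside the training split
(default 10 folds), test-side metrics come from the held-out fifth,
and per-repeat values are retained for paired one-tailed t-tests
between algorithms. Reported metrics: accuracy, sensitivity,
specificity, F1, and balanced accuracy = (sensitivity+specificity)/2.
Ratios with zero denominators are reported as 0 and flagged.

**The network.** Rectifier or tanh hidden layers from a preset menu
(100; 200; 10,10; 20,20; 50,50; 30,30,30; 25,25,25,25), input dropout
on the 0.1 lattice up to 0.9, L1/L2 penalties, mini-batch SGD (batch
32) with an ADADELTA-style per-parameter adaptive step governed by the
decay factor ρ ∈ {0.5, 0.99} plus a classical momentum term
(`momentum_start` ∈ {0, 0.5}), cross-entropy loss, an epoch cap
(fractional caps allowed), and one scoring round per epoch with early
stopping when the misclassification rate fails to improve by 0.01
within 5 rounds. `quantile_alpha`/`huber_alpha` pertain to regression
losses and are carried as inert configuration. Hyperparameter search
("RandomDiscrete") samples configurations uniformly without
replacement from the 560-point lattice (2 activations × 7 layouts × 10
dropouts × 2 momentum × 2 ρ), scores each by CV F1, and refits the
winner; a budget at or above the lattice size is an exhaustive search.

## Prognosis

Both models produce a per-sample prognosis index (PI) — the log hazard
ratio θ. The baseline hazard is never estimated: ranking (C-index),
log-rank on PI-defined groups, and Kaplan–Meier curves need only θ.

**Partial likelihood.** pl(θ) = Σ_{events i} [θ_i − log Σ_{t_j ≥ t_i}
exp(θ_j)], with tied event times sharing one risk set (Breslow — the
simplest rule consistent with that expression). The gradient is
computed in closed form and is finite-difference-checked in the tests.

**Penalized Cox.** Elastic-net penalty λ[α‖β‖₁ + (1−α)‖β‖₂²/2] with
α = 1 (Lasso) by default. The path (100 log-spaced λ down to
0.001·λ_max) is solved by scikit-survival's coordinate descent for
α > 0 and by lifelines' Newton solver for ridge (α = 0) and the
unpenalized λ = 0 fit. λ is selected by k-fold CV (default 5,
event-stratified folds) on the Verweij–van Houwelingen cross-validated
partial-likelihood deviance; `lambda_min` takes the best mean,
`lambda_1se` the largest λ within one standard error of it (the
default, favouring sparser models). When the per-fold path solver
truncates, the last computed coefficients are carried forward for
smaller λ, as in glmnet's cross-validation.

**Cox neural network.** One hidden layer, θ = G(Wx+b)ᵀβ with G ∈
{tanh, rectifier, identity}, hidden size defaulting to ⌈√p⌉, trained
by full-batch standard/momentum/Nesterov gradient descent on
Cost = −pl + λ(‖β‖₂² + ‖W‖₂²) (squared norms, i.e. weight decay;
biases unpenalized). The step is scaled by 1/(number of events) so the
learning rate (default 0.01) is insensitive to cohort size. The
learning rate multiplies by 1.1 when the cost improved over the last
10 iterations and by 0.5 otherwise; a step that makes the cost
non-finite or explode is reverted with the rate halved. Training stops
at `max_iter`, when the relative improvement over an evaluation
interval falls below 1e-5 (after `min_iter`), or when no new lowest
cost appears within the patience window; the best-cost parameters are
returned. λ can be chosen by CV on the training set
(`select_lambda`). With the identity activation and λ = 0 the model is
an over-parameterized linear Cox model, and its held-out C-index
matches the Newton fit — a test exploits this.

**Evaluation.** Dichotomization methods: median PI (default),
event/non-event ratio (the k largest PIs are high-risk, k = observed
events), quartile (below Q1 low, above Q3 high, middle excluded), and a
single-threshold `q1_threshold` variant (both quartile readings are
provided because the source material is ambiguous about which is
canonical). Quantiles use the type-7 linear-interpolation rule; group
membership near the cut can differ by rule, hence the documentation.
Harrell's C counts pairs where the earlier time is an observed event;
PI ties score 0.5. The log-rank statistic is the classical (O−E)²/V
sum over event times against χ²(1). KM step tables come from
lifelines. With `cv_folds` set, evaluation refits the model per fold
and pools out-of-fold PI, one entry per sample.

## Synthetic fixtures

Intensities are log-normal (per-metabolite log-mean uniform in [2, 6],
log-sd 0.5 — a typical within-cohort spread for quantified
metabolomics panels). Case/control datasets shift the member
metabolites of designated effect pathways by `effect_size` control-sd
on the log scale. Survival datasets draw a standard-normal latent
activity per pathway per sample, shift member metabolites by 0.8·log-sd
per activity unit, and draw event times exponentially with hazard
h₀·exp(zᵀβ_true); censoring is independent uniform with the upper
bound calibrated by bisection to the requested censored fraction.
Missingness is MCAR at a given rate, never blanking a whole feature.
Pathway membership may overlap and the fixtures exercise that.

The fixtures deliberately omit chromatographic drift, batch effects,
detection-limit (left-censored) missingness, and realistic compound
identities. Tests passing on them demonstrate that the pipeline
recovers the structure it models — concentrated pathway shifts and
log-linear hazards — not that it is robust to those unmodelled
artefacts.

## Problem sizes and defaults used in the shipped checks

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which the statistical claims are comfortably
identifiable: C-index calibration at n = 1000 with 50 replicates; PDS
range checks on 200 samples × 100 metabolites with 10 pathways of 8;
survival parameter recovery at n = 200 with 30 pathway features over
20 seeds; classification sanity on two 5-dimensional Gaussians 6 sd
apart, n = 200, with the network capped at 30–60 epochs. Defaults in
the API are the full-size ones stated above.

## Known limitations

- Name matching is exact after case-folding/trimming; no fuzzy
  matching. No online ID lookups.
- Binary phenotypes only; no multi-class classification, no
  time-dependent covariates or competing risks, no Efron tie
  correction.
- The curve orientation guarantees a control median at the near end of
  the *distance* scale; when cases are unshifted, case and control
  score distributions coincide by design.
- SOV assumes additive factor effects (no interactions).
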