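# Methods

This note documents the statistical machinery in `fairdep`, the design
choices behind it, and what the synthetic experiments do and do not show.

## Problem setting

A binary clinical risk model (here motivated by depression screening)
maps descriptive features Y to a predicted probability, thresholded into
a hard call Ĉ ∈ {0, 1} with 1 = condition present. The population carries
one or more categorical protected attributes X (sex, ethnicity, age band,
income, comorbidity); each category x defines a subgroup. The audit
question is whether the model performs equally across subgroups, and the
mitigation question is how to repair it when it does not.

## Metrics

- **Subgroup rates.** TPR_x = E[Ĉ | C=1, X=x], FPR_x = E[Ĉ | C=0, X=x].
  A rate whose conditioning set is empty is *undefined* and carried as an
  explicit flag — never coerced to 0 and never silently dropped, because
  the smallest subgroups are exactly the ones an audit must keep visible.
  Metrics that need an undefined rate raise instead of guessing.
- **EOD** (equal-opportunity difference) = min_x TPR_x − max_x TPR_x,
  stored signed in [−1, 0]; 0 means all subgroup sensitivities agree.
  The conventional acceptance band |EOD| ≤ 0.1 is exposed as a labeled
  predicate (`is_fair_eod`), not hard-coded anywhere.
- **AOD** (average-odds difference) = ½[min_x(TPR_x+FPR_x) −
  max_x(TPR_x+FPR_x)], the equalized-odds analogue. Groups with opposite
  error profiles but equal rate sums cancel; AOD is a spread measure,
  not a per-rate test.
- **BAcc** = (sensitivity + specificity)/2, the appropriate scalar under
  the class imbalance typical of these cohorts (4%–40% positives);
  **AUC-ROC** is reported alongside (threshold-free).
- **Δ score** = (1+β²)·BAcc·(1−|EOD|) / (β²·BAcc + (1−|EOD|)), the
  weighted harmonic mean of performance and fairness. β = 0.5 weights
  performance over fairness — the clinically conservative choice when
  missed positives cost more than residual disparity. β → 0 recovers
  BAcc exactly.
- **Tukey HSD** on a folds × groups rate table treats CV folds as
  replicates in a balanced one-way layout. This is an approximation —
  folds share training data, so within-group variance is understated —
  but it is the standard way such audit figures annotate significance.
  Implemented directly on the studentized-range distribution; zero
  within-group variance degenerates to zero-width intervals with a
  warning.
- **Mann–Whitney U** compares per-group score distributions (the
  diagnostic for prevalence-driven score shifts). Exact enumeration when
  both samples are ≤ 20 without ties; tie-corrected normal approximation
  otherwise, keeping desk-scale runtimes.

## Mitigation techniques

Pre-processing (act on training data; the model is refit):

- **SUP** deletes the protected attribute from the feature set. Groups
  remain available for evaluation. Insufficient whenever proxy features
  carry group information.
- **RW** weighs each (group x, label c) cell by
  w = P̂(C=c)/P̂(C=c | X=x). The weighted contingency table factorizes
  exactly, total weighted mass equals n, and all weights are 1 when X
  and C are already independent. Feature values are untouched; the
  protected attribute stays among the features (base models include it).
- **DIR** (quantile repair) maps each numeric/ordinal feature value v in
  group x to (1−λ)·v + λ·Q_target(F̂_x(v)), where F̂_x is the group's
  mid-rank training ECDF and Q_target(u) is the median across groups of
  the group quantile functions at rank u. λ = 0 is the identity, λ = 1
  (the default, and the form the repair is usually described in) makes
  all group marginals coincide up to order-statistic interpolation.
  Categorical features pass through unchanged (quantile repair is
  undefined for unordered categories); the treated attribute is excluded
  from the output feature set. Applied to new data with the *fitted*
  quantile functions, so no test-time information enters the transform.

Post-processing (act on model outputs; the model is untouched):

- **CPP** equalizes the generalized false-negative rate
  g_x = E[1 − score | C=1, X=x] across groups: each group below the
  maximum cost replaces the scores of a seeded random fraction α of its
  samples with the group base rate (the trivial calibrated predictor),
  with α = (g_max − g_x)/((1 − base_rate_x) − g_x) solving the mixed-cost
  equality. The random selection is stratified by label to reduce
  Monte-Carlo noise in the positive-class cost. The FNR cost is the
  right one when recall matters more than precision (underdiagnosis is
  the costly error in screening).
- **PSTA** assigns per-group decision thresholds. Anchors S* and F* are
  the overall training sensitivity and FPR at the reference threshold
  t₀ = 0.5. Groups whose sensitivity at t₀ already reaches S* keep t₀.
  Each remaining group receives the largest t ≤ t₀ among its observed
  positive scores (plus t₀) with group sensitivity(t) ≥ S* and group
  FPR(t) ≤ F* + δ; failing that, the candidate maximizing sensitivity
  under the FPR cap (larger t on ties, minimizing FPR inflation); if
  even t₀ violates the cap the group stays at t₀ with a warning. Default
  δ = 0.10; both t₀ and δ are hyperparameters. Choosing the *largest*
  qualifying threshold is deliberate: among thresholds that align the
  group's sensitivity with the population's, it inflates that group's
  FPR the least. The candidate set is restricted to observed positive
  scores because sensitivity only changes at those points. The fit is
  invariant to sample order.

Treating every below-S* group (rather than only the single worst) keeps
the method meaningful for multi-category attributes.

## Evaluation protocol

`run_scenario` runs stratified k-fold cross-validation (default k = 10;
stratification on the outcome stabilizes subgroup rate estimates in
imbalanced cohorts). Within each fold: pre-processing transforms are
fitted on and applied to the training split only; the model (standardized
logistic regression or gradient-boosted trees, both seeded and
single-threaded for reproducibility) is fitted on the training split;
post-processing policies are fitted on training-split scores only; all
metrics are computed on the held-out split. Optional nested-CV
hyperparameter tuning (small default grids: 4 regularization strengths
for the linear model, a 3×3 depth × learning-rate grid for the boosted
trees) is off by default — the audit experiments here use the default
settings, and the grids are config-overridable.

Fold summaries are mean ± 1.96·SE (normal approximation); Tukey
simultaneous intervals are available separately for pairwise subgroup
claims. Folds where a metric is undefined are skipped with a warning;
a scenario aborts if more than half its folds are lost. Results
serialize to JSON deterministically (sorted keys, no wall-clock fields),
so a fixed spec + seed reproduces byte-identical output.

`compare_methods` scores each (scenario, method) cell by Δ computed from
fold-mean BAcc and fold-mean EOD and tallies argmax winners; exact ties
are counted for all tied methods and flagged. `spillover_analysis`
reports the change in |EOD| and |AOD| on untreated attributes
(positive = fairness worsened).

## Synthetic cohorts

The generator reproduces the statistical structure that drives algorithmic
bias in real screening cohorts without any restricted data:

- **Group-dependent prevalence.** Outcome is logistic in the features
  plus a per-group intercept solved by root-finding so each group's
  *marginal* prevalence matches its target on the realized sample.
  Default sex prevalences 0.08 vs 0.04 — the well-replicated ≈2:1
  female:male depression ratio; the canonical *biased* audit cohort uses
  0.10 vs 0.04.
- **Proxy features.** The first `n_proxy` (default 2) of `n_features`
  (default 6) informative features get group-shifted means, scale
  `proxy_strength`, ordered by prevalence rank so proxies point the same
  way as the outcome gap — the structure that lets a model recover a
  deleted attribute, making SUP insufficient and DIR meaningful.
- **Effect sizes.** All informative features carry a common log-odds
  coefficient (default 0.8, noise SD 1.0), giving a discriminative but
  imperfect model (test AUC ≈ 0.89, BAcc at 0.5 ≈ 0.62 on the biased
  cohort) — the regime questionnaire-based risk scores occupy.
- **Attribute correlation.** A second attribute can copy the driver's
  category with probability p (otherwise drawing from the other
  categories): p = 1 duplicates, 0.5 is independence, 0 anti-aligns.
  Used for spillover experiments.

`generate_scored_population` skips the model entirely and draws labelled,
group-tagged scores from clipped-Gaussian laws per (group, class) — the
right fixture for post-processing methods, which only ever see scores.

What the generator does **not** emulate: realistic exposome feature
semantics, feature missingness, longitudinal structure, survey weights,
label noise, or calibrated real-world effect sizes. Passing tests
demonstrate that the machinery behaves as specified under controlled
bias structure, not that any particular real cohort would show the same
magnitudes.

## Observed behavior of the audit experiment

On the canonical biased cohort (n = 20000, prevalences 0.10/0.04, proxy
strength 0.5, logistic model, 10-fold CV, 10 replicate seeds), computed
by the test suite and `scripts/acceptance.py`:

- the base model shows a consistent disparity against the low-prevalence
  group (fold-mean EOD ≈ −0.09 to −0.18 across seeds);
- RW reduces |EOD| in 9/10 replicates and PSTA in 10/10, both with mean
  BAcc within 0.015 of base; PSTA attains the highest Δ;
- SUP never reduces |EOD| here — with informative proxies present,
  deleting the attribute removes the model's ability to *compensate*,
  and residual |EOD| stays above 0.12;
- CPP equalizes the FNR cost well but pays for it in BAcc (score mixing
  degrades the privileged group), the known cost of calibrated mixing;
- DIR reduces |EOD| in 8/10 replicates with a mean BAcc gap of ≈0.025.
  The shortfall is structural, not numerical: full repair removes *all*
  group information from the features, but part of the configured
  prevalence gap is intercept-driven (not feature-mediated). Positives
  from the rare group are selected to have more extreme features, so
  after repair their TPR overshoots the other group's — the sign of EOD
  flips rather than shrinking to zero. Verified directly: the repair
  itself drives the between-group KS statistic to 0. In cohorts where
  the prevalence gap is mostly feature-mediated, full repair behaves
  better; a partial repair level (λ < 1) interpolates.

## Numerical choices and degenerate inputs

- Lexicographic category order everywhere an order is needed.
- Missing protected values form an explicit "Missing" category; they are
  audited as a subgroup, never imputed or dropped.
- PHQ-9 totals outside [0, 27] are rejected; the positive label is
  total ≥ 10.
- RW with an absent (group, label) cell simply assigns no weight there.
- CPP where the trivial predictor cannot raise a group's cost
  (g_trivial ≤ g) leaves α = 0 with a warning.
- Δ is defined as 0 when both terms vanish.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); no global state.

## Problem sizes

The shipped experiments use n = 20000 cohorts, 10-fold cross-validation
and 10 replicate seeds — large enough that binomial noise on subgroup
rates (SE ≈ 0.01–0.02 on fold-level TPRs) is well below the effects
being measured, and small enough to run on a laptop in minutes.
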