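# Methods

## Problem setting

`hetsurv` targets right-censored survival prediction on tabular clinical
cohorts: each patient contributes a follow-up time in days, an event
indicator (1 = death observed, 0 = censored at that time), and a mix of
continuous, nominal and ordinal features.  Different survival models
(penalized Cox regression, survival SVMs, gradient-boosted Cox and
accelerated-failure-time models, random survival forests) optimize different
losses and fail in different ways; rather than betting on one, the package
builds a *heterogeneous ensemble*: a library of many fitted configurations,
filtered for accuracy, pruned for diversity, and aggregated.

## Cross-validated models and selection

Every library entry (a learner family plus one hyper-parameter map) is
fitted as a **cross-validated model**: the training data is split into K
event-stratified folds (default K = 5) and one *sibling* is trained on each
of the K leave-one-fold-out subsets.  Each training sample then has exactly
one out-of-fold prediction, produced by the sibling that never saw it, so
the full training set doubles as a validation set without sacrificing data.
A model's performance c̄ is the per-fold metric averaged over folds
(Harrell's concordance index by default; an integrated time-dependent AUC
and an events-only RMSE are also available).  A pooled variant — one metric
over all out-of-fold predictions at once — is provided behind a switch; the
per-fold average is the default because downstream pruning consumes the
average cross-validation performance.

Selection keeps models whose c̄ meets a minimum threshold: an absolute
c_min (default 0.66, boundary kept, i.e. "≥") for higher-is-better metrics,
or, for RMSE, every model within 15 % of the best model's error.  Selection
is a pure threshold rule; iterative forward hillclimbing is deliberately not
implemented.  At prediction time a cross-validated model emits the mean of
its K siblings' predictions, so an ensemble of S cross-validated models is
in effect an ensemble of K × S fitted models.

## Diversity pruning

Survival predictions are risk scores on arbitrary scales, so residual-style
per-sample errors do not exist.  Diversity is therefore measured on the
predictions themselves: given the n × |L| matrix of member predictions,
member i's diversity is

    d_i = (|L| − count_i) / |L|,

where count_i is the number of *other* members whose prediction vector
correlates with member i's at or above a threshold τ_corr (default 0.6),
under Pearson (default) or Kendall tau-b correlation.  Note the formula's
floor is 1/|L|, not 0, because a member is never counted against itself; the
formula is implemented exactly as stated.  A constant prediction vector has
no defined correlation; it maps to a NaN sentinel that never reaches the
threshold, so a constant predictor looks maximally diverse rather than
crashing the count — it carries no ranking information and is effectively
uncorrelated with everything.

Accuracy is scored relative to the best member — a_i = c̄_i / c̄_max for
higher-is-better metrics, min(RMSE)/RMSE_i for lower-is-better — and the
top S members by combined score a_i + d_i form the pruned ensemble
(default S = top 5 % of the library, rounded half-down; libraries already
no larger than S pass through unpruned).  Boundary ties break by higher
accuracy, then input order.

Because risk-score diversity needs no ground truth, pruning is **dynamic**:
it runs at prediction time on the test features themselves, so a different
test set may select different members.  For survival-time (AFT-style)
libraries, diversity instead uses out-of-fold training residuals over
observed events, since predictions and times share a scale there.

## Aggregation

Two aggregations are provided.  The plain **mean** of member predictions is
the default and is the natural choice for time predictions, which share a
scale (days).  For heterogeneous risk scores the mean is scale-sensitive: a
Cox model's linear predictor lives near zero while a forest's
cumulative-hazard score lives in the tens, so the largest-scale member
dominates and oppositely signed scores can cancel.  **Rank-mean**
aggregation converts each member's predictions to within-sample ranks
(average ranks on ties) before averaging, which is invariant to any
strictly increasing per-member transform.  Rank-mean requires at least two
samples — ranking a single prediction is undefined — and this is raised as
an explicit error.

## Censored-data metrics

* **Harrell's c-index**: over pairs (i, j) with an observed event i and
  t_i < t_j, the fraction where risk_i > risk_j, tied risks counting ½.
  Pairs tied on time are not comparable.  No comparable pair raises an
  explicit error instead of silently returning 0.5.
* **Censoring survival Ĝ**: Kaplan–Meier product-limit estimate with
  censoring as the event of interest; constant 1 when no censoring is
  observed.
* **Cumulative/dynamic AUC at horizon t**: cases are test samples dead by
  t, controls those under observation past t; cases are reweighted by
  1/Ĝ(T_i) with Ĝ estimated on the training data (inverse probability of
  censoring weighting).  A required weight at a time where Ĝ = 0 — the
  horizon exceeding the training follow-up — raises an explicit error
  rather than returning NaN.
* **Integrated AUC**: unweighted mean of AUC(t) over a horizon grid,
  defaulting to every 6 months up to 30 months at 30.4375 days/month.  The
  unweighted mean (rather than a survival-weighted integral) is a
  documented simplification.
* **Events-only RMSE**: root mean squared error of predicted survival days
  over observed deaths only; censored samples carry no usable time of
  death and are excluded; zero events is an error.

## Encoding and the clinical kernel

Continuous features are imputed by the training median and standardized to
zero mean, unit population variance with training statistics; nominal and
ordinal features are imputed by the training mode and dummy coded with the
first schema level dropped as reference (avoiding collinearity for linear
models).  Median/mode imputation is a deliberate simplification and can be
switched off to require complete data.  Ordinal level order is taken from
the schema as given.

Kernel SSVMs consume the **clinical kernel** instead of the design matrix:
per-feature similarities — (range − |a − b|)/range for continuous features
(range from the schema), exact-match indicator for nominal, the continuous
formula on level ranks for ordinal — averaged over features.  Entries lie
in [0, 1] with unit diagonal; values outside the schema range are clipped
with a logged warning.

## Learner families

Nine families are exposed behind a thin adapter: ridge-penalized Cox,
linear and clinical-kernel ranking SVMs, gradient-boosted Cox models with
tree and componentwise-least-squares base learners, random survival
forests (risk ranking); gradient-boosted accelerated-failure-time models
(tree and componentwise) and a hybrid ranking/regression kernel SVM
(survival-time prediction).  The underlying estimators are scikit-survival's;
the adapter's own content is the orientation contract (ranking families
emit higher = riskier; time families emit days, negated when a risk score
is needed), the encoder/kernel binding, and conversion of fit failures into
structured errors so that thousand-model library builds skip and log rather
than abort.  Default grids reproduce the library composition used at the
two deployment scales (1,728 + 36 + 24 + 13 = 1,801 ranking configurations;
1,728 + 36 + 78 = 1,842 time-prediction configurations) but are fully
configurable; the hybrid SVM's grid includes rank_ratio 0.0–0.5 alongside
13 regularization values.

Grid search, where used, follows a repeated-split protocol: ten
event-stratified random 80/20 splits per hyper-parameter map, the map with
the best average metric refit on the complete data.

## Synthetic cohorts

The simulator draws event times by inverse-transform sampling from an
exponential (default) or Weibull baseline hazard scaled by exp(η), with η a
linear predictor over a numeric representation of the features (continuous
values; centered level codes for categorical features), optionally plus one
pairwise interaction term — a single controllable nonlinearity is enough to
separate linear from nonlinear learners in tests.  Observation is cut by
independent uniform or exponential censoring and an administrative
follow-up horizon; the event indicator marks whether the true event time
was the minimum.  Defaults emulate a mid-sized phase-III oncology trial:
500 patients, 13 mixed-type features with moderate effects, ~600-day median
baseline survival, a 3-year horizon, and uniform loss to follow-up —
parameters of the same order as phase-III metastatic castration-resistant
prostate cancer trials, whose follow-up medians span roughly 280–640 days.  One global seed drives three independent
substreams (features, event times, censoring), so the censoring regime can
be varied with the population held fixed.  The multi-trial generator gives
each trial a shared feature block with identical true coefficients plus
trial-private features, for exercising feature intersection and
between-trial transfer.

What the simulator does *not* emulate: real covariate distributions and
correlations, informative (outcome-dependent) censoring, competing risks,
time-varying effects, or the measurement quirks of real case report forms.
Passing tests therefore demonstrate correctness of the machinery and
qualitative behaviour under proportional hazards, not clinical performance.

## The multi-horizon benchmark

`hetsurv.experiments.run_ensemble_benchmark` fixes one train (n = 400) and
one test (n = 200) population from a linear hazard with one interaction
term and re-observes both under five administrative horizons from 300 to
1,200 days, emulating trials with very different follow-up.  Per horizon it
builds a 21-configuration library across six families (K = 5, c_min = 0.6,
τ_corr = 0.6), prunes to the top 10 by combined score on the test features,
and aggregates by rank-mean.  Holding the population fixed isolates the
follow-up-regime effect from resampling noise; rank-mean avoids the
scale-domination failure of plain averaging across families; keeping about
half the library in the ensemble is what buys variance reduction.  The
expected behaviour, asserted in tests and recomputed by the acceptance
script, is that the ensemble's test c-index is at least the median
member's in every regime and that its range across regimes is no larger
than the range of any single family's best model.  Problem sizes (21
configurations, 400/200 samples, five horizons) are the package's chosen
desk-scale study; they keep a full run to a few minutes on one CPU.

## Numerical choices and edge cases

* Fold assignment and grid-search splits are event-stratified so partial-
  likelihood fits never see an event-free training fold; a fold with fewer
  than two events marks the model failed rather than crashing the build.
* Standardization uses population variance (ddof = 0); a constant feature
  gets scale 1 (centered, not divided).
* top_fraction resolves to S by round-half-down (5 % of 1,801 → 90, 5 % of
  1,842 → 92), with a floor of one member.
* Event indicators accept {0, 1, False, True} only; anything else is
  rejected rather than coerced.  Times must be strictly positive, finite
  days; no unit inference is attempted.
* Determinism: the same seed reproduces folds, grid-search splits,
  simulated cohorts and therefore entire library builds bit for bit.

## Known limitations

* Metrics are O(n²) pair computations; adequate for cohorts of thousands,
  not for hundreds of thousands.
* Dynamic pruning recomputes member predictions and the full correlation
  matrix per test set; Kendall diversity is quadratic in library size and
  noticeably slower than Pearson for thousand-model libraries.
* The censoring Kaplan–Meier makes the usual random-censoring assumption;
  IPCW-based AUC is undefined past the training follow-up by design.
* Missing values are handled by median/mode imputation only; model-based
  imputation is out of scope.
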