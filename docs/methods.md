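# Methods

This note documents the models, numerical choices and design decisions behind
`vo2quant`, and what its synthetic-data experiments do and do not demonstrate.

## Preprocessing conventions

Heart-rate samples are averaged over the minute *starting* at each minute
mark `t_i`; only minutes containing at least one sample appear.  Cadence at
`t_i` is the number of steps in the half-open window `(t_i − 1 min, t_i]` —
the minute *ending* at `t_i` — so the per-minute pair couples a heart-rate
reading with the stepping that immediately preceded it, which is the right
direction for a lagged physiological response.  Step intervals spanning
several minute windows distribute their count proportionally to overlap
duration (a constant stepping-rate assumption); total steps are conserved
exactly.  Overlapping intervals from one user are treated as an input error,
not silently merged.

All timestamps are interpreted as the wearer's local wall clock, because day
boundaries and the noon–9 pm resting window are local-clock concepts; readers
strip any UTC offset after recovering the wall-clock reading.  The daily
resting heart rate is the 10th percentile of heart rate between noon and
9 pm; when a day has no data in that window the whole day's 10th percentile
is used instead (days with no heart-rate data at all contribute nothing).
All percentiles and quartiles in the package use linear interpolation between
closest ranks (numpy's default, the "type 7" convention).

## MET-minutes

A minute's metabolic equivalent is estimated from heart rate as
`MET = 6·hr/hr_rest − 5` and floored at 1: the formula goes below the resting
metabolic rate whenever `hr < hr_rest`, which is physiologically meaningless,
and the floor makes covered resting minutes consistent with the convention
that uncovered minutes count as exactly 1 MET.  A day's value is total
MET-minutes divided by 1440, so a day without activity scores exactly 1.

## Piecewise-linear quantile regression

The heart-rate response to cadence is a continuous two-segment piecewise
linear curve `w0 + w1·min(c, 100) + w2·max(c − 100, 0)` — the knot is fixed
at 100 steps/min (roughly the walk/run transition, 3 MET) and is not
estimated.  For each level q the coefficients minimise total pinball loss
over active minutes (`hr > 75` bpm, `c > 60` steps/min; strict inequalities).
The minimisation is solved as an exact linear program in dual form
(`max y'λ` s.t. `X'λ = 0`, `λ_i ∈ [q−1, q]`), whose equality-constraint
shadow prices are the primal coefficients; HiGHS solves it deterministically
and the three-row constraint matrix keeps the cost independent of sample
size.  Coefficients are reported rounded to 1e-6 for reproducibility.

Degenerate designs — fewer than two distinct cadence values on one side of
the knot — drop the unidentifiable slope column (the returned slope is zero
and the model is flagged).  Users with fewer than 30 qualifying minutes are
fitted anyway but flagged low-data.  Quantile curves are fitted independently
per level and may cross; monotonization is applied only to the final
prediction stack, not to the response feature.

## Quantile stack and rearrangement

One LightGBM learner per level q = 0.05, …, 0.95 is trained with the
quantile objective; default hyperparameters are depth 4, 313 estimators,
bagging fraction 0.75 every 13 iterations, learning rate 0.1, minimum 22
samples per leaf, L1 regularization 0.142.  Training is seeded and
single-threaded with LightGBM's deterministic mode, so identical data and
seed give bit-identical models.  Missing feature components (users without
activity minutes) are NaN sentinels handled natively by the trees — sparse
users are predicted, not dropped.

The raw curve q ↦ f_q(x) is monotonized by rearrangement: interpolate the
(level, value) pairs piecewise-linearly, clamp constant outside
[0.05, 0.95] (the curve is undefined beyond the fitted levels without
extrapolation), evaluate on a fixed grid of 1001 equispaced points in [0, 1],
sort, and read quantiles off the sorted grid by linear interpolation.  This
is the standard deterministic plug-in estimator of the quantile function of
`f_x(U)`; no random uniform draws are involved, so predictions are exactly
reproducible and exactly monotone.  Rearrangement happens per prediction at
inference time.  Grid resolution limits the accuracy of the rearranged curve
to roughly (steepest interpolant slope)/1000; for realistic raw stacks the
error is far below 0.05 ml/kg/min.

Hyperparameter search is a pluggable grid/random search minimising 5-fold
cross-validated CRPS (`evaluation.search_hyperparams`); no Bayesian
optimiser is bundled.

## Evaluation metrics

CRPS is computed in quantile space through the identity
`CRPS = 2·∫₀¹ L_q(y, Q̂(x, q)) dq`, evaluated by trapezoid on the
rearrangement grid; a CDF-space quadrature of `∫(F(z) − 1{z ≥ y})² dz` is
kept as an independent cross-check (the two agree within 1% on random
predictions).  The score is reported positively oriented — lower is better —
although it is sometimes written with a leading minus and maximised.

The expected calibration error integrates `|p_obs(q) − q|` where `p_obs(q)`
is the fraction of labels at or below the predicted q-quantile.  The
integrand is observable only at the fitted levels, so the integral is a
trapezoid over [0.05, 0.95]; the tails of the nominal [0, 1] range would
require extrapolating the quantile function and are left out, making the
reported ECE a slight underestimate of the full-range definition.  Sharpness
is the mean predicted interquartile range.  Median-error SD uses the sample
(n−1) denominator.  Cross-validation folds are shuffled and seeded but not
stratified.

The ablation experiment refits the stack on nested feature-group subsets
with a shared seeded train/test split; the empty subset is the marginal
model that predicts the empirical label quantiles regardless of features
(its ECE on its own defining sample is ~0 by construction, and its sharpness
is the marginal label IQR).  The sharpness-versus-data experiment mirrors
the history-window design: features are recomputed from lookback windows of
each test user's stream history (1, 3 and 10 days at the default cohort
length, standing in for the 1-week–8-month windows applicable to longer
histories), and the predicted IQR is binned by the window's active-minute
count.

## Shapley attribution

The attributed function is the raw 0.5-level learner (the median model),
not the rearranged median.  Coalition values are interventional: `f_S(x)`
averages the model over background rows with the features in S replaced by
x's values, so the empty coalition is the background mean and the full
coalition is `f(x)`.  Group-level values over the four groups (ant, chr,
met, resp) enumerate all 2⁴ coalitions with the exact factorial weights;
efficiency — values summing to `f(x)` minus the background mean — holds to
float round-off, and a group the model ignores gets exactly zero.
Per-feature values over all 24 features are estimated by seeded permutation
sampling with reported standard errors.  The background set is a seeded
sub-sample of up to 500 training rows by default (the full training set is
an option).  Tree-path-dependent attribution is deliberately not used as the
reference: the interventional definition is the semantics the tests check.

## Synthetic cohort generator

The generator is the feature model run forward, so every statistic the
pipeline computes is identifiable; it does not claim physiological realism
beyond that.  Per user it draws gender (2:1 male:female), age (42 ± 10.6 y),
and BMI (26.5 ± 4 kg/m²), and composes a latent VO₂ max as

    vo2 = 36.16 + 6.0·(male − ⅔) − 0.35·(age − 42) − 0.60·(bmi − 26.5)
          + 2.5·z_act + core

where `z_act` is the standard-normal driver of habitual activity volume and
`core` is residual fitness variation whose SD is set by variance accounting
so the marginal distribution is 36.16 ± 6.66 ml/kg/min.  The coupling
magnitudes are physiological: a cross-sectional age decline of ~0.35
ml/kg/min per year, a male–female gap of ~6 ml/kg/min, and a BMI penalty of
~0.6 per kg/m².  Labels add Gaussian device-style noise (SD 3.5 ml/kg/min,
the accuracy reported for wrist-device estimates) and are clipped to the
[12, 80] range wearables actually report.

Fitness is expressed in the streams through the structures the features
assume: the per-user generating response curve lowers its intercept
(−0.8 bpm per ml/kg/min around 95 bpm) and slopes with the fitness core;
resting heart rate falls with fitness (−0.5 bpm per ml/kg/min around
72 bpm).  Daily activity is Poisson around a per-user log-normal propensity
(median 20 min/day, σ = 1.4 on the log scale), arranged into walking
(~95 steps/min) and running (~160 steps/min) bouts of geometric length;
each bout emits one multi-minute step interval at constant integer cadence,
which exercises proration and makes step conservation exact.  Heart rate
adds heteroscedastic minute noise (SD 5 bpm at moderate cadence, growing
with cadence) and a day-level systemic shift (SD 5 bpm) shared by resting
and exercising heart rate — the day-to-day variation (sleep, stress, heat)
that makes response estimates from short histories genuinely uncertain and
is what drives sharpness improving with observed data.  Every user and
(user, day) has its own RNG stream derived from the cohort seed, so
generation is fully deterministic and order-independent.

Default experiment sizes are desk-scale: 2000 users and 10 observed days
per user (the feature-ablation and sharpness experiments run on ten such
cohorts), with lookback windows of 1/3/10 days standing in for the
1-week–8-month windows of long free-living histories.

What passing tests on these cohorts shows: that the pipeline recovers the
structures it assumes, that calibration/sharpness/ablation behave as the
method predicts, and that every analytic identity holds.  What they do not
show: performance on real wearable data, whose activity structure, device
artefacts, label bias and population heterogeneity the generator does not
model (no circadian rhythm, heart-rate variability, GPS, terrain, disease
states or device-specific sampling quirks).

## Known limitations

* The ECE support is [0.05, 0.95]; models pathological only in the extreme
  tails would not be penalised.
* The LP fit is exact but unregularised; users with very few active minutes
  produce extreme response coefficients (they are flagged, and the tree
  model learns to treat them as uninformative, but downstream consumers of
  `features.csv` should respect the low-data flag).
* The marginal-quantile baseline and the stack share the rearrangement code
  path, so a defect there would bias both; the Monte-Carlo and CDF-space
  oracles in the test suite exist to catch exactly that.
* Synthetic-cohort conclusions are about internal consistency, not external
  validity (see above).
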