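# Methods

`actipred` models daily motor activity of psychiatric inpatients, recorded by
wrist-worn inertial sensors and classified minute-by-minute into five states
(running, walking, standing, sitting, lying) over a 120-minute unstructured
afternoon block, and uses early activity patterns to estimate the hospital
discharge date. This note documents the models, the synthetic cohort that
stands in for clinical recordings, and the numerical and design choices.

## Variables

For each patient-day the five states collapse into two categories — activity
(running, walking, standing) and rest (sitting, lying). Two windowed
statistics summarize the day:

- **Activity Time** — the maximum number of activity-category minutes in any
  contiguous 30-minute window of the block (91 candidate windows at the
  defaults), in [0, 30] minutes. The windowed maximum is preferred to the
  2-hour total because a patient's best sustained effort is more stable than
  fluctuating overall levels.
- **Rest Time** — the analogous maximum for rest-category minutes, computed
  independently (the two argmax windows may differ, so the two values need
  not sum to 30). A `lying-only` switch restricts the rest category to lying.

Time is indexed by **DoA** (day of admission, 1-based) and normalized as
**PTD** (Progress Towards Discharge) = DoA / length of stay, so the
discharge day maps to 1 and day 10 of a 20-day stay maps to 0.5. Days with
fewer than 30 recorded minutes (e.g. discharge before the observation block)
are dropped with a warning; windows on partially recorded days run over the
available span.

## Hierarchical linear trend (does activity rise over the admission?)

Per patient *j* and day *i*, with x = (1, PTD) and y = Activity Time / 30:

    y_ij = x_ij^T w_j + eps_ij,  eps_ij ~ N(0, sigma_eps^2),
    w_j ~ N(mu_w, Sigma_w).

Hyperparameters are estimated by empirical Bayes. Each iteration performs an
exact generalized-least-squares update of mu_w (the coordinate maximizer of
the marginal likelihood) followed by one conjugate E-step and the closed-form
M-step for (Sigma_w, sigma_eps^2); every step is monotone in the log marginal
likelihood, and the trace is retained so the monotonicity is testable. The
rank-2 design lets all marginal quantities reduce to 2×2 sufficient
statistics via the Woodbury identity, so the many cheap iterations the
variance components need (EM approaches them geometrically; default cap
20,000, relative tolerance 1e-8) cost milliseconds. A direct EM update of
mu_w was rejected: in the Sigma_w → 0 limit its step size collapses with
Sigma_w and the pooled-regression limit becomes unreachable in practice,
whereas the GLS coordinate update is exact there.

Intervals use the study's operational 78% definition, [mean − sd, mean + sd]
(other levels fall back to Gaussian quantiles). For the population slope the
reported band uses sd = sqrt(Sigma_w[1,1]) — the between-patient spread that
brackets the individual lines, which is the spread a clinician sees in the
per-patient trend plot; the standard error of mu_w itself (from the GLS
information matrix) is exposed separately as `fixed_effect_interval`. Note
that ±1 SD carries 68.3% Gaussian mass, not 78%; the operational definition
is kept as stated rather than silently recalibrated.

## Hierarchical Gaussian process (predicting discharge)

PTD is regressed on (Activity Time, Rest Time, DoA) with two additive GP
levels: an upper-level function g shared by the ward and independent
per-patient deviations f_n,

    y = g(x) + f_n(x) + noise,  g ~ GP(0, k_g),  f_n ~ GP(0, k_f),

which marginally is a single Gaussian whose covariance is k_g between all
pairs of days, plus k_f within a patient, plus noise on the diagonal. Both
kernels are squared-exponential on standardized inputs. Hyperparameters
maximize the joint log marginal likelihood (L-BFGS-B with analytic
gradients, 5 random restarts by default, Cholesky jitter 1e-8 escalating
×10 to 1e-4).

Two numerical safeguards are defaults rather than options, both motivated by
a structural identifiability trap: within a patient, PTD is an *exact*
function of DoA, so the per-patient level plus a vanishing noise variance
can memorize the training targets outright.

- **Tied (isotropic) lengthscales per level.** With free per-dimension
  lengthscales the marginal likelihood exploits the memorization route and
  prunes the activity inputs entirely (their lengthscales diverge), leaving
  the similarity search below blind to activity; in clustered-ward
  simulations this inverted the archetype match and doubled the error
  relative to the trivial baseline. One lengthscale per level keeps
  activity in the metric. Per-dimension scaling remains available
  (`ard=True`) for data where activity is not confounded with DoA.
- **Noise floor** (variance ≥ 1e-3 on the PTD scale, sd ≥ ~0.03) blocks the
  zero-noise collapse itself.

### Recursive discharge estimation

A new patient's days arrive in admission order with PTD unknown. At day d:

1. **Similarity.** Every training patient n is scored by the log predictive
   density of the new patient's accumulated days 1..d under n's posterior
   (upper level + n's deviation, conditioned on all training data). The
   targets used for scoring are *candidate-implied*: Y_i = min(1, doa_i /
   L_n), the progress the new patient would have if they shared candidate
   n's length of stay. The score therefore asks "how probable is this
   activity pattern at n's pace of progress?". An alternative — scoring one
   guessed trajectory shared by all candidates (e.g. from the previous
   day's estimate) — was implemented and rejected: a shared guess rewards
   candidates whose predictions are merely vague (high variance) over
   precise near-misses, and measurably inverted the cluster assignment.
   The implied-target score also makes an exact clone of a training patient
   select that patient from day one. Ties break to the smallest patient id.
2. **Prediction.** The selected patient's deviation is borrowed wholesale
   and PTD is predicted at day d's inputs, with a 78% band of ±1 predictive
   SD. The held-out patient's own deviation is never re-estimated — the
   selected inpatient literally serves as the regressor.
3. **Discharge arithmetic.** total = DoA / PTD̂ with PTD̂ clipped to
   [DoA/64, 1]; 64 days is the largest observed stay and the floor prevents
   unbounded estimates when predicted progress is near zero. Remaining days
   = total − DoA. The signed error is estimated minus real total length;
   negative means discharge predicted too early. Totals are real-valued;
   rounding (half-up) is left to report tables.

Day-d output depends only on days ≤ d (prefix consistency), and the
evaluation harness re-runs the selection each day.

## Baselines

- **Mean trained PTD**: predicts a new patient's PTD at day d as the mean
  (± SD) of d / L over training patients still admitted at day d, with
  nearest-day fallback outside the training support. On cohorts dominated
  by short stays its error at large DoA trends negative (discharge pulled
  forward) — the behaviour that motivates the hierarchy.
- **Random forest**: 500 trees, unlimited depth, fixed seed (scikit-learn),
  regressing PTD on the same three inputs; the per-tree spread supplies a
  predictive SD, and discharge arithmetic is shared with the GP so the
  predictors are drop-in comparable. Predicting PTD (rather than length
  directly) keeps the target symmetric across predictors.

## Evaluation

Leave-one-patient-out: train on the rest, run the recursive predictor over
the held-out patient's days, collect signed errors. Aggregation by DoA uses
the patients still admitted (n_admitted reproduces the survival pattern of
lengths of stay); per-day 95% CIs are mean ± t(0.975, n−1)·SD/√n, left blank
when fewer than two patients remain. Patients are bucketed by mean absolute
error (<1, 1–3, 3–5, 5–10, >10 days), and the best prediction day is the DoA
minimizing |mean error| among days with a configurable minimum of admitted
patients (default 3; ties to the earliest day). A predictor that fails on a
fold is skipped and reported, not silently dropped. An oracle predictor
(returns true PTD) gives exactly zero error everywhere and pins every
patient in the best bucket — the harness's correctness probe.

## Synthetic cohort

No clinical recordings ship with the package, so a generator emulates the
study conditions: 23 patients; lengths of stay from a log-normal clipped to
[5, 64] days with median ≈ 20.5 (log-mean ln 20.5, log-sd 0.65, matching a
mean near 25 days); per-patient trend weights w_j ~ N(mu_w, Sigma_w) with
mu_w = (0.445, 0.123) on the normalized activity scale, Sigma_w =
diag(0.01, 0.017) (slope SD ≈ 0.13); day-level noise sigma_eps = 0.28
(≈ 8.4 minutes on the 0–30 scale). Each day's intended activity occupancy is
clip(w_j · (1, PTD) + eps, 0, 1); minutes then alternate activity/rest in
geometric bouts (mean bout 5 minutes) whose means are rescaled so the
stationary occupancy equals the target exactly — geometric bouts are
memoryless, so starting from the stationary category distribution makes
every minute's occupancy exact. Within a category, labels follow a fixed
mix in which running is rare. Cohorts are byte-reproducible from (config,
seed) via per-patient spawned RNG streams.

A clustered variant (`two_archetype_configs`) mixes fast improvers (stays
~1 week, high steep activity) with slow improvers (~4 weeks, low shallow
activity); it is the condition under which the hierarchy demonstrably beats
the mean-PTD baseline.

What the generator does **not** emulate: sensor physics and activity
recognition errors (state labels are taken as given), circadian structure,
missing days, weekday effects, or any dependence of discharge decisions on
activity (lengths of stay are drawn independently of the trend). Passing
tests therefore show the estimators recover the structure this generator
encodes, not that clinical recordings satisfy that structure. One known
consequence: Activity Time is a windowed maximum and hence upward-biased
and slightly compressed relative to the generative occupancy, so recovered
population intercepts sit above the generative intercept and slopes are
mildly attenuated; recovery tests check interval coverage of the slope, not
unbiasedness of the intercept.

## Problem sizes used in the shipped checks

Parameter-recovery runs use 100 replicate 23-patient cohorts; the
clustered-ward comparison uses 20 replicates of 8 patients (4 per
archetype) with the leave-one-out GP refit per fold (2 restarts, 100
optimizer iterations). Dense GP algebra throughout — at ≤ a few hundred
training days per fit, sparse approximations would add nothing.

## Known limitations

- The 78%-interval convention equates ±1 SD with 78% confidence; the
  Gaussian mass of that region is 68.3%. The convention is reproduced, not
  endorsed.
- Similarity borrows one training patient's deviation wholesale; a mixture
  or re-estimated deviation might predict better but would no longer pick
  "the most similar inpatient".
- The mean-PTD baseline's SD at a day with a single remaining training
  patient is 0, making its nominal bands degenerate late in long stays.
- Empirical-Bayes intervals ignore hyperparameter uncertainty; a fully
  Bayesian treatment (hyperpriors, MCMC) is out of scope.
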