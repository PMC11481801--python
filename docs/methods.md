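# Methods

This note documents the models, the numerical choices, and the places
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The adaptive engine

The engine holds one binary classifier per (exercise, difficulty level):
an L2-penalised logistic regression of success on the four standardised
cognitive-status subscores plus an intercept. Level selection returns the
hardest level whose predicted success probability is at least the cut-off
(default 0.65), falling back to the easiest level when none qualifies —
the most literal reading of "train at peak performance without being
excessively demanding". Each completed exercise is appended to its
classifier's data and that one classifier is refit; classifiers are fully
independent (no pooling across levels or exercises).

**Penalised fitting.** The ridge penalty (λ = 1 by default) applies to
the whole coefficient vector *including the intercept*. This is what
makes the engine's contracts simultaneously satisfiable: separable or
all-success training sets still yield finite coefficients, and a
balanced, feature-free prior yields exactly p = 0.5. Optimisation is
Newton's method on the strictly convex objective to a gradient
infinity-norm of 1e-8, started from zero — deterministic by
construction. Online refits warm-start from the previous optimum; since
the optimum is unique and the data sequence is identical, replaying a
training log from the same priors reproduces the engine state
bit-for-bit (asserted in the tests).

**Cold start.** Every classifier is born with 8 pseudo-observations on
the all-equal status direction around its level's design difficulty
`d`: mostly-success points above `d`, mostly-failure points below, with
*fractional* outcomes (equivalent to weighted success/failure pairs)
carrying a small linear correction chosen so that the penalised fit of
the pseudo-data reproduces the designed response curve
`p = logistic(mean status − d)` exactly. The cold-start policy therefore
selects the level the difficulty design intends for any status; real
results take over from there. A plain balanced-binary prior works too
but, under the intercept penalty, compresses all level curves toward
0.5 at status 0, which makes early selections too easy for able users
and too hard for weak ones.

**Difficulty ladder.** Levels are evenly spaced on the logit scale,
centred at 0 (the reference-population midpoint): 9 levels at 0.5-logit
spacing by default, spanning ±2.0. The granularity matters: with the
selection margin fixed by the cut-off (logit 0.65 ≈ 0.62), a ladder with
spacing s makes the de-novo selected level's true success probability
range over [0.65, logistic(0.62+s)]; 0.5 spacing keeps that inside
[0.65, 0.75]. The wide span keeps level 1 genuinely easy for the weakest
eligible users (ability ≈ −1.5 still succeeds at ~60% on level 1). Both
the count and spacing are configuration.

**Status input.** The classifiers consume the four digital-test-battery
subscores standardised to the reference population. In the simulated
trial the battery is re-administered monthly (measurement noise SD 0.25
per subscore). This cadence is part of the closed loop: levels can move
*down* from failures at the selected level, but an untried harder level
never receives data, so upward moves happen only when the status input
itself reflects the user's practice gains.

## The simulated learner and cohort

**Response model.** One-parameter logistic: an attempt at level `l` of
exercise `e` succeeds with probability
`logistic(w_e · ability − d_l)`, where `w_e` (nonnegative, summing to 1)
says how the exercise loads on the four trained functions. The ten
adaptive-programme exercises cover single-function, two-function and
evenly mixed weightings; the basic programme uses five of them, always at
level 1.

**Practice gains.** Per attempt and function `f`:

```
Δability_f = learning_rate_f · w_f · (1 − p_success) · max(0, 1 − gain_f / gain_max)
```

on success, and a fraction (default 0.25) of that on failure. The
`(1 − p_success)` surprise factor implements error-driven learning:
succeeding where success was near-certain teaches little, which is the
mechanistic reason adaptive training (held near p ≈ 0.7) outpaces
fixed-easy training (p ≈ 0.85) per attempt. The `(1 − gain/gain_max)`
factor saturates cumulative gains (default cap 0.9 logits per function).
Abilities never decrease. Basic-programme practice additionally
transfers at 60% (default) to the four trained functions — its simpler
quiz-style tasks lean on long-term memory, which the outcome instruments
do not credit.

**Outcome mapping.** MoCA = clamp(round(22 + 3 · mean ability + ε)),
ε ~ N(0, 1) for the parallel-form administrations; MMSE analogous with
anchor 27 and slope 2. The anchor/slope place the eligible population
(MoCA ≤ 24) around the study's observed baseline (≈ 22 ± 1.7) and make a
0.5-logit ability gain worth ≈ 1.5 MoCA points.

**Cohort marginals.** The generator targets the study sample: n = 89,
age 73.5 ± 7.3, 41.6% female, the four education levels, activity hours
(cognitive 19.6 ± 12.6, physical 10.5 ± 6.8, social 6.9 ± 4.3 per week),
vascular risk as Binomial(4, 0.275) (mean 1.1), a medication sum score
concentrated at 0, PHQ-9 3.1 ± 2.8, Charlson mostly 0. Nonnegative
quantities are drawn from zero-truncated normals moment-matched to the
target mean/SD, so sample marginals converge to the configured values
(tested at n = 10,000 within 2 Monte-Carlo SEs). Couples (default 10% of
participants) share a household, have correlated ages and usually
opposite sex. All randomness flows from one root seed through named
substreams (cohort, screening, randomisation, responses, measurement,
dropout), so a run is replayable from `(config, seed)`.

**Screening and randomisation.** The eligibility cascade is MoCA ≤ 24,
MMSE ≥ 24, PHQ-9 ≤ 12, technology check — in that order, the first
failure naming the exclusion reason. Randomisation is biased-coin
minimisation on sex (probability 0.8 for the imbalance-reducing arm, a
fair coin on ties; 1.0 gives deterministic minimisation), allocating
households as units so couples are always co-assigned.

**Usage schedule.** Monthly session counts interpolate the study's
observed first→last month means (adaptive 15.6 → 12.7, SD 6.9; basic
13.7 → 12.3, SD 6.0); session durations are ≈ 34 min (adaptive) and
≈ 38 min (basic) at ~3 minutes per task. A 10% uniform
missing-at-follow-up option emulates the observed drop-out.

## The statistics pipeline

Protocol order: outliers → imputation → covariate selection → ANCOVA →
transitions.

**Outlier rule.** Fences at Q1 − 1.5·IQR and Q3 + 1.5·IQR of the
follow-up change-score distribution (quartiles by linear interpolation —
the convention is stated in the audit output). Flagged cases are
*excluded* only when a clinical explanation is recorded; unexplained
statistical outliers stay in.

**EM imputation.** Missing follow-ups are imputed under a joint Gaussian
model by expectation–maximisation: E-step fills conditional expectations
(adding the conditional variance to the second-moment statistics),
M-step updates mean and covariance; iterate to parameter change < 1e-6
(500-iteration cap, non-convergence raises with the iteration trace).
Deterministic single imputation — no noise draw — and observed cells are
never modified. With missingness confined to one outcome this converges
to the complete-case regression prediction, which the tests assert to
1e-8 (running the solver at a tighter tolerance than the default
stopping rule).

**Covariate rule.** Keep candidates that are evidence-flagged *and* show
a group-difference effect size ≥ 0.1 (Cohen's d for continuous, Cramér's
V for binary); then enforce a pairwise |Pearson r| ≤ 0.80 ceiling,
dropping the smaller-effect member of an offending pair. Every decision
is logged. The published baseline table can be used directly as input;
by default its own printed effect-size column is honoured, because
recomputing from the rounded means/SDs moves two rows across the 0.1
floor (a documented rounding artefact).

**Mixed-model ANCOVA.** With exactly two occasions, the
repeated-measures GLM decomposes exactly into two orthogonal OLS parts:
the change scores carry the within-subject terms (time = intercept, all
time × covariate terms, time × group), the subject means carry the
between terms. Group is effect-coded ±0.5 and covariates are centred, so
each reported term is a single-df Type-III F test; partial η² =
SS_effect/(SS_effect + SS_error). Estimated marginal means per
group × time cell are evaluated at the covariate means with standard
errors combining the two parts' covariances (exact under the model's
equal-variance assumption). Singular designs raise with the aliased
columns named. The implementation is plain linear algebra; the test
suite proves term-by-term F/p agreement with an independent statsmodels
route to 1e-6 relative, 5% type-I calibration of the time × group test
over 1,000 null replicates, and recovery of an injected interaction
(contrast and partial η², the latter against its exact noncentral
expectation via the Poisson-mixture form) over 500 replicates.

**Transitions.** Fraction per arm with follow-up above the MCI cutoff
(24), compared by Pearson χ² without continuity correction — the
convention confirmed by re-deriving the published 4.55 (and 4.16 with
the outlier included) from the printed counts.

**UEQ.** Answers 1–7 recode to [−3, +3] (reversed items mirrored);
scales are item means, with a scale scored only if at least half its
items are answered. The item→scale map (6/4/4/4/4/4, 13 reverse-keyed)
and the benchmark thresholds ship as editable configuration; the
benchmark defaults are illustrative, category assignment is strict
("better than"), ties go to the lower band.

## What the synthetic data does and does not show

The generator emulates the study's *design*: its marginals, screening
cascade, usage pattern, missingness, and an adaptive-vs-basic contrast
whose direction is stable. It does not emulate item-level test content,
dropout mechanisms beyond uniform missingness, practice-independent
drift (ageing, day-to-day fluctuation), motivational feedback loops
between difficulty and adherence, or any neurobiological interpretation.
Passing tests therefore show that the engine and pipeline behave as
specified on learners *of this model class* — not that the real
intervention has a particular effect size; the study's subject-level
inferential results are not recomputable from published summaries, and
the package does not pretend otherwise.

## Replication scales and numerical conventions

Monte-Carlo studies run at sizes chosen to make their error bars small
relative to the bands they check: 1,000 replicates for type-I error,
500 for effect recovery, 200 participants for closed-loop tracking, and
200 paired trials of 16 participants per arm for the direction study
(the full 89-participant trial is simulated once, end to end, in the
acceptance script). Difficulty tracking is scored as the cumulative
success rate checked at each month-end after a 50-attempt burn-in
against [0.55, 0.85] — a per-attempt pathwise check on a cumulative
average is an extreme-value statistic that fails with non-trivial
probability even for a policy tracking perfectly at p ≈ 0.72, so the
monthly cadence is the honest reading of "stays within". Reported
statistics round to 2 decimals in reports; all comparisons in code use
full precision.

## Known limitations

* The learner's surprise-weighted gain model is the simplest mechanism
  that rewards individualised difficulty; real transfer and retention
  curves are richer, and the basic-programme transfer fraction (0.6) is
  a stipulated design constant, not an estimate.
* The engine can only raise a user's level through the status input;
  if the test battery were administered only at baseline, difficulty
  would ratchet down but not up. The monthly re-administration is a
  modelling choice about the deployed system's cadence.
* The ANCOVA is the exact two-occasion decomposition; it does not
  generalise to three or more occasions or non-compound-symmetric
  covariance structures.
* Single imputation understates outcome uncertainty relative to
  multiple imputation; it is used because it is the study's stated
  method.
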