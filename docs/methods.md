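# Methods

## Cohort model

The ward population is described entirely by a probability vector over
discretized LOS ∈ {1, 2, 3, 4} days (ceiling discretization upstream; the
"≥4 d" class is treated as exactly 4 days everywhere, including the
simulator's certainty that a fourth-day patient leaves overnight). The
default vector is the HiRID class mix 18,629/6,722/2,623/5,931
(probabilities 0.5494/0.1983/0.0774/0.1749). Patients are drawn i.i.d.
with replacement from this distribution rather than resampled from a finite
patient list: the class probabilities equal the dataset proportions, so all
expectations are identical, and the variance difference is negligible
against Monte Carlo error at R = 1000. Within-day admission times,
covariate-dependent LOS and readmissions are not modeled.

At ward initialization each patient's current stage (the index of the
currently-used prediction) is uniform over the predictions actually made
for their LOS, i.e. over {0, …, min(LOS, 3) − 1}. For LOS = 4 that support
is {0, 1, 2}: only three predictions exist, so the fourth treatment day
(stage 3) is reached only by time evolution, never drawn as an initial
state. The alternative — uniform over all four treatment days — is ruled
out numerically: the expectation recursion below then misses the observed
t = 0 KPI means.

## Prediction rules

* **Naive rule.** At each τ, the fixed majority class of
  P(LOS = τ+1 | LOS ≥ τ+1) vs its complement. Under the default mix this
  is (0, 1, 1). Ties, and empty risk sets, resolve to predicting 1, the
  capacity-conservative choice (the bed is kept); no tie occurs with the
  default counts.
* **Confusion emulator.** Given the truth label at τ, predict 1 with
  probability SE(τ) (truth 1) or 1 − SP(τ) (truth 0). The shipped
  reference specs are the out-of-fold SE/SP triples of the simple and
  complex logistic lasso and the XGB classifier fitted to HiRID, e.g. XGB:
  SE = (0.66, 0.73, 0.91), SP = (0.76, 0.62, 0.20). Draws are independent
  across patients and across τ. Cross-τ independence is a modeling choice,
  not a claim about real classifiers: because predictions never change a
  patient's true discharge day, every per-timepoint KPI expectation depends
  only on the per-τ marginals, so the coupling affects run-to-run variance
  only. The package includes a comonotone coupling (one latent uniform per
  patient thresholds every draw) and a test that the mean occupancy paths
  of the two couplings coincide within Monte Carlo error.
* **Table rule.** Real out-of-fold predictions keyed by (patient_id, τ);
  probabilities are binarized at a configurable threshold (default 0.5,
  inclusive ≥). With a `true_los` column the table doubles as a finite
  cohort the simulator resamples whole patients from.

## Ward dynamics

Daily event order: KPI count → free-bed forecast F̂ → actual departures
(stage = LOS − 1) → survivor stage/prediction update (fresh prediction
while stage ≤ 2; the τ=2 prediction is retained at stage 3, since only
predictions actually made are used) → admissions → t+1. Admissions are
A = max(0, F̂ + (B − Npat)): predicted discharges plus an occupancy
correction toward the B-bed target. The floor at zero is required because
planned admissions cannot be negative; it essentially never binds at the
default scale (F̂ ≥ ~30 in expectation). There is no hard cap at the
physical capacity: exceedance is the interesting failure mode and is
reported as P(Npat > reference_capacity), default 60.

RNG: one master seed; each (model, run) cell gets an independent
`SeedSequence(seed, spawn_key=(model_index, run))` substream, so results
are reproducible bitwise and appending a model never perturbs the others.

## Analytic oracle

`tests/analytic_oracle.py` propagates the *expected* occupancy measure over
(LOS, stage) cells through the same event order with no sampling, for any
rule with known marginals P(p̂=1 | LOS, τ). It is exact up to the
(negligible) admission floor and serves as the independent check that the
simulator's means are right — e.g. naive-rule expected occupancy
(50, 52.92, 60.26, 57.95, …) and initial Nov/Nun of 6.25/9.16. It lives in
the test tree, not the package, to keep it independent of the
implementation it audits.

## KPI analysis

Per-(model, t) means over runs; Npat five-number boxplot summaries with
1.5·IQR whiskers (the default convention of common plotting environments);
exceedance frequencies. Between-model occupancy differences are validated
with one-way ANOVA per timepoint and Tukey HSD post hoc (chosen as the
standard all-pairs companion of one-way ANOVA; scipy implementations).
Zero within-group variance with equal means — the t = 0 state, where every
run starts with exactly B patients — is reported as F = 0, p = 1. No
multiplicity correction is applied across timepoints.

## Evaluation stack

* AUROC: midrank (Mann–Whitney, ties ½) estimator with the DeLong
  variance for the 95% CI; written in-package because no installed library
  exposes DeLong, and verified in tests against brute-force pair counting.
* Proportion CIs (SE, SP, PRE, ACC): Wilson, via statsmodels. The CI
  methods are package choices; they make CI widths comparable, not
  bit-identical, to other software.
* NIR test: exact one-sided binomial tail P(X ≥ k | p = NIR), NIR being
  the majority-class share of the τ-specific risk set (0.55/0.56/0.69 under
  the default mix).
* Scaled Brier: 1 − BS/BS_ref with BS_ref = p̄(1 − p̄), the
  constant-prevalence reference.
* Decision curves: NB(pt) = TP/n − (FP/n)·pt/(1−pt), standardized by the
  prevalence; treat-all closed form π − (1−π)·pt/(1−pt); treat-none ≡ 0;
  pt = 1 excluded; the band [0.25, 0.75] is flagged as the operationally
  relevant threshold range.
* Calibration: equal-width bins on [0, 1], empty bins kept with count 0.

## Prediction cascade

Features per variable: admission-window (first 40 min) aggregates — mean,
max, or binary occurrence per a required `FeatureSpec` (default: mean for
continuous channels; binary is intended for treatment/dosing channels) —
plus OLS (intercept, slope) of value on time-in-hours over the τ-specific
informative horizon. Horizons are cumulative from admission and include
the admission window: 40 min at τ=0, 24 h at τ=1, 48 h at τ=2. Trend
fits with <2 points give missing values; zero time-variance gives
(mean, 0). Missing features are mean-imputed inside the learner pipeline.

Risk sets shrink over τ: features and labels at τ are built only for
patients with LOS ≥ τ+1. One random 5-fold partition (sizes within ±1) is
drawn once and shared by all per-τ models; each submodel scores only the
fold it never trained on, so every patient gets exactly one out-of-fold
probability. The learner is a pluggable contract; the reference is an
L1-penalized logistic regression (impute → standardize → lasso logit,
C = 1). Gradient boosting or anything else can be plugged in through the
same contract; its hyperparameters are out of scope here.

## Synthetic vitals generator

Per patient: LOS from the cohort distribution; per variable a latent line
value(t) = a + b·t + ε on the 5-min grid over min(LOS·24 h, 48 h), with
a ~ N(0, 1), b ~ N(0, 0.5²), ε ~ N(0, 0.5²), and b shifted by
`effect_size` for patients with LOS > 1. Defaults were chosen so that at a
large effect (≈3) the slope signal clearly dominates the OLS noise of the
40-min window while a zero effect is exactly null. Because the shift is a
*one-day-vs-longer* indicator, discrimination exists only at τ=0; within
the τ=1 and τ=2 risk sets the indicator is constant, which is precisely
the intended end-to-end check that signal placed in early hours does not
leak into later predictions. The generator emulates the shape of
high-resolution ICU data (fixed grid, per-patient horizons, multi-channel,
LOS-correlated drift) — not its clinical content, missingness patterns or
inter-channel correlation, so passing tests certify the pipeline's
plumbing and signal recovery, not clinical performance.

## Problem sizes used in tests

The full-scale experiment (4 models × R = 1000 × T = 10 × B = 50) is run
once in the acceptance tests and by `scripts/acceptance.py` (seconds).
Unit-level Monte Carlo checks use R = 300–600 with 3-standard-error
tolerances; emulator calibration uses 10⁵ draws; the cascade recovery
check uses 2000 patients × 3 variables. All tolerances are derived from
binomial/Monte Carlo standard errors, never tuned constants.

## Known limitations

Queueing of refused patients, transfers, triage, staffing and within-day
timing are outside the model. LOS beyond 4 days is truncated, which
overstates the predictability of long stays. The emulators reproduce
marginal confusion rates only; real classifiers' errors are correlated
with patient state across τ, which would change occupancy variance (not
means). The evaluation module is verified against oracles and synthetic
sets; reproducing a specific fitted model's metric values requires that
model's predictions as a table.
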