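# icusim

Monte Carlo ICU bed-capacity simulation for day-indexed length-of-stay
classifiers.

## The problem

Machine-learning models that predict ICU length of stay (LOS) are usually
judged by AUROC, sensitivity and the like. For the people who actually run
a ward, the relevant question is different: *if admissions were planned from
this model's predictions, how full would the unit be?* `icusim` answers that
question with a stochastic ward simulation, alongside the classical metrics
and decision-curve analysis, so a naive benchmark, a calibrated emulator of
a published classifier, or real out-of-fold model outputs can all be
compared by their operational effect.

The setting: LOS is discretized to whole days (ceiling) and capped at 4
("≥4 d" counts as 4). At prediction times τ ∈ {0, 1, 2} — roughly 40 min,
24 h and 48 h after admission — a binary prediction p̂(i, τ) is issued for
every patient i still in treatment (LOS ≥ τ+1):

    p̂(i, τ) = 0  if LOS = τ+1   (stay ends after day τ+1)
    p̂(i, τ) = 1  if LOS > τ+1   (stay continues)

The default cohort mix comes from the HiRID ICU dataset (Bern University
Hospital): 18,629 / 6,722 / 2,623 / 5,931 patients with LOS of 1 / 2 / 3 /
≥4 days.

## The ward model

A B-bed unit (default B = 50, on a physically 60-bed ward) is simulated
over T = 10 daily steps, R = 1000 independent runs per prediction model.
The ward starts full, each occupant at a uniformly drawn point of their
stay. Each day the engine

1. counts, among the Npat occupants, correct (Ncor), overestimating (Nov:
   predict stay, truth discharge) and underestimating (Nun: predict
   discharge, truth stay) currently-used predictions;
2. forecasts the beds freeing overnight, F̂, from those predictions
   (fourth-day patients free their bed with certainty — the 4-day cap is
   known);
3. discharges patients whose stay truly ends, advances the rest (updating
   their prediction while τ ≤ 2), and admits
   A = max(0, F̂ + (B − Npat)) new patients.

A perfect predictor holds Npat ≡ B exactly; systematic over- or
underestimation of LOS shows up as under- or overoccupancy. Prediction
models are interchangeable: the naive conditional-majority rule, a
stochastic emulator calibrated to a classifier's per-τ
sensitivity/specificity, or a lookup table of real out-of-fold predictions.

The package also ships the evaluation stack for prediction tables (AUROC
with DeLong CI, Wilson CIs for proportions, scaled Brier score, exact
binomial no-information-rate test, standardized-net-benefit decision
curves, calibration bins), per-timepoint ANOVA + Tukey HSD across models,
and a 5-fold out-of-sample prediction cascade with a synthetic vitals
generator to exercise it.

## Worked example

```python
from icusim import (
    HIRID_LOS_CLASS_COUNTS, REFERENCE_CONFUSION_SPECS, SimulationConfig,
    anova_per_timepoint, emulator_from_confusion, from_class_counts,
    kpi_wide_table, naive_from_distribution, run_experiment,
    summarize_trajectories, trajectories_to_frame,
)

dist = from_class_counts(HIRID_LOS_CLASS_COUNTS)
cfg = SimulationConfig(runs=1000, horizon=10, beds=50, seed=1)
models = [naive_from_distribution(dist)] + [
    emulator_from_confusion(REFERENCE_CONFUSION_SPECS[name], name=name)
    for name in ("LRs", "LRc", "XGB")
]
frame = trajectories_to_frame(run_experiment(cfg, dist, models))
wide = kpi_wide_table(summarize_trajectories(frame))
print(wide[wide.kpi == "Npat"].round(2).to_string(index=False))
print("ANOVA at t=6: F=%.1f, p=%.3g" % anova_per_timepoint(frame, 6))
```

prints (seed 1):

```
model  kpi  t=0   t=1   t=2   t=3   t=4   t=5   t=6   t=7   t=8   t=9  t=10
  LRc Npat 50.0 48.82 53.54 53.54 52.46 51.99 52.65 52.68 52.50 52.47 52.25
  LRs Npat 50.0 49.41 54.79 55.06 53.17 52.37 53.01 53.91 53.68 53.13 53.19
   NP Npat 50.0 53.23 60.14 57.78 53.06 52.31 55.42 56.91 55.82 54.13 54.57
  XGB Npat 50.0 45.23 49.11 49.83 49.03 49.08 48.98 49.25 49.18 49.35 48.92
ANOVA at t=6: F=431.3, p=9.7e-243
```

Reading: the naive rule lets occupancy overshoot the 50-bed target by up to
ten beds (it never anticipates discharges of multi-day patients); the
emulated logistic regressions run slightly over target, the gradient-
boosting emulator slightly under and closest to it — and the occupancy
differences between models are overwhelmingly significant from t = 1 on.
At t = 6 the naive ward exceeds the physical 60-bed capacity in 11.5% of
runs, the XGB-driven ward in none.

The same experiment from the shell:

```sh
icusim replicate-table2 --seed 1 --out-dir out/
icusim simulate --config examples/experiment.yaml --out-dir out/
icusim evaluate predictions.csv --out-dir eval/      # metrics + DCA + calibration
icusim cascade-demo --n-patients 2000 --seed 1       # synthetic vitals cascade
```

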