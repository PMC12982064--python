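# tygdyn

Dynamic triglyceride–glucose (TyG) exposure analysis for ICU cohorts:
trajectory phenotyping of serial TyG measurements, cumulative
supra-threshold burden, and day-7 time-stratified survival models — with a
synthetic-cohort generator so the whole pipeline is testable without access
to restricted ICU databases.

## The scientific problem

The TyG index, `TyG = ln(triglycerides [mg/dL] × glucose [mg/dL] / 2)`, is a
routine-laboratory surrogate of insulin resistance. In critically ill
patients with acute brain injury, a single admission TyG value conflates a
transient stress response with sustained metabolic dysregulation. This
package treats TyG as a *time-aware* exposure built from each patient's
serial ICU measurements (2–7 values, ordered chronologically):

1. **Trajectory phenotypes.** Within-database z-scored series are fitted
   with a latent class growth model — a finite mixture of polynomial mean
   curves `z_ij ~ N(x(t_j)'β_k, σ²)` with shared residual variance — by EM
   over K = 2..6 classes, selected by BIC subject to entropy and
   minimum-class-size floors. A three-class solution yields the phenotypes
   LSI (low–slightly increasing), MI (moderate–increasing), and PH
   (persistently high).
2. **Threshold-based mean burden (TBM).** For prespecified thresholds
   τ ∈ {8.0, 8.3, 8.5, 8.7, 9.0, 9.5}, the excess of the piecewise-linear
   TyG curve above τ is integrated exactly (zero-truncated, with
   crossing-point triangles) and divided by the number of observed
   intervals N − 1, giving columns `TBM8p0 … TBM9p5`.
3. **Time-stratified survival.** In-hospital mortality is modeled by Cox
   partial likelihood (Breslow ties, counting-process records, own
   Newton–Raphson engine). Because trajectory effects emerge only after the
   first week, follow-up is episode-split at day 7 and a single model with
   an interval-stratified baseline hazard estimates separate hazard ratios
   for days 0–7 and >7 days, across staged adjustment tiers (M1 unadjusted,
   M2 demographics/comorbidities, M3 plus severity/treatments).
   Schoenfeld-residual score tests (identity/rank/KM time transforms)
   diagnose proportional hazards; landmark Kaplan–Meier/log-rank and
   subgroup interaction scans complete the analysis.

The synthetic-data module is first-class: it generates cohorts with known
latent classes, known piecewise hazards (null class effects before day 7,
hazard ratios ≈ 1.5 after), class-dependent confounders, and discharge
censoring, so every estimator can be validated by parameter recovery.

## Worked example

```python
import tygdyn as tg

cohort = tg.generate_cohort(tg.SyntheticCohortConfig(n_patients=1500, seed=7))
series, _ = tg.build_series(cohort.measurements)
series, _ = tg.standardize_by_database(series)
sel = tg.select_classes(series, K_range=(2, 3, 4), seed=0, n_starts=2)
print(sel.model.K, sel.model.entropy, sel.model.mixing_weights)
```

prints

```
selected K = 3, entropy = 0.90
mixing weights: [0.62  0.233 0.147]
```

i.e. class enumeration recovers the three generating phenotypes at their
true prevalences (61.7/23.5/14.8%) with high assignment certainty. Fitting
the two-interval Cox model on a 4,000-patient cohort
(`examples/04_time_stratified_cox.py`) prints landmark log-rank contrasts

```
landmark log-rank, days 0-7: chi2=0.79, p=0.675
landmark log-rank, >7 days : chi2=41.58, p=9.4e-10
```

— no separation of the trajectory groups in the first week, strong ordered
divergence afterwards, which is the delayed-effect pattern the day-7
stratification is designed to capture.

Each script in `examples/` is a short narrative of one capability:
simulation, trajectory fitting, TBM, the two-interval Cox model, and the
full pipeline. A thin CLI mirrors the pipeline stages
(`tygdyn simulate | validate | trajectories | tbm | survival | all`).

## Layout

```
src/tygdyn/
  tyg.py        TyG computation, unit harmonization, series, z-scoring
  lcgm.py       growth-mixture EM, class enumeration, labeling
  tbm.py        zero-truncated trapezoidal burden + numeric oracle
  survival.py   Cox engine, Schoenfeld tests, KM/log-rank, episode split,
                two-interval models, subgroup scans, descriptives
  simulate.py   synthetic-cohort generator (the study-condition emulator)
  pipeline.py   orchestration, eligibility screens, report bundle
  cli.py        thin click wrapper
docs/methods.md   model, assumptions, parameter choices, limitations
```
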