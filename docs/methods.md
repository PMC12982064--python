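# Methods

This note documents the models implemented in `tygdyn`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## TyG exposure construction

`TyG = ln(TG[mg/dL] × GLU[mg/dL] / 2)` is computed after harmonizing units
to mg/dL (glucose ×18.016, triglycerides ×88.57 per mmol/L; molar masses
180.16 and an average triglyceride of 885.7 g/mol). Per patient, values are
ordered chronologically (by measurement time when available, otherwise by
measurement index; ties keep input order with a warning), truncated to the
first seven, and patients with fewer than two values are excluded and
logged. Rows with a missing component are dropped, never imputed.

Standardization pools **all** measurements within a database and z-scores
them with a single (mean, SD) pair per database, sample SD (`ddof=1`) by
default. Pooling across measurement indices, rather than per-index
standardization, keeps the growth curves on one common scale, which the
mixture model requires; the per-database constants are returned so new
patients and raw-scale plots can reuse them. Standardization is idempotent:
re-standardizing z-scores yields constants (0, 1) to machine precision.

## Latent class growth model

The trajectory model is a K-component mixture of polynomial mean curves
over the measurement index t = 1..7, centered at 4 for conditioning, with
within-class independent Gaussian residuals and a single shared variance
(classic group-based trajectory modeling; no random effects, no
covariate-dependent membership). Unbalanced series contribute only their
observed indices to the likelihood. Calendar-time fitting is available via
`time_axis="calendar"`.

Fitting is EM: the E-step computes responsibilities in log space
(`logsumexp`), the M-step solves per-class weighted least squares and a
pooled variance update. The observed-data log-likelihood is recorded every
iteration and is non-decreasing by construction (asserted in tests).
Convergence is |Δloglik| < 1e-6 or 500 iterations. Initialization is
k-means on per-patient (mean, OLS slope) summaries; further starts
alternate k-means reseedings with Dirichlet-random responsibilities, and
the best final log-likelihood wins. A start whose smallest mixing weight
falls below 1/n is aborted as a class collapse; if every start collapses
(typical when K exceeds the number of real clusters), the best pre-collapse
state is returned flagged `converged=False` so class enumeration can still
compare it by BIC.

Polynomial degree defaults to 2 (degree 1 available): a quadratic can
represent the slowly declining persistently-high shape as well as the
increasing shapes. Model selection fits K = 2..6 and minimizes BIC among
candidates with relative entropy ≥ 0.5 and minimum modal class fraction
≥ 0.05 (both configurable operationalizations of "acceptable class
sizes"); with no admissible candidate the best-BIC model is returned with a
`constraints_unmet` flag. Information criteria: AIC = −2ℓ + 2p,
BIC = −2ℓ + p·ln n, and the sample-size–adjusted BIC with
ln((n + 2)/24) in place of ln n, with p = (K − 1) + K(degree + 1) + 1.
Relative entropy is 1 − Σ(−p·ln p)/(n·ln K), defined as 1 for K = 1.

Classes are stored in canonical order (ascending mean fitted level over
indices 1..7) and labels are attached by rank at assignment time, so all
reported quantities are invariant to label switching. For K = 3 the rank
labels are the phenotype names LSI < MI < PH; otherwise C1..CK.

## Threshold-based mean burden

For threshold τ, each adjacent pair of measurements defines a linear
segment of excess e(t) = L(t) − τ; the burden integrates max(e, 0)
exactly: a fully supra-threshold segment contributes the trapezoid
(e₁+e₂)/2, a crossing segment the partial triangle e₊²/(2|e₁−e₂|), a
sub-threshold segment zero. The "clipped-endpoint" trapezoid — which
over-counts crossing segments — is available as a sensitivity variant
(`truncation="clipped"`). The default axis is the measurement index with
unit spacing, so dividing the summed area by N − 1 makes TBM a
per-interval mean, exactly matching the (N − 1) normalizer; a calendar
axis weights segments by elapsed days and divides by the span instead.
TBM is computed on raw TyG values because the thresholds live on the raw
scale. TBM is non-negative, translation-equivariant
(values + c, τ + c), continuous and non-increasing in τ, and zero iff no
measurement exceeds τ — all property-tested, plus equivalence with a
dense-grid numeric oracle to 1e-6.

## Survival machinery

The Cox engine maximizes the partial likelihood on counting-process
(start, stop] records by Newton–Raphson with step-halving, convergence on
step size < 1e-9. Risk sets under delayed entry are evaluated with two
suffix-cumulative-sum passes (one sorted by stop, one by start), so each
iteration is O(n·p²). Ties: Breslow by default (the simplest consistent
choice); Efron is available behind `ties="efron"`. Covariates are centered
internally (exactly cancels in the partial likelihood) to avoid overflow.
Zero-variance covariates are reported with coefficient 0, hazard ratio 1
and infinite SE rather than failing; monotone likelihoods (separation) are
detected by runaway coefficients, capped at |15| and flagged. Standard
errors come from the inverse observed information; CIs are Wald on the
log scale at 95%. The score test at β = 0 is exposed and equals the
log-rank chi-square for a single binary covariate without ties (asserted
to 1e-8).

The proportional-hazards diagnostic is a score test for a time-varying
coefficient β(t) = β + θ·g(t) evaluated at θ = 0: with centered
transformed event times c, Schoenfeld residuals r_k and per-event
risk-set covariances V_k, the score u = Σ c_k r_k has variance
D = Σ c_k² V_k − (Σ c_k V_k) I⁻¹ (Σ c_k V_k)′, where the subtraction
accounts for β̂ being estimated. Per-covariate, block (e.g. the exposure
dummies only), and global chi-square statistics are reported. The default
transform is the pooled left-continuous Kaplan–Meier of follow-up
(delayed-entry aware), matching the convention of the survival analysis
software the original analyses were run in; identity and rank transforms
are options. Null calibration of the default was verified by simulation
(rejection 0.050 at α = 0.05 over 1,000 replicates).

Episode splitting rewrites follow-up as (0, 7] and (7, stop] rows with the
closed-right convention — a death at exactly day 7 is an early-interval
death — conserving person-time exactly and leaving time-fixed coefficients
unchanged (asserted to 1e-8). The two-interval exposure model fits one Cox
model on split records with the baseline hazard stratified by interval and
one exposure coefficient per interval (adjustment covariates keep a single
time-fixed coefficient): equivalent to separate per-interval fits when
everything interacts, more stable otherwise. Categorical exposures use LSI
as the reference when present; numeric exposures (TBM columns) are modeled
per 1-unit increase. Subgroup scans refit the model within each level
(levels without events, or with degenerate fits, are skipped with a
warning) and obtain interaction p-values from a joint Wald test on
exposure × interval × subgroup product terms in the pooled model.
Landmark Kaplan–Meier/log-rank analyses condition on being at risk at the
window start and censor at its end; the multi-group log-rank uses the
hypergeometric variance with G − 1 degrees of freedom.

## Synthetic cohort generator

The generator defines the study conditions all recovery tests run under:

* **Classes.** Three latent classes with proportions
  (0.618, 0.235, 0.148)/1.001 — normalized because the printed percentages
  round to 100.1% — assigned independently per patient.
* **Trajectories.** Raw-scale class mean curves over measurement index
  j − 1: LSI 8.2 + 0.04·t, MI 8.8 + 0.10·t, PH 9.6 − 0.05·t (low–slightly
  increasing, moderate–increasing, persistently high with MI and PH
  converging at later measurements), residual SD 0.35. Measurement count
  uniform on 2..7, one measurement per day from day 0. Per-database
  additive offsets (default 0) exercise the standardization code.
* **Laboratory pairs.** Each TyG value is back-solved into (TG, GLU) by
  splitting the log budget L = TyG + ln 2 with a per-patient ratio drawn
  Uniform(0.4, 0.6), keeping both components physiologic and making
  `ln(TG·GLU/2)` hold row-exactly.
* **Survival.** Piecewise-exponential death hazard: 0.005/day on (0, 7]
  and 0.009/day after, class log-HRs (0, 0, 0) early and
  (0, ln 1.48, ln 1.51) late, covariate effects in both intervals;
  discharge is a competing exponential draw at 0.05/day that censors, with
  administrative censoring at 60 days. All clocks are drawn conditional on
  surviving a 1-day eligibility floor (exact, by memorylessness), because
  the analysis cohort excludes sub-24-hour stays. These rates were chosen
  once to match the published cohort's marginal statistics (≈12.5%
  in-hospital mortality before conditioning, median follow-up ≈ 13 days);
  after eligibility conditioning realized mortality is ≈ 15%.
* **Covariates.** Age ~ N(58, 14²); male 58.7%; diabetes, hypertension and
  mechanical ventilation Bernoulli with class-increasing prevalences
  (e.g. diabetes 8.6/27.1/39.1%); SOFA ~ N(class mean 3.8–4.8, 2.2),
  clipped at 0. Each has a fixed log-HR (age 0.02/yr, male 0.10, DM 0.30,
  HTN 0.15, MV 0.50, SOFA 0.08/point) and is centered at its marginal mean
  in the linear predictor, so the baseline rates remain typical-patient
  rates and the class gradients create genuine confounding for the
  M1→M3 adjustment tiers. Trauma (22.1%) and craniotomy (40.9%) are pure
  subgroup labels with null effects.
* **Reproducibility.** One seed feeds named `SeedSequence` substreams
  (class, database, trajectory, covariates, survival), so changing one
  component's parameters does not perturb the other draws.
* **Truth table.** True class plus TBM at every configured threshold,
  computed by an algebraically independent clipped-square identity, giving
  downstream tests an exact cross-route oracle.

What the generator does **not** emulate: missing data (the analysis drops,
never imputes), dependence between measurement count and severity,
laboratory drift beyond an additive per-database offset, competing-risk
structure beyond discharge-as-censoring, and any direct hazard effect of
TBM (its association arises through the classes). Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
data-generating process, not robustness to real-data pathologies.

## Statistical power of the PH contrast

With the cohort calibrated to the published marginals (≈15% mortality at
n = 4,000, about one fifth of deaths in the first week) and a late hazard
ratio of ≈1.5, the Schoenfeld score test applied to the unstratified
trajectory model has a noncentrality of only ≈4–5 (2 df), i.e. power
≈0.25–0.45 depending on transform and adjustment — detection of the PH
violation at these effect sizes requires roughly three times as many
events. The per-interval estimates themselves are unbiased with nominal
CI coverage (verified by simulation), and the landmark log-rank contrast
shows the delayed-divergence pattern clearly; the PH test is the
low-powered element at this scale.

## Pipeline conventions

Eligibility screens run in a fixed order (short stay < 1 day, missing
outcome, fewer than two measurements) with first-rule-wins accounting, so
excluded + analyzed = input exactly. All timestamps are float days from
ICU admission. Every random stage derives its seed from the global config
seed; identical config + seed produce byte-identical output bundles
(asserted). A 9:1 train/validation split utility exists for external use
but the statistical pipeline never uses it. Stage failures abort with a
stage-named error and leave a `FAILED` marker beside any partial outputs.
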