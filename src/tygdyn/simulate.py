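"""Synthetic ICU cohorts with latent TyG trajectory classes and
time-varying survival effects.

The generator emulates the study conditions the analysis assumes, so every
downstream stage is testable without access to restricted ICU databases:

* each patient belongs to one of K latent classes (default three, with
  proportions 61.8/23.5/14.8% normalized to sum to one);
* the patient's serial TyG values follow the class polynomial mean
  trajectory over measurement index plus Gaussian within-patient noise;
* triglyceride/glucose pairs are back-solved from each TyG value, so the
  identity ``tyg = ln(TG * GLU / 2)`` holds row-exactly and unit
  harmonization code is exercised;
* in-hospital death times come from a piecewise-exponential hazard with
  separate baseline rates on (0, 7] and (7, t_max] days; trajectory-class
  effects are null before day 7 and elevated (HR about 1.5) after it;
* discharge is a competing exponential draw that censors (event = 0), with
  administrative censoring at ``t_max``.

Covariates (age, sex, diabetes, hypertension, mechanical ventilation,
SOFA) have class-dependent distributions so the staged adjustment models
face realistic confounding.  A single seed drives named substreams, so
changing one component's parameters does not perturb the others' draws.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSpec",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "back_solve_components",
    "death_survivor",
    "default_covariates",
]

_LN2 = math.log(2.0)


@dataclass
class CovariateSpec:
    """One adjustment covariate of the generative model.

    ``params`` is either a single parameter set (shared across classes) or
    one per class: ``(loc, scale)`` for ``normal``, a probability for
    ``bernoulli``.  ``log_hr`` multiplies the hazard in both intervals;
    the covariate is centered at ``center`` in the linear predictor so the
    baseline rates stay typical-patient rates.
    """

    name: str
    dist: str  # "normal" | "bernoulli"
    params: tuple
    log_hr: float = 0.0
    center: float = 0.0
    clip_min: float | None = None

    def per_class(self, K: int):
        p = self.params
        if self.dist == "normal":
            if np.ndim(p[0]) == 0:
                return [tuple(p)] * K
            return [tuple(q) for q in p]
        if np.ndim(p) == 0:
            return [float(p)] * K
        return [float(q) for q in p]


def default_covariates() -> list[CovariateSpec]:
    """Covariate mix echoing the clinical gradient across trajectory
    classes (more diabetes, hypertension, ventilation and higher severity
    in the higher-TyG classes); trauma and craniotomy are pure subgroup
    labels with no hazard effect."""
    return [
        CovariateSpec("age", "normal", (58.0, 14.0), log_hr=0.02, center=58.0),
        CovariateSpec("male", "bernoulli", 0.587, log_hr=0.10, center=0.587),
        CovariateSpec("dm", "bernoulli", (0.086, 0.271, 0.391), log_hr=0.30, center=0.175),
        CovariateSpec("htn", "bernoulli", (0.568, 0.693, 0.714), log_hr=0.15, center=0.62),
        CovariateSpec("mv", "bernoulli", (0.415, 0.598, 0.661), log_hr=0.50, center=0.494),
        CovariateSpec(
            "sofa", "normal", ((3.8, 2.2), (4.3, 2.2), (4.8, 2.2)),
            log_hr=0.08, center=4.1, clip_min=0.0,
        ),
        CovariateSpec("trauma", "bernoulli", 0.221, log_hr=0.0, center=0.221),
        CovariateSpec("craniotomy", "bernoulli", 0.409, log_hr=0.0, center=0.409),
    ]


def _normalized(p):
    arr = np.asarray(p, dtype=float)
    return tuple(arr / arr.sum())


@dataclass
class SyntheticCohortConfig:
    """Full generative parameterization of a synthetic cohort."""

    n_patients: int = 4000
    class_proportions: tuple = field(default_factory=lambda: _normalized((0.618, 0.235, 0.148)))
    # per-class (intercept, slope[, quadratic]) on the raw TyG scale over
    # measurement index - 1 (so the intercept is the first-measurement mean)
    class_growth_coeffs: tuple = ((8.2, 0.04), (8.8, 0.10), (9.6, -0.05))
    residual_sd: float = 0.35
    # probabilities of 2..7 measurements per patient
    n_measurements_probs: tuple = (1 / 6,) * 6
    measurement_gap_days: float = 1.0
    # piecewise-exponential death rates (events/day) on (0, cutpoint] and beyond
    baseline_hazard_rates: tuple = (0.005, 0.009)
    class_log_hr_early: tuple = (0.0, 0.0, 0.0)
    class_log_hr_late: tuple = (0.0, math.log(1.48), math.log(1.51))
    covariate_spec: list = field(default_factory=default_covariates)
    discharge_rate: float = 0.05
    t_max: float = 60.0
    cutpoint_days: float = 7.0
    # cohort eligibility requires an ICU stay of at least this long, so
    # event/discharge clocks are drawn conditional on reaching it
    # (memorylessness makes the conditional draw exact)
    eligibility_min_stay_days: float = 1.0
    tbm_thresholds: tuple = (8.0, 8.3, 8.5, 8.7, 9.0, 9.5)
    database_ids: tuple = ("NSICU", "MIMIC", "EICU")
    database_probs: tuple = field(default_factory=lambda: _normalized((3819, 329, 612)))
    database_offsets: tuple = (0.0, 0.0, 0.0)
    split_ratio_range: tuple = (0.4, 0.6)
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.class_proportions)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        p = np.asarray(self.class_proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-12 or np.any(p <= 0):
            raise ValueError("class_proportions must be positive and sum to 1 within 1e-12")
        K = self.K
        for name in ("class_growth_coeffs", "class_log_hr_early", "class_log_hr_late"):
            if len(getattr(self, name)) != K:
                raise ValueError(f"{name} must have one entry per class (K={K})")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        rates = list(self.baseline_hazard_rates) + [self.discharge_rate]
        if any(r <= 0 for r in rates):
            raise ValueError("all hazard rates must be > 0")
        q = np.asarray(self.n_measurements_probs, dtype=float)
        if len(q) != 6 or np.any(q < 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("n_measurements_probs must be 6 probabilities over counts 2..7")
        if not (len(self.database_ids) == len(self.database_probs) == len(self.database_offsets)):
            raise ValueError("database ids/probs/offsets must align")
        lo, hi = self.split_ratio_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("split_ratio_range must lie inside (0, 1)")

    # -- JSON round-trip ----------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["covariate_spec"] = [dataclasses.asdict(c) for c in self.covariate_spec]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticCohortConfig":
        d = json.loads(text)
        d["covariate_spec"] = [
            CovariateSpec(**{**c, "params": _tuplify(c["params"])})
            for c in d.get("covariate_spec", [])
        ]
        for key, val in d.items():
            if key != "covariate_spec" and isinstance(val, list):
                d[key] = _tuplify(val)
        return cls(**d)


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


@dataclass
class SyntheticCohort:
    """Long measurements table, per-patient outcomes, and the truth table
    (latent class and independently computed TBM values)."""

    measurements: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig

    def write_csv(self, outdir) -> dict:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("measurements", self.measurements),
            ("outcomes", self.outcomes),
            ("truth", self.truth),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        (out / "cohort_config.json").write_text(self.config.to_json())
        paths["config"] = str(out / "cohort_config.json")
        return paths


def back_solve_components(tyg_target: float, split_ratio: float):
    """Invert the TyG formula into a (TG, GLU) pair in mg/dL.

    One equation, two unknowns: the log budget ``L = tyg + ln 2`` is split
    as ``ln TG = r * L`` and ``ln GLU = (1 - r) * L``.  Vectorized.
    """
    r = np.asarray(split_ratio, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise ValueError("split_ratio must lie strictly inside (0, 1)")
    L = np.asarray(tyg_target, dtype=float) + _LN2
    tg = np.exp(r * L)
    glu = np.exp((1.0 - r) * L)
    if np.ndim(tyg_target) == 0 and np.ndim(split_ratio) == 0:
        return float(tg), float(glu)
    return tg, glu


def _draw_piecewise_death(rng, rate_early, rate_late, cut, t0=0.0):
    """Inverse-CDF draw from a two-piece exponential hazard, conditional on
    survival to ``t0`` (vectorized; exact by memorylessness)."""
    H = -np.log(rng.uniform(size=len(rate_early)))
    h_cut = rate_early * max(cut - t0, 0.0)
    early = H <= h_cut
    with np.errstate(divide="ignore"):
        t = np.where(early, t0 + H / rate_early, max(cut, t0) + (H - h_cut) / rate_late)
    return t


def death_survivor(config: SyntheticCohortConfig, t, class_idx: int = 0):
    """Closed-form death survivor function for one class at null covariate
    effects, conditional on surviving the eligibility floor; the simulation
    oracle for KM checks."""
    lam1, lam2 = config.baseline_hazard_rates
    lam1 = lam1 * math.exp(config.class_log_hr_early[class_idx])
    lam2 = lam2 * math.exp(config.class_log_hr_late[class_idx])
    cut = config.cutpoint_days
    t0 = config.eligibility_min_stay_days
    t = np.asarray(t, dtype=float)

    def cumhaz(x):
        return np.where(x <= cut, lam1 * x, lam1 * cut + lam2 * (x - cut))

    return np.where(t <= t0, 1.0, np.exp(-(cumhaz(t) - cumhaz(t0))))


def _truth_tbm(values: np.ndarray, threshold: float) -> float:
    """Independent exact supra-threshold area per interval, via the
    clipped-square algebraic identity (distinct from the crossing-point
    geometry used by the analysis route)."""
    e1 = values[:-1] - threshold
    e2 = values[1:] - threshold
    flat = np.isclose(e1, e2)
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = (np.clip(e1, 0, None) ** 2 - np.clip(e2, 0, None) ** 2) / (2.0 * (e1 - e2))
    seg = np.where(flat, np.clip(e1, 0, None), seg)
    return float(seg.sum() / len(e1))


def generate_cohort(config: SyntheticCohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort; deterministic given the seed."""
    if config is None:
        config = SyntheticCohortConfig()
    config.validate()
    n = config.n_patients
    K = config.K

    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["class", "database", "trajectory", "covariates", "survival"], root.spawn(5)
        )
    }

    cls = streams["class"].choice(K, size=n, p=np.asarray(config.class_proportions))
    db_idx = streams["database"].choice(
        len(config.database_ids), size=n, p=np.asarray(config.database_probs)
    )
    pids = np.array([f"P{i + 1:06d}" for i in range(n)])

    # --- serial TyG values -------------------------------------------------
    rng_t = streams["trajectory"]
    n_meas = rng_t.choice(np.arange(2, 8), size=n, p=np.asarray(config.n_measurements_probs))
    split_r = rng_t.uniform(*config.split_ratio_range, size=n)
    total_obs = int(n_meas.sum())
    noise = rng_t.normal(0.0, config.residual_sd, size=total_obs)

    subj = np.repeat(np.arange(n), n_meas)
    idx1 = np.concatenate([np.arange(1, m + 1) for m in n_meas])
    t_axis = (idx1 - 1).astype(float)
    coeffs = [np.asarray(c, dtype=float) for c in config.class_growth_coeffs]
    mean_tyg = np.empty(total_obs)
    for k in range(K):
        mask = cls[subj] == k
        c = coeffs[k]
        mean_tyg[mask] = sum(c[d] * t_axis[mask] ** d for d in range(len(c)))
    offsets = np.asarray(config.database_offsets, dtype=float)[db_idx]
    tyg = mean_tyg + offsets[subj] + noise
    tg, glu = back_solve_components(tyg, split_r[subj])

    measurements = pd.DataFrame(
        {
            "patient_id": pids[subj],
            "database_id": np.asarray(config.database_ids)[db_idx][subj],
            "meas_index": idx1,
            "meas_time_days": t_axis * config.measurement_gap_days,
            "triglycerides_mgdl": tg,
            "glucose_mgdl": glu,
            "tyg_raw": tyg,
        }
    )

    # --- covariates --------------------------------------------------------
    rng_c = streams["covariates"]
    cov_cols = {}
    lp = np.zeros(n)
    for spec in config.covariate_spec:
        per = spec.per_class(K)
        if spec.dist == "normal":
            loc = np.array([per[k][0] for k in range(K)])[cls]
            scale = np.array([per[k][1] for k in range(K)])[cls]
            x = rng_c.normal(loc, scale)
            if spec.clip_min is not None:
                x = np.clip(x, spec.clip_min, None)
        elif spec.dist == "bernoulli":
            p = np.array(per)[cls]
            x = (rng_c.uniform(size=n) < p).astype(float)
        else:
            raise ValueError(f"unknown covariate dist {spec.dist!r}")
        cov_cols[spec.name] = x
        lp += spec.log_hr * (x - spec.center)

    # --- survival ----------------------------------------------------------
    rng_s = streams["survival"]
    lam1, lam2 = config.baseline_hazard_rates
    rate_early = lam1 * np.exp(np.asarray(config.class_log_hr_early)[cls] + lp)
    rate_late = lam2 * np.exp(np.asarray(config.class_log_hr_late)[cls] + lp)
    t0 = config.eligibility_min_stay_days
    t_death = _draw_piecewise_death(
        rng_s, rate_early, rate_late, config.cutpoint_days, t0=t0
    )
    t_disch = t0 + rng_s.exponential(1.0 / config.discharge_rate, size=n)
    followup = np.minimum(np.minimum(t_death, t_disch), config.t_max)
    event = (t_death < np.minimum(t_disch, config.t_max)).astype(int)

    outcomes = pd.DataFrame(
        {
            "patient_id": pids,
            "database_id": np.asarray(config.database_ids)[db_idx],
            "followup_days": followup,
            "event": event,
            **cov_cols,
        }
    )
    outcomes["age_ge65"] = (outcomes["age"] >= 65).astype(int)

    # --- truth table -------------------------------------------------------
    from .tbm import threshold_label  # local import to avoid cycles

    truth_cols = {"patient_id": pids, "true_class": cls}
    obs_split = np.cumsum(n_meas)[:-1]
    per_patient_values = np.split(tyg, obs_split)
    for tau in config.tbm_thresholds:
        truth_cols[threshold_label(tau)] = [
            _truth_tbm(v, tau) for v in per_patient_values
        ]
    truth = pd.DataFrame(truth_cols)

    return SyntheticCohort(
        measurements=measurements, outcomes=outcomes, truth=truth, config=config
    )
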