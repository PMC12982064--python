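"""End-to-end analysis pipeline.

Runs, in order: input validation and eligibility screening, TyG series
construction and within-database standardization, trajectory modeling with
class enumeration, TBM computation at the prespecified thresholds,
descriptive comparison across classes, staged time-stratified Cox models
for trajectory and TBM exposures, subgroup scans, and proportional-hazards
diagnostics.  Every stage writes a plain-text artifact into the output
directory and the run is byte-reproducible given config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lcgm, survival, tyg
from .tbm import tbm_family, threshold_label
from .simulate import SyntheticCohort, SyntheticCohortConfig, generate_cohort

__all__ = [
    "AnalysisConfig",
    "PipelineResult",
    "run_pipeline",
    "validate_inputs",
    "ValidationReport",
    "train_validation_split",
]

logger = logging.getLogger("tygdyn.pipeline")

REQUIRED_MEASUREMENT_COLS = ("patient_id", "triglycerides_mgdl", "glucose_mgdl")
REQUIRED_OUTCOME_COLS = ("patient_id", "followup_days", "event")

DEFAULT_TIERS = {
    "M1": [],
    "M2": ["age", "male", "dm", "htn"],
    "M3": ["age", "male", "dm", "htn", "sofa", "mv"],
}
DEFAULT_SUBGROUPS = ("age_ge65", "trauma", "htn", "craniotomy", "database_id")


@dataclass
class AnalysisConfig:
    """JSON-serializable configuration of a full pipeline run."""

    synthetic: SyntheticCohortConfig | None = field(default_factory=SyntheticCohortConfig)
    measurements_path: str | None = None
    outcomes_path: str | None = None
    min_stay_days: float = 1.0
    min_measurements: int = 2
    max_measurements: int = 7
    standardize_ddof: int = 1
    k_range: tuple = (2, 3, 4, 5, 6)
    degree: int = 2
    n_starts: int = 3
    entropy_floor: float = 0.5
    min_class_floor: float = 0.05
    tbm_thresholds: tuple = (8.0, 8.3, 8.5, 8.7, 9.0, 9.5)
    tbm_axis: str = "index"
    cutpoint_days: float = 7.0
    tiers: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TIERS.items()})
    subgroups: tuple = DEFAULT_SUBGROUPS
    ties: str = "breslow"
    descriptive_continuous: tuple = ("age", "sofa")
    descriptive_binary: tuple = ("male", "dm", "htn", "mv", "trauma", "craniotomy")
    outdir: str = "tygdyn_output"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = json.loads(self.synthetic.to_json())
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        d = json.loads(text)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticCohortConfig.from_json(json.dumps(d["synthetic"]))
        for key, val in d.items():
            if key not in ("synthetic", "tiers") and isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where it is written
        d = json.loads(self.to_json())
        d.pop("outdir", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ValidationReport:
    counts: pd.DataFrame  # rule, n_excluded (in application order)
    eligible_measurements: pd.DataFrame
    eligible_outcomes: pd.DataFrame
    n_input: int
    n_analyzed: int


def validate_inputs(
    measurements: pd.DataFrame,
    outcomes: pd.DataFrame,
    min_stay_days: float = 1.0,
    min_measurements: int = 2,
) -> ValidationReport:
    """Apply the eligibility screens in their stated order.

    Rules, applied sequentially so each patient is counted against the
    first rule that excludes them: ``short_stay`` (follow-up below the
    minimum stay), ``missing_outcome`` (missing event flag or follow-up),
    ``insufficient_measurements`` (fewer than two TyG rows).  The counts
    plus the analyzed total always equal the number of input patients.
    """
    for col in REQUIRED_OUTCOME_COLS:
        if col not in outcomes.columns:
            raise ValueError(f"outcomes table is missing required column {col!r}")
    if "patient_id" not in measurements.columns:
        raise ValueError("measurements table is missing required column 'patient_id'")
    if "tyg_raw" not in measurements.columns:
        for col in ("triglycerides_mgdl", "glucose_mgdl"):
            if col not in measurements.columns:
                raise ValueError(f"measurements table is missing required column {col!r}")

    out = outcomes.copy()
    ids = out["patient_id"]
    if ids.duplicated().any():
        if "database_id" not in out.columns:
            raise ValueError(
                "duplicate patient ids without a database_id column to disambiguate"
            )
        raise ValueError("duplicate patient ids in outcomes table")
    n_input = len(out)
    excluded: dict[str, int] = {}
    remaining = out

    missing = remaining["followup_days"].isna() | remaining["event"].isna()
    short = (~missing) & (remaining["followup_days"] < min_stay_days)
    excluded["short_stay"] = int(short.sum())
    remaining = remaining.loc[~short]
    missing = remaining["followup_days"].isna() | remaining["event"].isna()
    excluded["missing_outcome"] = int(missing.sum())
    remaining = remaining.loc[~missing]

    meas_counts = measurements.groupby("patient_id").size()
    n_meas = remaining["patient_id"].map(meas_counts).fillna(0)
    few = n_meas < min_measurements
    excluded["insufficient_measurements"] = int(few.sum())
    remaining = remaining.loc[~few]

    counts = pd.DataFrame(
        {"rule": list(excluded), "n_excluded": list(excluded.values())}
    )
    eligible_meas = measurements.loc[
        measurements["patient_id"].isin(remaining["patient_id"])
    ]
    return ValidationReport(
        counts=counts,
        eligible_measurements=eligible_meas,
        eligible_outcomes=remaining,
        n_input=n_input,
        n_analyzed=len(remaining),
    )


def train_validation_split(outcomes: pd.DataFrame, frac_train: float = 0.9, seed: int = 0):
    """Utility 9:1 patient-level split (not used by the statistical
    pipeline itself)."""
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    order = rng.permutation(n)
    n_train = int(round(frac_train * n))
    return (
        outcomes.iloc[order[:n_train]].reset_index(drop=True),
        outcomes.iloc[order[n_train:]].reset_index(drop=True),
    )


@dataclass
class PipelineResult:
    outdir: Path
    paths: dict
    selection: lcgm.SelectionResult
    assignments: pd.DataFrame
    tbm_table: pd.DataFrame
    hr_table: pd.DataFrame
    subgroup_result: survival.SubgroupScanResult
    ph_diagnostics: dict
    analysis_frame: pd.DataFrame
    manifest: dict


def _stage(name, **info):
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: AnalysisConfig, outdir: str | None = None) -> PipelineResult:
    """Run the full analysis and write the report bundle.

    Identical config + seed produce byte-identical outputs.  Any stage
    failure aborts with a stage-named error; partial outputs already
    written are retained alongside a FAILED marker file.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    stage = "setup"
    try:
        # --- input acquisition -------------------------------------------
        stage = "input"
        if config.measurements_path and config.outcomes_path:
            measurements = pd.read_csv(config.measurements_path)
            outcomes = pd.read_csv(config.outcomes_path)
            truth = None
        elif config.synthetic is not None:
            syn = dataclasses.replace(config.synthetic, seed=config.seed)
            cohort = generate_cohort(syn)
            measurements, outcomes, truth = cohort.measurements, cohort.outcomes, cohort.truth
        else:
            raise ValueError("config needs input paths or a synthetic block")
        _stage("input", patients=len(outcomes), rows=len(measurements))

        # --- eligibility ---------------------------------------------------
        stage = "validate"
        report = validate_inputs(
            measurements, outcomes, config.min_stay_days, config.min_measurements
        )
        report.counts.to_csv(out / "exclusions_eligibility.csv", index=False)
        paths["exclusions_eligibility"] = str(out / "exclusions_eligibility.csv")
        _stage("validate", analyzed=report.n_analyzed, excluded=report.n_input - report.n_analyzed)

        # --- series + standardization -------------------------------------
        stage = "series"
        series, series_excl = tyg.build_series(
            report.eligible_measurements,
            min_measurements=config.min_measurements,
            max_measurements=config.max_measurements,
        )
        series_excl.to_csv(out / "exclusions_series.csv", index=False)
        paths["exclusions_series"] = str(out / "exclusions_series.csv")
        series, constants = tyg.standardize_by_database(series, ddof=config.standardize_ddof)
        (out / "standardization.json").write_text(
            json.dumps({db: {"mean": m, "sd": s} for db, (m, s) in constants.items()},
                       indent=2, sort_keys=True)
        )
        paths["standardization"] = str(out / "standardization.json")
        _stage("series", n_series=len(series), excluded=len(series_excl))

        # --- trajectories --------------------------------------------------
        stage = "trajectories"
        sel = lcgm.select_classes(
            series,
            K_range=config.k_range,
            degree=config.degree,
            seed=config.seed,
            n_starts=config.n_starts,
            entropy_floor=config.entropy_floor,
            min_class_floor=config.min_class_floor,
        )
        sel.table.to_csv(out / "lcgm_selection.csv", index=False)
        paths["lcgm_selection"] = str(out / "lcgm_selection.csv")
        model_doc = sel.model.to_dict()
        model_doc["standardization"] = {
            db: {"mean": m, "sd": s} for db, (m, s) in constants.items()
        }
        (out / "trajectory_model.json").write_text(json.dumps(model_doc, indent=2, sort_keys=True))
        paths["trajectory_model"] = str(out / "trajectory_model.json")
        assignments = lcgm.assign_and_label(sel.model, series)
        assign_df = pd.DataFrame(
            {
                "patient_id": [a.patient_id for a in assignments],
                "trajectory": [a.label for a in assignments],
                "modal_class": [a.modal_class for a in assignments],
                "max_posterior": [float(a.posterior.max()) for a in assignments],
            }
        )
        assign_df.to_csv(out / "assignments.csv", index=False)
        paths["assignments"] = str(out / "assignments.csv")
        _stage("trajectories", K=sel.model.K, entropy=round(sel.model.entropy, 3))

        # --- TBM -----------------------------------------------------------
        stage = "tbm"
        tbm_table = tbm_family(
            series, thresholds=config.tbm_thresholds, time_axis=config.tbm_axis
        ).reset_index()
        tbm_table.to_csv(out / "tbm.csv", index=False)
        paths["tbm"] = str(out / "tbm.csv")
        _stage("tbm", rows=len(tbm_table), thresholds=len(config.tbm_thresholds))

        # --- analysis frame -------------------------------------------------
        stage = "join"
        frame = (
            report.eligible_outcomes.merge(assign_df[["patient_id", "trajectory"]], on="patient_id")
            .merge(tbm_table, on="patient_id")
        )

        # --- descriptives ---------------------------------------------------
        stage = "descriptives"
        cont = [c for c in config.descriptive_continuous if c in frame.columns]
        bin_ = [c for c in config.descriptive_binary if c in frame.columns]
        table1 = survival.descriptives_by_class(frame, "trajectory", cont, bin_)
        table1.to_csv(out / "table1_descriptives.csv", index=False)
        paths["table1"] = str(out / "table1_descriptives.csv")

        # --- time-stratified models -----------------------------------------
        stage = "survival"
        tiers = {"M1": [], **{k: list(v) for k, v in config.tiers.items() if k != "M1"}}
        hr_rows = []
        ph_diag: dict = {}
        tbm_cols = [threshold_label(t) for t in config.tbm_thresholds]
        for tier_name, covs in tiers.items():
            covs = [c for c in covs if c in frame.columns]
            res = survival.time_stratified_model(
                frame, "trajectory",
                covariates=covs, cutpoint_days=config.cutpoint_days, ties=config.ties,
            )
            t = res.table.copy()
            t.insert(0, "model", tier_name)
            hr_rows.append(t)
            if tier_name == max(tiers):
                ph_diag["trajectory"] = {
                    "unstratified": _ph_dict(res.unstratified_ph_test),
                    "time_stratified": _ph_dict(res.ph_test),
                }
            for col in tbm_cols:
                res_t = survival.time_stratified_model(
                    frame, col,
                    covariates=covs, cutpoint_days=config.cutpoint_days, ties=config.ties,
                    include_unstratified=False,
                )
                tt = res_t.table.copy()
                tt.insert(0, "model", tier_name)
                hr_rows.append(tt)
        hr_table = pd.concat(hr_rows, ignore_index=True)
        hr_table.to_csv(out / "table2_hr.csv", index=False)
        paths["table2"] = str(out / "table2_hr.csv")
        (out / "ph_diagnostics.json").write_text(json.dumps(ph_diag, indent=2, sort_keys=True))
        paths["ph_diagnostics"] = str(out / "ph_diagnostics.json")
        _stage("survival", models=len(tiers), rows=len(hr_table))

        # --- subgroups -------------------------------------------------------
        stage = "subgroups"
        top_tier = tiers[max(tiers)]
        sg_cols = [c for c in config.subgroups if c in frame.columns]
        sg = survival.subgroup_scan(
            frame, "trajectory", sg_cols,
            covariates=[c for c in top_tier if c in frame.columns],
            cutpoint_days=config.cutpoint_days, ties=config.ties,
        )
        sg.table.to_csv(out / "subgroup_hr.csv", index=False)
        sg.interactions.to_csv(out / "subgroup_interactions.csv", index=False)
        paths["subgroups"] = str(out / "subgroup_hr.csv")
        paths["subgroup_interactions"] = str(out / "subgroup_interactions.csv")

        # --- manifest --------------------------------------------------------
        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_input": report.n_input,
            "n_analyzed": report.n_analyzed,
            "selected_k": int(sel.model.K),
            "constraints_met": bool(sel.constraints_met),
            "stages": list(paths),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = str(out / "manifest.json")
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}: {err}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return PipelineResult(
        outdir=out,
        paths=paths,
        selection=sel,
        assignments=assign_df,
        tbm_table=tbm_table,
        hr_table=hr_table,
        subgroup_result=sg,
        ph_diagnostics=ph_diag,
        analysis_frame=frame,
        manifest=manifest,
    )


def _ph_dict(ph: survival.PHTestResult | None) -> dict:
    if ph is None:
        return {}
    out = {}
    for name, row in ph.table.iterrows():
        out[str(name)] = {"chi2": float(row["chi2"]), "df": int(row["df"]), "p": float(row["p"])}
    return out
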