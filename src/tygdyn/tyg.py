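"""Construction of the triglyceride-glucose (TyG) exposure series.

The TyG index, ``ln(triglycerides [mg/dL] x glucose [mg/dL] / 2)``, is a
cheap laboratory surrogate of insulin resistance.  This module turns raw
laboratory rows into per-patient ordered TyG series:

* unit harmonization of triglycerides and glucose to mg/dL,
* computation of the index itself,
* chronological assembly of each patient's series with truncation to the
  first seven measurements and exclusion of patients with fewer than two,
* within-database z-standardization so series coming from laboratories
  with different calibration can be pooled for trajectory modeling.

All operations here are deterministic functions of their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_PER_MMOLL",
    "harmonize_units",
    "compute_tyg",
    "BiomarkerSeries",
    "build_series",
    "standardize_by_database",
    "apply_standardization",
]

#: mg/dL per mmol/L; molar mass of glucose is 180.16 g/mol and an average
#: triglyceride is taken as 885.7 g/mol.
MGDL_PER_MMOLL = {"glucose": 18.016, "triglycerides": 88.57}


def harmonize_units(value, analyte: str, unit: str):
    """Convert a triglyceride or glucose value to mg/dL.

    Parameters
    ----------
    value : float or array-like
        Strictly positive laboratory value(s).
    analyte : {"triglycerides", "glucose"}
    unit : {"mg/dL", "mmol/L"}
        ``mg/dL`` values pass through unchanged; ``mmol/L`` values are
        multiplied by the analyte's molar-mass conversion factor.

    Returns
    -------
    float or ndarray
        The value in mg/dL.
    """
    if analyte not in MGDL_PER_MMOLL:
        raise ValueError(f"unknown analyte {analyte!r}; expected 'triglycerides' or 'glucose'")
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError(f"non-positive {analyte} value; laboratory values must be > 0")
    if unit == "mg/dL":
        out = arr
    elif unit == "mmol/L":
        out = arr * MGDL_PER_MMOLL[analyte]
    else:
        raise ValueError(f"unknown unit {unit!r}; expected 'mg/dL' or 'mmol/L'")
    return float(out) if np.ndim(value) == 0 else out


def compute_tyg(tg_mgdl, glu_mgdl):
    """TyG index: ``ln(TG[mg/dL] * GLU[mg/dL] / 2)``.

    Both inputs must already be harmonized to mg/dL and strictly positive.
    Accepts scalars or arrays (broadcast).
    """
    tg = np.asarray(tg_mgdl, dtype=float)
    glu = np.asarray(glu_mgdl, dtype=float)
    if np.any(~(tg > 0)) or np.any(~(glu > 0)):
        raise ValueError("invalid laboratory value: TG and glucose must be > 0")
    out = np.log(tg * glu / 2.0)
    if np.ndim(tg_mgdl) == 0 and np.ndim(glu_mgdl) == 0:
        return float(out)
    return out


@dataclass
class BiomarkerSeries:
    """One patient's ordered TyG measurements.

    ``values`` are raw (dimensionless) TyG index values ordered
    chronologically; ``times_days`` are optional measurement times in days
    from ICU admission; ``z_values`` are filled by
    :func:`standardize_by_database`.
    """

    patient_id: str
    database_id: str
    values: np.ndarray
    times_days: np.ndarray | None = None
    z_values: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.values)
        if not 2 <= n <= 7:
            raise ValueError(f"series for {self.patient_id!r} has {n} values; need 2..7")
        if self.times_days is not None:
            self.times_days = np.asarray(self.times_days, dtype=float)
            if len(self.times_days) != n:
                raise ValueError("times_days length does not match values")
            if np.any(np.diff(self.times_days) <= 0):
                raise ValueError(f"times for {self.patient_id!r} are not strictly increasing")
        if self.z_values is not None:
            self.z_values = np.asarray(self.z_values, dtype=float)
            if len(self.z_values) != n:
                raise ValueError("z_values length does not match values")

    @property
    def n(self) -> int:
        return len(self.values)


def build_series(
    measurements: pd.DataFrame,
    min_measurements: int = 2,
    max_measurements: int = 7,
) -> tuple[list[BiomarkerSeries], pd.DataFrame]:
    """Assemble per-patient TyG series from a long measurements table.

    The table needs ``patient_id`` plus either a precomputed ``tyg_raw``
    column or both ``triglycerides_mgdl`` and ``glucose_mgdl`` (the index is
    then computed row-wise).  Rows are ordered within patient by
    ``meas_time_days`` when present, otherwise by ``meas_index`` (1-based).
    Rows with missing TG or glucose are dropped, not imputed.  Only the
    first ``max_measurements`` rows are retained; patients left with fewer
    than ``min_measurements`` are excluded and logged.

    Returns
    -------
    (series, exclusions)
        ``series`` is a list of :class:`BiomarkerSeries` in first-appearance
        order; ``exclusions`` is a DataFrame with columns
        ``patient_id, reason``.
    """
    df = measurements.copy()
    if "patient_id" not in df.columns:
        raise ValueError("measurements table must have a 'patient_id' column")
    if "tyg_raw" not in df.columns:
        if not {"triglycerides_mgdl", "glucose_mgdl"} <= set(df.columns):
            raise ValueError(
                "measurements need a 'tyg_raw' column or both "
                "'triglycerides_mgdl' and 'glucose_mgdl'"
            )
        ok = df["triglycerides_mgdl"].notna() & df["glucose_mgdl"].notna()
        df = df.loc[ok]
        df = df.assign(
            tyg_raw=compute_tyg(
                df["triglycerides_mgdl"].to_numpy(), df["glucose_mgdl"].to_numpy()
            )
        )
    else:
        df = df.loc[df["tyg_raw"].notna()]
    if "database_id" not in df.columns:
        df = df.assign(database_id="ALL")

    has_time = "meas_time_days" in df.columns and df["meas_time_days"].notna().all()
    if not has_time and "meas_index" not in df.columns:
        raise ValueError("measurements need 'meas_time_days' or 'meas_index' for ordering")

    if "meas_index" in df.columns:
        dup = df.duplicated(subset=["patient_id", "meas_index"])
        if dup.any():
            bad = df.loc[dup, "patient_id"].iloc[0]
            raise ValueError(f"duplicate (patient_id, meas_index) rows, e.g. patient {bad!r}")

    series: list[BiomarkerSeries] = []
    excluded: list[tuple[str, str]] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        if has_time:
            t = grp["meas_time_days"].to_numpy(dtype=float)
            if pd.Series(t).duplicated().any():
                warnings.warn(
                    f"tied measurement times for patient {pid!r}; keeping input row order",
                    stacklevel=2,
                )
            order = np.argsort(t, kind="stable")
            grp = grp.iloc[order]
        else:
            grp = grp.sort_values("meas_index", kind="stable")
        grp = grp.iloc[:max_measurements]
        if len(grp) < min_measurements:
            excluded.append((pid, "insufficient_measurements"))
            continue
        times = grp["meas_time_days"].to_numpy(dtype=float) if has_time else None
        series.append(
            BiomarkerSeries(
                patient_id=pid,
                database_id=str(grp["database_id"].iloc[0]),
                values=grp["tyg_raw"].to_numpy(dtype=float),
                times_days=times,
            )
        )
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return series, exclusions


def standardize_by_database(
    series: list[BiomarkerSeries], ddof: int = 1
) -> tuple[list[BiomarkerSeries], dict[str, tuple[float, float]]]:
    """Fill ``z_values`` by pooled within-database z-scoring.

    All measurements from all patients of a database are pooled; the pooled
    mean and SD (sample SD, ``ddof=1``, by default) define that database's
    standardization constants.  After the call every database's z-values
    have mean 0 and SD 1.

    Returns the same series objects (mutated) and a dict mapping
    ``database_id`` to ``(mean, sd)`` for reuse on new patients.
    """
    by_db: dict[str, list[np.ndarray]] = {}
    for s in series:
        by_db.setdefault(s.database_id, []).append(s.values)
    constants: dict[str, tuple[float, float]] = {}
    for db, chunks in by_db.items():
        pooled = np.concatenate(chunks)
        if len(pooled) < 2:
            raise ValueError(f"database {db!r} has fewer than 2 measurements")
        mean = float(np.mean(pooled))
        sd = float(np.std(pooled, ddof=ddof))
        if sd == 0.0:
            raise ValueError(f"database {db!r} has zero within-database variance")
        constants[db] = (mean, sd)
    apply_standardization(series, constants)
    return series, constants


def apply_standardization(
    series: list[BiomarkerSeries], constants: dict[str, tuple[float, float]]
) -> list[BiomarkerSeries]:
    """Apply stored per-database ``(mean, sd)`` constants to series."""
    for s in series:
        if s.database_id not in constants:
            raise KeyError(f"no standardization constants for database {s.database_id!r}")
        mean, sd = constants[s.database_id]
        s.z_values = (s.values - mean) / sd
    return series
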