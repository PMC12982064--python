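"""Latent class growth modeling (LCGM) of standardized TyG series.

The model is a finite mixture of polynomial mean trajectories with a shared
homoscedastic residual variance and no random effects (classic group-based
trajectory modeling).  Subject ``i`` in class ``k`` has

    z_ij ~ Normal( x(t_ij)' beta_k , sigma^2 ),  independently over j,

where ``x(t)`` is a polynomial basis in the measurement index (1..7,
centered at the midpoint for conditioning) or, optionally, calendar time.
Fitting is by EM with k-means and random restarts; class enumeration is
guided by BIC subject to entropy and minimum-class-size floors.

Classes in a fitted model are stored in canonical order: ascending mean
fitted trajectory level over measurement indices 1..7.  For a three-class
model the canonical labels are the phenotype names LSI (low-slightly
increasing), MI (moderate-increasing), and PH (persistently high).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .tyg import BiomarkerSeries

__all__ = [
    "TrajectoryModel",
    "ClassAssignment",
    "SelectionResult",
    "fit_lcgm",
    "mixture_loglik",
    "select_classes",
    "relative_entropy",
    "assign_and_label",
    "posterior_matrix",
]

_INDEX_CENTER = 4.0  # midpoint of measurement numbers 1..7


@dataclass
class TrajectoryModel:
    """A fitted K-class polynomial growth mixture on the z-score scale."""

    K: int
    degree: int
    mixing_weights: np.ndarray
    coeffs: np.ndarray  # (K, degree + 1), basis centered at `center`
    residual_var: float
    loglik: float
    n_params: int
    aic: float
    bic: float
    sabic: float
    entropy: float
    min_class_fraction: float
    converged: bool
    n_iter: int
    n_subjects: int
    center: float = _INDEX_CENTER
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int | None = None

    @property
    def class_labels(self) -> list[str]:
        if self.K == 3:
            return ["LSI", "MI", "PH"]
        return [f"C{k + 1}" for k in range(self.K)]

    def design(self, t: np.ndarray) -> np.ndarray:
        tc = np.asarray(t, dtype=float) - self.center
        return np.vander(tc, self.degree + 1, increasing=True)

    def mean_curve(self, indices=None) -> np.ndarray:
        """Fitted class means (K, len(indices)); default indices 1..7."""
        if indices is None:
            indices = np.arange(1, 8)
        return self.design(np.asarray(indices, float)) @ self.coeffs.T

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "degree": self.degree,
            "center": self.center,
            "mixing_weights": self.mixing_weights.tolist(),
            "coeffs": self.coeffs.tolist(),
            "residual_var": self.residual_var,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "aic": self.aic,
            "bic": self.bic,
            "sabic": self.sabic,
            "entropy": self.entropy,
            "min_class_fraction": self.min_class_fraction,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_subjects": self.n_subjects,
            "class_labels": self.class_labels,
        }


@dataclass
class ClassAssignment:
    patient_id: str
    posterior: np.ndarray
    modal_class: int
    label: str


@dataclass
class SelectionResult:
    model: TrajectoryModel
    table: pd.DataFrame
    constraints_met: bool


def _flatten(series: list[BiomarkerSeries], time_axis: str):
    """Stack all observations: (subject index, design time, z value)."""
    subj, tt, zz = [], [], []
    for i, s in enumerate(series):
        if s.z_values is None:
            raise ValueError("series must be standardized (z_values) before LCGM")
        if time_axis == "index":
            t = np.arange(1, s.n + 1, dtype=float)
        elif time_axis == "calendar":
            if s.times_days is None:
                raise ValueError("calendar time axis requires times_days")
            t = np.asarray(s.times_days, dtype=float)
        else:
            raise ValueError(f"unknown time_axis {time_axis!r}")
        subj.append(np.full(s.n, i))
        tt.append(t)
        zz.append(s.z_values)
    return (
        np.concatenate(subj).astype(np.int64),
        np.concatenate(tt),
        np.concatenate(zz),
    )


def _class_loglik(subj, Xobs, z, n_subj, coeffs, sigma2, n_per):
    """Per-subject, per-class Gaussian log-likelihood (n_subj, K)."""
    mu = Xobs @ coeffs.T  # (n_obs, K)
    resid2 = (z[:, None] - mu) ** 2
    K = coeffs.shape[0]
    sse = np.empty((n_subj, K))
    for k in range(K):
        sse[:, k] = np.bincount(subj, weights=resid2[:, k], minlength=n_subj)
    return -0.5 * n_per[:, None] * np.log(2.0 * np.pi * sigma2) - sse / (2.0 * sigma2)


def _m_step(subj, Xobs, z, resp):
    """Weighted-least-squares update of weights, coefficients, variance."""
    n_subj, K = resp.shape
    w_obs = resp[subj]  # (n_obs, K)
    d = Xobs.shape[1]
    coeffs = np.empty((K, d))
    for k in range(K):
        w = w_obs[:, k]
        A = Xobs.T @ (w[:, None] * Xobs)
        b = Xobs.T @ (w * z)
        coeffs[k] = np.linalg.solve(A, b)
    mu = Xobs @ coeffs.T
    resid2 = (z[:, None] - mu) ** 2
    sigma2 = float(np.sum(w_obs * resid2) / len(z))
    sigma2 = max(sigma2, 1e-10)
    weights = resp.mean(axis=0)
    return weights, coeffs, sigma2


def relative_entropy(posteriors: np.ndarray) -> float:
    """Normalized classification certainty, 1 - sum(-p ln p) / (n ln K).

    1.0 for perfectly separated (one-hot) posteriors, 0.0 for uniform
    posteriors; by convention 1.0 when K = 1.  ``0 * ln 0`` is treated as 0.
    """
    R = np.asarray(posteriors, dtype=float)
    n, K = R.shape
    if K == 1:
        return 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(R > 0, R * np.log(R), 0.0)
    ent = -plogp.sum()
    return float(np.clip(1.0 - ent / (n * np.log(K)), 0.0, 1.0))


def _init_responsibilities(series, subj, tt, z, n_subj, K, start, rng, kmeans_seed):
    if K == 1:
        return np.ones((n_subj, 1))
    if start == 0 or start % 2 == 1:
        # k-means on (per-subject mean, per-subject slope) summaries
        sum_n = np.bincount(subj, minlength=n_subj).astype(float)
        sum_t = np.bincount(subj, weights=tt, minlength=n_subj)
        sum_z = np.bincount(subj, weights=z, minlength=n_subj)
        sum_tz = np.bincount(subj, weights=tt * z, minlength=n_subj)
        sum_t2 = np.bincount(subj, weights=tt * tt, minlength=n_subj)
        mean_z = sum_z / sum_n
        var_t = sum_t2 / sum_n - (sum_t / sum_n) ** 2
        cov_tz = sum_tz / sum_n - (sum_t / sum_n) * mean_z
        slope = np.where(var_t > 1e-12, cov_tz / np.maximum(var_t, 1e-12), 0.0)
        feats = np.column_stack([mean_z, slope])
        feats = (feats - feats.mean(0)) / np.maximum(feats.std(0), 1e-12)
        labels = KMeans(n_clusters=K, n_init=1, random_state=kmeans_seed + start).fit(
            feats
        ).labels_
        resp = np.full((n_subj, K), 0.05 / max(K - 1, 1))
        resp[np.arange(n_subj), labels] = 0.95
    else:
        resp = rng.dirichlet(np.ones(K), size=n_subj)
    return resp


def fit_lcgm(
    series: list[BiomarkerSeries],
    K: int,
    degree: int = 2,
    seed: int = 0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    time_axis: str = "index",
    center: float = _INDEX_CENTER,
) -> TrajectoryModel:
    """Fit a K-class polynomial growth mixture by EM with restarts.

    The observed-data log-likelihood is non-decreasing over EM iterations
    (recorded in ``loglik_path`` of the winning start).  Starts whose
    smallest mixing weight collapses below ``1/n_subjects`` are aborted.
    Raises if ``K < 1`` or ``degree`` not in {1, 2}.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n_subj = len(series)
    if n_subj < K:
        raise ValueError("fewer subjects than classes")
    subj, tt, z = _flatten(series, time_axis)
    Xobs = np.vander(tt - center, degree + 1, increasing=True)
    n_per = np.bincount(subj, minlength=n_subj).astype(float)
    rng = np.random.default_rng(np.random.SeedSequence([seed, K, degree]))
    kmeans_seed = int(rng.integers(2**31 - 1))

    best = None
    best_fallback = None  # best pre-collapse state, if every start collapses
    for start in range(max(1, n_starts)):
        resp = _init_responsibilities(series, subj, tt, z, n_subj, K, start, rng, kmeans_seed)
        weights, coeffs, sigma2 = _m_step(subj, Xobs, z, resp)
        path = []
        converged = False
        failed = False
        for it in range(max_iter):
            logf = _class_loglik(subj, Xobs, z, n_subj, coeffs, sigma2, n_per)
            logpost = np.log(weights)[None, :] + logf
            ll_i = logsumexp(logpost, axis=1)
            ll = float(ll_i.sum())
            path.append(ll)
            resp = np.exp(logpost - ll_i[:, None])
            if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
                converged = True
                break
            prev = (weights, coeffs, sigma2)
            weights, coeffs, sigma2 = _m_step(subj, Xobs, z, resp)
            if np.any(weights < 1.0 / n_subj):
                failed = True
                weights, coeffs, sigma2 = prev
                break
        cand = (path[-1], converged, weights, coeffs, sigma2, resp, np.array(path))
        if failed:
            if best_fallback is None or cand[0] > best_fallback[0]:
                best_fallback = cand
            continue
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        warnings.warn(
            f"all {n_starts} EM starts collapsed an empty class for K={K}; "
            "returning the best pre-collapse state (converged=False)",
            stacklevel=2,
        )
        best = best_fallback[:1] + (False,) + best_fallback[2:]

    ll, converged, weights, coeffs, sigma2, resp, path = best

    # canonical class order: ascending mean fitted level over indices 1..7
    grid = np.vander(np.arange(1.0, 8.0) - center, degree + 1, increasing=True)
    order = np.argsort((grid @ coeffs.T).mean(axis=0), kind="stable")
    weights, coeffs, resp = weights[order], coeffs[order], resp[:, order]

    d = degree + 1
    n_params = (K - 1) + K * d + 1
    aic = -2.0 * ll + 2.0 * n_params
    bic = -2.0 * ll + n_params * np.log(n_subj)
    sabic = -2.0 * ll + n_params * np.log((n_subj + 2.0) / 24.0)
    modal = resp.argmax(axis=1)
    frac = np.bincount(modal, minlength=K) / n_subj
    return TrajectoryModel(
        K=K,
        degree=degree,
        mixing_weights=weights,
        coeffs=coeffs,
        residual_var=sigma2,
        loglik=ll,
        n_params=n_params,
        aic=float(aic),
        bic=float(bic),
        sabic=float(sabic),
        entropy=relative_entropy(resp),
        min_class_fraction=float(frac.min()),
        converged=bool(converged),
        n_iter=len(path),
        n_subjects=n_subj,
        center=center,
        loglik_path=path,
        seed=seed,
    )


def mixture_loglik(
    model: TrajectoryModel, series: list[BiomarkerSeries], time_axis: str = "index"
) -> float:
    """Observed-data log-likelihood of ``series`` under a fitted model."""
    subj, tt, z = _flatten(series, time_axis)
    n_subj = len(series)
    Xobs = np.vander(tt - model.center, model.degree + 1, increasing=True)
    n_per = np.bincount(subj, minlength=n_subj).astype(float)
    logf = _class_loglik(subj, Xobs, z, n_subj, model.coeffs, model.residual_var, n_per)
    return float(logsumexp(np.log(model.mixing_weights)[None, :] + logf, axis=1).sum())


def posterior_matrix(
    model: TrajectoryModel, series: list[BiomarkerSeries], time_axis: str = "index"
) -> np.ndarray:
    """Posterior class-membership probabilities (n_subjects, K), computed
    in log space so degenerate densities never produce NaN."""
    subj, tt, z = _flatten(series, time_axis)
    n_subj = len(series)
    Xobs = np.vander(tt - model.center, model.degree + 1, increasing=True)
    n_per = np.bincount(subj, minlength=n_subj).astype(float)
    logf = _class_loglik(subj, Xobs, z, n_subj, model.coeffs, model.residual_var, n_per)
    logpost = np.log(model.mixing_weights)[None, :] + logf
    return np.exp(logpost - logsumexp(logpost, axis=1)[:, None])


def assign_and_label(
    model: TrajectoryModel, series: list[BiomarkerSeries], time_axis: str = "index"
) -> list[ClassAssignment]:
    """Modal posterior assignment with phenotype labels.

    Labels follow the canonical (ascending mean level) class order, so they
    are invariant to how classes happened to be indexed during fitting:
    for K = 3 the lowest mean trajectory is LSI, the middle MI, the highest
    PH; otherwise rank labels C1..CK.
    """
    R = posterior_matrix(model, series, time_axis)
    # labels are attached by trajectory level rank, so permuting the class
    # order inside the model cannot change any patient's label
    levels = model.mean_curve().mean(axis=0)
    rank_of_class = np.empty(model.K, dtype=int)
    rank_of_class[np.argsort(levels, kind="stable")] = np.arange(model.K)
    labels = model.class_labels
    out = []
    for i, s in enumerate(series):
        modal = int(R[i].argmax())
        out.append(
            ClassAssignment(
                patient_id=s.patient_id,
                posterior=R[i],
                modal_class=modal,
                label=labels[rank_of_class[modal]],
            )
        )
    return out


def select_classes(
    series: list[BiomarkerSeries],
    K_range=(2, 3, 4, 5, 6),
    degree: int = 2,
    seed: int = 0,
    n_starts: int = 5,
    entropy_floor: float = 0.5,
    min_class_floor: float = 0.05,
    time_axis: str = "index",
    **fit_kwargs,
) -> SelectionResult:
    """Fit each candidate K and select by BIC subject to quality floors.

    The chosen model minimizes BIC among candidates whose minimum modal
    class fraction and relative entropy meet the floors ("acceptable class
    sizes").  If no candidate passes, the overall best-BIC model is
    returned with ``constraints_met=False``.
    """
    K_list = sorted(set(int(k) for k in K_range))
    if not K_list:
        raise ValueError("K_range is empty")
    models = []
    for K in K_list:
        models.append(
            fit_lcgm(
                series, K, degree=degree, seed=seed, n_starts=n_starts,
                time_axis=time_axis, **fit_kwargs,
            )
        )
    rows = []
    for m in models:
        passes = (m.entropy >= entropy_floor or m.K == 1) and (
            m.min_class_fraction >= min_class_floor
        )
        rows.append(
            {
                "K": m.K,
                "loglik": m.loglik,
                "n_params": m.n_params,
                "AIC": m.aic,
                "BIC": m.bic,
                "SABIC": m.sabic,
                "entropy": m.entropy,
                "min_class_fraction": m.min_class_fraction,
                "converged": m.converged,
                "passes_floors": passes,
            }
        )
    table = pd.DataFrame(rows)
    eligible = table.index[table["passes_floors"]]
    constraints_met = len(eligible) > 0
    if constraints_met:
        best_idx = int(table.loc[eligible, "BIC"].idxmin())
    else:
        warnings.warn(
            "no candidate K passed the entropy/class-size floors; "
            "returning best-BIC model flagged constraints_unmet",
            stacklevel=2,
        )
        best_idx = int(table["BIC"].idxmin())
    table["selected"] = False
    table.loc[best_idx, "selected"] = True
    return SelectionResult(model=models[best_idx], table=table, constraints_met=constraints_met)
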