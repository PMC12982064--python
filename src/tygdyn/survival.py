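"""Survival machinery for the time-stratified TyG analysis.

Implements, on counting-process ``(start, stop]`` records:

* Cox proportional hazards by Newton-Raphson maximization of the partial
  likelihood, with Breslow (default) or Efron tie handling and optional
  baseline-hazard stratification,
* Schoenfeld-residual diagnostics of the proportional-hazards assumption
  (Grambsch-Therneau score test with identity / rank / KM time transforms),
* Kaplan-Meier curves and the (landmark) log-rank test,
* episode splitting at a prespecified day-7 cutpoint, so exposure effects
  can differ between the acute interval (0, 7] and the late interval
  (7, infinity),
* the two-interval ("time-stratified") exposure model with staged
  covariate adjustment, and subgroup / interaction scans,
* Table-1 style descriptive comparisons across trajectory classes.

Conventions: intervals are closed on the right; a death at exactly the
cutpoint belongs to the early interval.  Confidence intervals are Wald
intervals on the log-hazard scale at the two-sided 0.05 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "fit_cox",
    "PHTestResult",
    "schoenfeld_ph_test",
    "km_curve",
    "km_logrank",
    "LogrankResult",
    "episode_split",
    "time_stratified_model",
    "TimeStratifiedResult",
    "subgroup_scan",
    "SubgroupScanResult",
    "descriptives_by_class",
]

_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Cox partial likelihood engine
# ---------------------------------------------------------------------------


def _suffix_sums(a: np.ndarray) -> np.ndarray:
    """Suffix cumulative sums along axis 0, with a trailing zero row."""
    rev = np.cumsum(a[::-1], axis=0)[::-1]
    pad = np.zeros((1,) + a.shape[1:])
    return np.concatenate([rev, pad], axis=0)


class _CoxData:
    """Pre-sorted per-stratum structures for repeated likelihood passes."""

    def __init__(self, start, stop, event, X, strata):
        self.n, self.p = X.shape
        self.X = X
        self.strata_levels = []
        self.blocks = []
        codes, levels = pd.factorize(strata, sort=True) if strata is not None else (
            np.zeros(len(stop), dtype=int),
            ["__all__"],
        )
        self.strata_levels = list(levels)
        for s in range(len(levels)):
            idx = np.flatnonzero(codes == s)
            if idx.size == 0:
                continue
            o_stop = idx[np.argsort(stop[idx], kind="stable")]
            o_start = idx[np.argsort(start[idx], kind="stable")]
            ev = o_stop[event[o_stop] == 1]  # event rows in ascending stop order
            te = stop[ev]
            tu, inv, d = np.unique(te, return_inverse=True, return_counts=True)
            self.blocks.append(
                {
                    "o_stop": o_stop,
                    "o_start": o_start,
                    "ss": stop[o_stop],
                    "sa": start[o_start],
                    "ev_rows": ev,
                    "te": te,
                    "tu": tu,
                    "inv": inv,
                    "d": d.astype(float),
                    "pos_stop": np.searchsorted(stop[o_stop], tu, side="left"),
                    "pos_start": np.searchsorted(start[o_start], tu, side="left"),
                    "stratum": s,
                }
            )
        self.n_events = int(event.sum())


def _cox_pass(data: _CoxData, beta: np.ndarray, ties: str, want_resid: bool = False):
    """One likelihood pass: returns (loglik, score, information[, residuals])."""
    X = data.X
    p = data.p
    eta = X @ beta
    eta = eta - eta.max() if eta.size else eta  # guard overflow; cancels in PL
    theta = np.exp(eta)
    ll = 0.0
    U = np.zeros(p)
    I = np.zeros((p, p))
    resid_rows = []
    for blk in data.blocks:
        tu, d, inv = blk["tu"], blk["d"], blk["inv"]
        if len(tu) == 0:
            continue
        os_, oa = blk["o_stop"], blk["o_start"]
        th_s = theta[os_]
        Xs = X[os_]
        th_a = theta[oa]
        Xa = X[oa]
        F0 = _suffix_sums(th_s)
        F1 = _suffix_sums(th_s[:, None] * Xs)
        F2 = _suffix_sums(th_s[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))
        G0 = _suffix_sums(th_a)
        G1 = _suffix_sums(th_a[:, None] * Xa)
        G2 = _suffix_sums(th_a[:, None, None] * (Xa[:, :, None] * Xa[:, None, :]))
        S0 = F0[blk["pos_stop"]] - G0[blk["pos_start"]]
        S1 = F1[blk["pos_stop"]] - G1[blk["pos_start"]]
        S2 = F2[blk["pos_stop"]] - G2[blk["pos_start"]]
        ev = blk["ev_rows"]
        Xe = X[ev]
        s_k = np.zeros((len(tu), p))
        np.add.at(s_k, inv, Xe)
        eta_e = eta[ev]
        if ties == "breslow":
            ll += float(eta_e.sum() - (d * np.log(S0)).sum())
            m = S1 / S0[:, None]
            U += (s_k - d[:, None] * m).sum(axis=0)
            I += np.einsum(
                "k,kij->ij", d, S2 / S0[:, None, None] - m[:, :, None] * m[:, None, :]
            )
        elif ties == "efron":
            th_e = theta[ev]
            T0 = np.zeros(len(tu))
            np.add.at(T0, inv, th_e)
            T1 = np.zeros((len(tu), p))
            np.add.at(T1, inv, th_e[:, None] * Xe)
            T2 = np.zeros((len(tu), p, p))
            np.add.at(T2, inv, th_e[:, None, None] * (Xe[:, :, None] * Xe[:, None, :]))
            ll += float(eta_e.sum())
            for k in range(len(tu)):
                dk = int(d[k])
                for l in range(dk):
                    f = l / dk
                    s0 = S0[k] - f * T0[k]
                    s1 = S1[k] - f * T1[k]
                    s2 = S2[k] - f * T2[k]
                    ll -= np.log(s0)
                    m = s1 / s0
                    U += s_k[k] / dk - m
                    I += s2 / s0 - np.outer(m, m)
        else:
            raise ValueError(f"unknown ties method {ties!r}")
        if want_resid:
            m_all = S1 / S0[:, None]
            V_all = S2 / S0[:, None, None] - m_all[:, :, None] * m_all[:, None, :]
            resid_rows.append(
                (blk["te"], Xe - m_all[inv], V_all[inv], np.full(len(ev), blk["stratum"]))
            )
    if want_resid:
        if resid_rows:
            t = np.concatenate([r[0] for r in resid_rows])
            R = np.concatenate([r[1] for r in resid_rows])
            V = np.concatenate([r[2] for r in resid_rows])
            st = np.concatenate([r[3] for r in resid_rows])
        else:
            t, R, V, st = np.array([]), np.zeros((0, p)), np.zeros((0, p, p)), np.array([])
        return ll, U, I, (t, R, V, st)
    return ll, U, I


@dataclass
class CoxFit:
    """A fitted Cox model with Wald inference and PH-test ingredients."""

    names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int
    score_chi2: float
    score_df: int
    flags: list[str] = field(default_factory=list)
    schoen_times: np.ndarray | None = None
    schoen_resid: np.ndarray | None = None
    schoen_var: np.ndarray | None = None
    schoen_strata: np.ndarray | None = None
    info: np.ndarray | None = None
    entry: np.ndarray | None = None
    followup: np.ndarray | None = None
    events: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(self.beta - _Z95 * self.se)
        hi = np.exp(self.beta + _Z95 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, 0.0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_lo95": ci[:, 0],
                "hr_hi95": ci[:, 1],
                "p": self.p,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def fit_cox(
    data: pd.DataFrame,
    covariates: list[str],
    *,
    start_col: str | None = None,
    stop_col: str = "followup_days",
    event_col: str = "event",
    strata_col: str | None = None,
    ties: str = "breslow",
    max_iter: int = 60,
    tol: float = 1e-10,
) -> CoxFit:
    """Fit a Cox model on (start, stop] counting-process records.

    ``start_col=None`` means all records begin at time 0.  Covariates with
    zero variance carry no information: they are reported with coefficient
    0 and infinite standard error (hazard ratio 1) and flagged.  A monotone
    partial likelihood (perfect separation) is detected by runaway
    coefficients, which are capped and flagged.  Raises if there are no
    events or if the information matrix is singular (collinear covariates).
    """
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ValueError(f"covariates absent from data: {missing}")
    stop = data[stop_col].to_numpy(dtype=float)
    start = (
        data[start_col].to_numpy(dtype=float) if start_col else np.zeros(len(stop))
    )
    event = data[event_col].to_numpy(dtype=float).astype(int)
    if np.any(stop <= start):
        raise ValueError("every record needs stop > start")
    if event.sum() == 0:
        raise ValueError("no events in data")
    Xfull = data[list(covariates)].to_numpy(dtype=float)
    names = list(covariates)
    sd = Xfull.std(axis=0)
    active = sd > 0
    dropped = [n for n, a in zip(names, active) if not a]
    flags = []
    if dropped:
        flags.append(f"zero_variance:{','.join(dropped)}")
        warnings.warn(
            f"covariates with zero variance carry no information: {dropped}", stacklevel=2
        )
    Xa = Xfull[:, active] - Xfull[:, active].mean(axis=0)  # centering cancels in PL
    strata = data[strata_col].to_numpy() if strata_col else None
    cdata = _CoxData(start, stop, event, Xa, strata)
    pa = Xa.shape[1]

    # score test at the null (equals the log-rank statistic for a single
    # binary covariate without ties)
    ll0, U0, I0 = _cox_pass(cdata, np.zeros(pa), ties)
    try:
        score_chi2 = float(U0 @ np.linalg.solve(I0, U0)) if pa else 0.0
    except np.linalg.LinAlgError:
        score_chi2 = np.nan

    beta = np.zeros(pa)
    ll = ll0
    n_iter = 0
    converged = False
    I = I0
    for n_iter in range(1, max_iter + 1):
        ll_cur, U, I = _cox_pass(cdata, beta, ties)
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            if n_iter > 1:
                # information degenerated along the path (e.g. separation);
                # take a damped pseudo-inverse step and let the coefficient
                # cap below flag the problem
                step = np.linalg.pinv(I) @ U
            else:
                corr = np.corrcoef(Xa, rowvar=False)
                act_names = list(np.array(names)[active])
                pairs = [
                    (act_names[i], act_names[j])
                    for i in range(len(act_names))
                    for j in range(i + 1, len(act_names))
                    if abs(corr[i, j]) > 0.999
                ]
                raise np.linalg.LinAlgError(
                    "singular information matrix; collinear covariates: "
                    f"{pairs or 'unknown'}"
                )
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(25):
            beta_new = beta + scale * step
            ll_new, _, _ = _cox_pass(cdata, beta_new, ties)
            if ll_new >= ll_cur - 1e-12:
                break
            scale /= 2.0
        beta = beta_new
        if np.max(np.abs(beta)) > 15.0:
            beta = np.clip(beta, -15.0, 15.0)
            flags.append("monotone_likelihood")
            warnings.warn(
                "monotone partial likelihood (perfect separation?); "
                "coefficients capped at |15|",
                stacklevel=2,
            )
            ll = ll_new
            break
        if np.max(np.abs(scale * step)) < 1e-9 or abs(ll_new - ll_cur) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    ll_final, U, I, (st_t, st_R, st_V, st_s) = _cox_pass(cdata, beta, ties, want_resid=True)
    try:
        cov_a = np.linalg.inv(I)
    except np.linalg.LinAlgError:
        cov_a = np.linalg.pinv(I)
        flags.append("pinv_covariance")

    # re-expand dropped zero-variance covariates: beta 0, se inf
    p = len(names)
    beta_full = np.zeros(p)
    cov_full = np.zeros((p, p))
    R_full = np.zeros((len(st_t), p))
    V_full = np.zeros((len(st_t), p, p))
    info_full = np.zeros((p, p))
    ai = np.flatnonzero(active)
    beta_full[ai] = beta
    cov_full[np.ix_(ai, ai)] = cov_a
    info_full[np.ix_(ai, ai)] = I
    R_full[:, ai] = st_R
    V_full[np.ix_(np.arange(len(st_t)), ai, ai)] = st_V
    for j in np.flatnonzero(~active):
        cov_full[j, j] = np.inf

    return CoxFit(
        names=names,
        beta=beta_full,
        cov=cov_full,
        loglik=float(ll_final),
        loglik_null=float(ll0),
        n=len(stop),
        n_events=cdata.n_events,
        ties=ties,
        converged=converged,
        n_iter=n_iter,
        score_chi2=score_chi2,
        score_df=pa,
        flags=flags,
        schoen_times=st_t,
        schoen_resid=R_full,
        schoen_var=V_full,
        schoen_strata=st_s,
        info=info_full,
        entry=start,
        followup=stop,
        events=event,
    )


# ---------------------------------------------------------------------------
# Schoenfeld / Grambsch-Therneau proportional-hazards diagnostics
# ---------------------------------------------------------------------------


@dataclass
class PHTestResult:
    table: pd.DataFrame
    transform: str

    @property
    def global_p(self) -> float:
        return float(self.table.loc["GLOBAL", "p"])


def _time_transform(fit: CoxFit, transform: str) -> np.ndarray:
    t = fit.schoen_times
    if transform == "identity":
        return t.astype(float)
    if transform == "rank":
        return stats.rankdata(t).astype(float)
    if transform == "km":
        # left-continuous pooled KM of follow-up (delayed-entry aware),
        # evaluated just before each event time
        stop = np.sort(fit.followup)
        entry = np.sort(fit.entry) if fit.entry is not None else None
        tu = np.unique(fit.followup[fit.events == 1])
        n_risk = len(stop) - np.searchsorted(stop, tu, side="left")
        if entry is not None:
            n_risk = n_risk - (len(entry) - np.searchsorted(entry, tu, side="left"))
        d = np.zeros(len(tu))
        np.add.at(d, np.searchsorted(tu, fit.followup[fit.events == 1]), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            surv = np.cumprod(np.where(n_risk > 0, 1.0 - d / n_risk, 1.0))
        surv_before = np.concatenate([[1.0], surv[:-1]])
        return surv_before[np.searchsorted(tu, t)]
    raise ValueError(f"unknown time transform {transform!r}")


def schoenfeld_ph_test(
    fit: CoxFit, transform: str = "km", block: list[str] | None = None
) -> PHTestResult:
    """Score test of proportional hazards from Schoenfeld residuals.

    Tests whether coefficients drift with (a transform of) event time by
    scoring the time-varying coefficient model ``beta(t) = beta + theta
    g(t)`` at ``theta = 0``.  With centered transformed event times ``c``,
    Schoenfeld residuals ``r_k`` and per-event risk-set covariance
    ``V_k``, the score is ``u = sum c_k r_k`` with variance
    ``D = sum c_k^2 V_k - (sum c_k V_k) I^{-1} (sum c_k V_k)'`` (the
    second term accounts for beta having been estimated); the global
    statistic ``u' D^{-1} u`` and per-covariate ``u_j^2 / D_jj`` are
    chi-square under the null.  ``block`` adds the joint test for a named
    subset of covariates (e.g. the exposure terms only).
    """
    if fit.schoen_resid is None or len(fit.schoen_times) < 2:
        raise ValueError("need at least two events for the Schoenfeld test")
    active = np.isfinite(np.diag(fit.cov))
    names = [n for n, a in zip(fit.names, active) if a]
    R = fit.schoen_resid[:, active]
    V = fit.schoen_var[np.ix_(np.arange(len(fit.schoen_times)), active, active)]
    d, p = R.shape
    if d < p:
        raise ValueError(f"fewer events ({d}) than covariates ({p})")
    g = _time_transform(fit, transform)
    c = g - g.mean()
    u = R.T @ c
    I = fit.info[np.ix_(active, active)]
    cV = np.einsum("k,kij->ij", c, V)
    ccV = np.einsum("k,kij->ij", c * c, V)
    try:
        D = ccV - cV @ np.linalg.solve(I, cV)
    except np.linalg.LinAlgError:
        D = ccV - cV @ np.linalg.pinv(I) @ cV

    def _quad(uu, DD):
        if uu.size == 0:
            return 0.0
        try:
            return float(uu @ np.linalg.solve(DD, uu))
        except np.linalg.LinAlgError:
            return float(uu @ np.linalg.pinv(DD) @ uu)

    rows = {}
    for j, name in enumerate(names):
        chi2 = float(u[j] ** 2 / D[j, j]) if D[j, j] > 0 else 0.0
        rows[name] = (chi2, 1, stats.chi2.sf(chi2, 1))
    chi2_g = _quad(u, D)
    rows["GLOBAL"] = (chi2_g, p, stats.chi2.sf(chi2_g, p))
    if block is not None:
        bidx = [names.index(b) for b in block if b in names]
        chi2_b = _quad(u[bidx], D[np.ix_(bidx, bidx)])
        rows["BLOCK"] = (chi2_b, len(bidx), stats.chi2.sf(chi2_b, max(len(bidx), 1)))
    table = pd.DataFrame(rows, index=["chi2", "df", "p"]).T
    table["df"] = table["df"].astype(int)
    return PHTestResult(table=table, transform=transform)


# ---------------------------------------------------------------------------
# Kaplan-Meier and (landmark) log-rank
# ---------------------------------------------------------------------------


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit estimate over the distinct event/censoring times."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    tu = np.unique(t)
    n_at = len(t) - np.searchsorted(t, tu, side="left")
    d = np.zeros(len(tu))
    cidx = np.searchsorted(tu, t[e == 1])
    np.add.at(d, cidx, 1.0)
    cens = np.zeros(len(tu))
    np.add.at(cens, np.searchsorted(tu, t[e == 0]), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at > 0, 1.0 - d / n_at, 1.0)
    surv = np.cumprod(frac)
    return pd.DataFrame(
        {"time": tu, "n_risk": n_at, "n_events": d, "n_censored": cens, "survival": surv}
    )


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float
    observed: pd.Series
    expected: pd.Series
    curves: dict
    window: tuple | None = None
    warning: str | None = None


def km_logrank(
    data: pd.DataFrame,
    group_col: str,
    time_col: str = "followup_days",
    event_col: str = "event",
    window: tuple | None = None,
) -> LogrankResult:
    """Kaplan-Meier curves and the log-rank test, optionally on a landmark
    window ``(t0, t1]``.

    With a window, only subjects still at risk at ``t0`` enter (landmark
    conditioning), events after ``t1`` are censored at ``t1``, and the KM
    curves are conditional survival from ``t0``.
    """
    t = data[time_col].to_numpy(dtype=float)
    e = data[event_col].to_numpy(dtype=float).astype(int)
    g = data[group_col].to_numpy()
    if window is not None:
        t0, t1 = window
        keep = t > t0
        t, e, g = t[keep], e[keep], g[keep]
        if t1 is not None and np.isfinite(t1):
            beyond = t > t1
            e = np.where(beyond, 0, e)
            t = np.minimum(t, t1)
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    G = len(levels)
    ev_times = np.unique(t[e == 1])
    warning = None
    curves = {
        lev: km_curve(t[g == lev], e[g == lev]) for lev in levels
    }
    if len(ev_times) == 0:
        warning = "no events in window; log-rank statistic set to 0"
        warnings.warn(warning, stacklevel=2)
        zero = pd.Series(np.zeros(G), index=levels)
        return LogrankResult(0.0, G - 1, 1.0, zero, zero, curves, window, warning)
    # at-risk and event counts per group at each event time
    O = np.zeros(G)
    Ex = np.zeros(G)
    V = np.zeros((G, G))
    n_g = np.zeros((G, len(ev_times)))
    d_g = np.zeros((G, len(ev_times)))
    for a, lev in enumerate(levels):
        tg = np.sort(t[g == lev])
        n_g[a] = len(tg) - np.searchsorted(tg, ev_times, side="left")
        tg_ev = t[(g == lev) & (e == 1)]
        np.add.at(d_g[a], np.searchsorted(ev_times, tg_ev), 1.0)
    N = n_g.sum(axis=0)
    D = d_g.sum(axis=0)
    w = n_g / N
    O = d_g.sum(axis=1)
    Ex = (D * w).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(N > 1, D * (N - D) / (N - 1), 0.0)
    for a in range(G):
        for b in range(G):
            if a == b:
                V[a, b] = np.sum(scale * w[a] * (1.0 - w[a]))
            else:
                V[a, b] = -np.sum(scale * w[a] * w[b])
    diff = (O - Ex)[:-1]
    Vred = V[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vred, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vred) @ diff)
    df = G - 1
    return LogrankResult(
        chi2=chi2,
        df=df,
        p=float(stats.chi2.sf(chi2, df)),
        observed=pd.Series(O, index=levels),
        expected=pd.Series(Ex, index=levels),
        curves=curves,
        window=window,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Episode splitting and the two-interval exposure model
# ---------------------------------------------------------------------------


def episode_split(
    data: pd.DataFrame,
    cutpoint_days: float = 7.0,
    time_col: str = "followup_days",
    event_col: str = "event",
) -> pd.DataFrame:
    """Split each subject's follow-up at the cutpoint into (start, stop] rows.

    A subject followed beyond the cutpoint yields an early row
    ``(0, cutpoint]`` with ``event=0`` and a late row ``(cutpoint, stop]``
    carrying the terminal status.  Follow-up at or below the cutpoint yields
    a single early row (closed-right convention: a death at exactly the
    cutpoint is an early-interval death).  All other columns are copied to
    both rows; total person-time is conserved exactly.
    """
    t = data[time_col].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("follow-up times must be > 0")
    e = data[event_col].to_numpy(dtype=float).astype(int)
    late_mask = t > cutpoint_days
    early = data.copy()
    early["start"] = 0.0
    early["stop"] = np.minimum(t, cutpoint_days)
    early["event"] = np.where(late_mask, 0, e)
    early["interval"] = "early"
    late = data.loc[late_mask].copy()
    late["start"] = cutpoint_days
    late["stop"] = t[late_mask]
    late["event"] = e[late_mask]
    late["interval"] = "late"
    out = pd.concat([early, late], ignore_index=True)
    if time_col != "stop":
        out = out.drop(columns=[time_col])
    return out


def _exposure_design(split: pd.DataFrame, exposure: str, reference=None):
    """Add exposure-by-interval interaction columns; return term names/levels."""
    col = split[exposure]
    is_continuous = pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col)
    early = (split["interval"] == "early").to_numpy(dtype=float)
    late = 1.0 - early
    terms = []
    if is_continuous:
        v = col.to_numpy(dtype=float)
        for itv, ind in (("early", early), ("late", late)):
            name = f"{exposure}:{itv}"
            split[name] = v * ind
            terms.append((None, itv, name))
        levels = [None]
        ref = None
    else:
        vals = col.astype(str)
        levels = list(pd.unique(vals))
        if reference is None:
            ref = "LSI" if "LSI" in levels else sorted(levels)[0]
        else:
            ref = str(reference)
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not present in {exposure!r}")
        levels = [ref] + sorted(set(levels) - {ref})
        for lev in levels[1:]:
            ind_lev = (vals == lev).to_numpy(dtype=float)
            for itv, ind in (("early", early), ("late", late)):
                name = f"{exposure}[{lev}]:{itv}"
                split[name] = ind_lev * ind
                terms.append((lev, itv, name))
    return terms, levels, ref, is_continuous


@dataclass
class TimeStratifiedResult:
    table: pd.DataFrame
    fit: CoxFit
    ph_test: PHTestResult | None
    exposure_terms: list[str]
    unstratified_fit: CoxFit | None = None
    unstratified_ph_test: PHTestResult | None = None


def time_stratified_model(
    outcomes: pd.DataFrame,
    exposure: str,
    covariates: list[str] | tuple = (),
    cutpoint_days: float = 7.0,
    reference=None,
    time_col: str = "followup_days",
    event_col: str = "event",
    ties: str = "breslow",
    include_unstratified: bool = True,
    include_ph_test: bool = True,
    ph_transform: str = "km",
) -> TimeStratifiedResult:
    """Two-interval Cox model with exposure-by-interval interactions.

    Follow-up is episode-split at the cutpoint; one Cox model is fitted on
    the split records with the baseline hazard stratified by interval and a
    separate exposure coefficient per interval, while adjustment covariates
    keep a single time-fixed coefficient.  A categorical exposure uses LSI
    (when present) as the reference; a numeric exposure is modeled per
    1-unit increase.  The companion unstratified fit (single exposure
    coefficient, no splitting) feeds the proportional-hazards contrast.
    """
    missing = [c for c in covariates if c not in outcomes.columns]
    if missing:
        raise ValueError(f"adjustment covariates absent from data: {missing}")
    split = episode_split(outcomes, cutpoint_days, time_col=time_col, event_col=event_col)
    terms, levels, ref, is_cont = _exposure_design(split, exposure, reference)
    term_names = [t[2] for t in terms]
    fit = fit_cox(
        split,
        term_names + list(covariates),
        start_col="start",
        stop_col="stop",
        event_col="event",
        strata_col="interval",
        ties=ties,
    )
    ph = (
        schoenfeld_ph_test(fit, transform=ph_transform, block=term_names)
        if include_ph_test
        else None
    )
    rows = []
    summ = fit.summary()
    for lev, itv, name in terms:
        r = summ.loc[name]
        rows.append(
            {
                "exposure": exposure,
                "level": "per 1-unit" if is_cont else lev,
                "interval": "0-7 days" if itv == "early" else ">7 days",
                "hr": r["hr"],
                "hr_lo95": r["hr_lo95"],
                "hr_hi95": r["hr_hi95"],
                "p": r["p"],
            }
        )
    table = pd.DataFrame(rows)

    unstrat_fit = unstrat_ph = None
    if include_unstratified:
        df = outcomes.copy()
        if is_cont:
            u_terms = [exposure]
        else:
            vals = df[exposure].astype(str)
            u_terms = []
            for lev in levels[1:]:
                nm = f"{exposure}[{lev}]"
                df[nm] = (vals == lev).astype(float)
                u_terms.append(nm)
        unstrat_fit = fit_cox(
            df,
            u_terms + list(covariates),
            stop_col=time_col,
            event_col=event_col,
            ties=ties,
        )
        unstrat_ph = schoenfeld_ph_test(unstrat_fit, transform=ph_transform, block=u_terms)
    return TimeStratifiedResult(
        table=table,
        fit=fit,
        ph_test=ph,
        exposure_terms=term_names,
        unstratified_fit=unstrat_fit,
        unstratified_ph_test=unstrat_ph,
    )


# ---------------------------------------------------------------------------
# Subgroup / interaction scan
# ---------------------------------------------------------------------------


@dataclass
class SubgroupScanResult:
    table: pd.DataFrame
    interactions: pd.DataFrame


def subgroup_scan(
    outcomes: pd.DataFrame,
    exposure: str,
    subgroup_cols: list[str],
    covariates: list[str] | tuple = (),
    cutpoint_days: float = 7.0,
    reference=None,
    time_col: str = "followup_days",
    event_col: str = "event",
    ties: str = "breslow",
) -> SubgroupScanResult:
    """Per-subgroup time-stratified exposure fits plus interaction tests.

    For each subgroup field the exposure model is refitted within each
    level (levels without events are skipped with a warning), and a pooled
    model adds exposure x interval x subgroup product terms whose joint
    Wald test gives the interaction p-value.
    """
    rows = []
    inter_rows = []
    for sg in subgroup_cols:
        if sg not in outcomes.columns:
            raise ValueError(f"subgroup column {sg!r} absent from data")
        levels = list(pd.unique(outcomes[sg].astype(str)))
        for lev in sorted(levels):
            sub = outcomes.loc[outcomes[sg].astype(str) == lev]
            if sub[event_col].sum() == 0 or len(sub) == 0:
                warnings.warn(
                    f"subgroup {sg}={lev} has no events; skipped", stacklevel=2
                )
                continue
            covs = [c for c in covariates if c != sg and sub[c].nunique() > 1]
            try:
                res = time_stratified_model(
                    sub,
                    exposure,
                    covariates=covs,
                    cutpoint_days=cutpoint_days,
                    reference=reference,
                    time_col=time_col,
                    event_col=event_col,
                    ties=ties,
                    include_unstratified=False,
                    include_ph_test=False,
                )
            except (np.linalg.LinAlgError, ValueError) as err:
                warnings.warn(
                    f"subgroup {sg}={lev}: degenerate fit skipped ({err})",
                    stacklevel=2,
                )
                continue
            t = res.table.copy()
            t.insert(0, "subgroup", sg)
            t.insert(1, "subgroup_level", lev)
            t["n"] = len(sub)
            t["n_events"] = int(sub[event_col].sum())
            rows.append(t)
        # pooled interaction model
        split = episode_split(outcomes, cutpoint_days, time_col=time_col, event_col=event_col)
        terms, _, _, _ = _exposure_design(split, exposure, reference)
        term_names = [t[2] for t in terms]
        sg_vals = split[sg].astype(str)
        sg_levels = sorted(pd.unique(sg_vals))
        sg_dummies = []
        for lev in sg_levels[1:]:
            nm = f"{sg}[{lev}]"
            split[nm] = (sg_vals == lev).astype(float)
            sg_dummies.append(nm)
        inter_terms = []
        for lev_nm in sg_dummies:
            for t_nm in term_names:
                nm = f"{t_nm}*{lev_nm}"
                split[nm] = split[t_nm] * split[lev_nm]
                inter_terms.append(nm)
        covs = [c for c in covariates if c != sg]
        fit = fit_cox(
            split,
            term_names + sg_dummies + covs + inter_terms,
            start_col="start",
            stop_col="stop",
            event_col="event",
            strata_col="interval",
            ties=ties,
        )
        idx = [fit.names.index(nm) for nm in inter_terms]
        finite = [i for i in idx if np.isfinite(fit.cov[i, i])]
        b = fit.beta[finite]
        C = fit.cov[np.ix_(finite, finite)]
        if len(finite):
            try:
                w = float(b @ np.linalg.solve(C, b))
            except np.linalg.LinAlgError:
                w = float(b @ np.linalg.pinv(C) @ b)
            p = float(stats.chi2.sf(w, len(finite)))
        else:
            w, p = 0.0, 1.0
        inter_rows.append({"subgroup": sg, "wald_chi2": w, "df": len(finite), "p": p})
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["subgroup", "subgroup_level", "exposure", "level", "interval",
                     "hr", "hr_lo95", "hr_hi95", "p", "n", "n_events"]
        )
    )
    return SubgroupScanResult(table=table, interactions=pd.DataFrame(inter_rows))


# ---------------------------------------------------------------------------
# Table-1 style descriptives
# ---------------------------------------------------------------------------


def descriptives_by_class(
    data: pd.DataFrame,
    class_col: str,
    continuous: list[str] = (),
    binary: list[str] = (),
    continuous_test: str = "anova",
) -> pd.DataFrame:
    """Baseline comparison across trajectory classes.

    Continuous variables: mean (SD) with ANOVA, or median (IQR) with
    Kruskal-Wallis when ``continuous_test='kruskal'``.  Binary variables:
    n (%) with a chi-square test.
    """
    levels = sorted(pd.unique(data[class_col].astype(str)))
    groups = {lev: data.loc[data[class_col].astype(str) == lev] for lev in levels}
    rows = []
    for var in continuous:
        samples = [g[var].dropna().to_numpy(dtype=float) for g in groups.values()]
        if continuous_test == "kruskal":
            stat, p = stats.kruskal(*samples)
            summ = {
                lev: f"{np.median(s):.1f} ({np.percentile(s, 25):.1f}, {np.percentile(s, 75):.1f})"
                for lev, s in zip(levels, samples)
            }
            test = "kruskal"
        else:
            stat, p = stats.f_oneway(*samples)
            summ = {lev: f"{s.mean():.1f} ± {s.std(ddof=1):.1f}" for lev, s in zip(levels, samples)}
            test = "anova"
        rows.append({"variable": var, **summ, "test": test, "p": p})
    for var in binary:
        tab = pd.crosstab(data[class_col].astype(str), data[var])
        stat, p, _, _ = stats.chi2_contingency(tab)
        summ = {}
        for lev in levels:
            g = groups[lev][var]
            summ[lev] = f"{int(g.sum())} ({100.0 * g.mean():.1f})"
        rows.append({"variable": var, **summ, "test": "chi2", "p": p})
    return pd.DataFrame(rows)
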