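"""Cox engine, log-rank, Schoenfeld diagnostics, episode splitting,
the two-interval exposure model, and subgroup scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import tygdyn as tg
from tests.conftest import make_survival_frame


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------


def test_toy_cox_matches_brute_force_partial_likelihood():
    """Four subjects, one binary covariate: the Newton-Raphson estimate
    equals the maximizer of the hand-written partial likelihood."""
    df = pd.DataFrame(
        {
            "followup_days": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 0, 1],
            "x": [1.0, 0.0, 1.0, 0.0],
        }
    )
    fit = tg.fit_cox(df, ["x"])

    def neg_pl(beta):
        e = np.exp(beta)
        # risk sets: t=1 {all}, t=2 {2,3,4}, t=4 {4}
        return -(
            beta - np.log(2 * e + 2) + 0.0 - np.log(e + 2) + 0.0 - np.log(1.0)
        )

    res = optimize.minimize_scalar(neg_pl, bracket=(-2.0, 0.0, 2.0), method="brent",
                                   options={"xtol": 1e-12})
    assert fit.beta[0] == pytest.approx(res.x, abs=1e-8)


def test_constant_covariate_reports_null_hazard_ratio():
    df = make_survival_frame(np.random.default_rng(0), n=100, log_hr=0.5)
    df["const"] = 1.0
    with pytest.warns(UserWarning, match="zero variance"):
        fit = tg.fit_cox(df, ["x", "const"])
    s = fit.summary()
    assert s.loc["const", "coef"] == 0.0
    assert s.loc["const", "hr"] == 1.0
    assert np.isinf(s.loc["const", "se"])
    assert np.isfinite(s.loc["x", "se"])


def test_cox_agrees_with_lifelines_reference():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(3)
    n = 500
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.35, n).astype(float)
    lam = 0.08 * np.exp(0.6 * x1 - 0.4 * x2)
    t_ev = rng.exponential(1 / lam)
    c = rng.exponential(10, n)
    df = pd.DataFrame(
        {
            "followup_days": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
            "x1": x1,
            "x2": x2,
        }
    )
    fit = tg.fit_cox(df, ["x1", "x2"])
    ref = CoxPHFitter().fit(df, duration_col="followup_days", event_col="event")
    # agreement is limited by the reference fitter's own convergence
    # tolerance (its score norm at the returned solution is ~1e-4)
    np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-4)
    np.testing.assert_allclose(fit.se, ref.standard_errors_.values, atol=1e-4)
    assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)


def test_counting_process_agrees_with_lifelines_time_varying():
    from lifelines import CoxTimeVaryingFitter

    rng = np.random.default_rng(4)
    df = make_survival_frame(rng, n=300, log_hr=0.5)
    split = tg.episode_split(df, 4.0)
    fit = tg.fit_cox(split, ["x"], start_col="start", stop_col="stop")
    ctv = CoxTimeVaryingFitter().fit(
        split[["start", "stop", "event", "x"]],
        start_col="start", stop_col="stop", event_col="event",
    )
    np.testing.assert_allclose(fit.beta, ctv.params_.values, atol=1e-6)


def test_efron_ties_match_lifelines_on_tied_data():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(5)
    n = 200
    x = rng.normal(size=n)
    t_ev = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.4 * x))))  # heavy ties
    c = np.ceil(rng.exponential(8, n)) + 0.5
    df = pd.DataFrame(
        {
            "followup_days": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
            "x": x,
        }
    )
    fit = tg.fit_cox(df, ["x"], ties="efron")
    ref = CoxPHFitter().fit(df, duration_col="followup_days", event_col="event")
    np.testing.assert_allclose(fit.beta, ref.params_.values, atol=1e-6)


def test_score_test_equals_logrank_chi_square():
    df = make_survival_frame(np.random.default_rng(6), n=300, log_hr=0.4)
    assert df["followup_days"].duplicated().sum() == 0  # tie-free by construction
    fit = tg.fit_cox(df, ["x"])
    lr = tg.km_logrank(df, "grp")
    assert fit.score_chi2 == pytest.approx(lr.chi2, abs=1e-8)


def test_recovery_of_true_log_hazard_ratio():
    rng = np.random.default_rng(7)
    betas = []
    for _ in range(10):
        df = make_survival_frame(rng, n=1500, log_hr=0.4)
        betas.append(tg.fit_cox(df, ["x"]).beta[0])
    mc_se = np.std(betas, ddof=1) / np.sqrt(len(betas))
    assert abs(np.mean(betas) - 0.4) <= 3 * mc_se


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def test_identical_groups_give_zero_logrank():
    df = make_survival_frame(np.random.default_rng(8), n=120)
    dup = pd.concat(
        [df.assign(g="a"), df.assign(g="b")], ignore_index=True
    )
    res = tg.km_logrank(dup, "g")
    assert res.chi2 == pytest.approx(0.0, abs=1e-10)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_lifelines():
    from lifelines.statistics import multivariate_logrank_test

    df = make_survival_frame(np.random.default_rng(9), n=250, log_hr=0.6)
    res = tg.km_logrank(df, "grp")
    ref = multivariate_logrank_test(df["followup_days"], df["grp"], df["event"])
    assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-8)


def test_landmark_window_conditions_on_survivors():
    df = pd.DataFrame(
        {
            "followup_days": [2.0, 3.0, 8.0, 9.0, 10.0, 12.0],
            "event": [1, 1, 1, 0, 1, 0],
            "g": ["a", "b", "a", "b", "a", "b"],
        }
    )
    res = tg.km_logrank(df, "g", window=(7.0, None))
    # only the four subjects with follow-up beyond day 7 enter
    assert int(res.observed.sum()) == 2
    early = tg.km_logrank(df, "g", window=(0.0, 7.0))
    assert int(early.observed.sum()) == 2  # the two early deaths


def test_no_events_in_window_warns_and_returns_null():
    df = pd.DataFrame(
        {
            "followup_days": [8.0, 9.0, 10.0, 11.0],
            "event": [0, 0, 1, 1],
            "g": ["a", "b", "a", "b"],
        }
    )
    with pytest.warns(UserWarning, match="no events"):
        res = tg.km_logrank(df, "g", window=(0.0, 7.0))
    assert res.chi2 == 0.0 and res.p == 1.0


# ---------------------------------------------------------------------------
# Episode splitting
# ---------------------------------------------------------------------------


def test_episode_split_worked_examples():
    df = pd.DataFrame(
        {
            "patient_id": ["death10", "death3", "discharge7"],
            "followup_days": [10.0, 3.0, 7.0],
            "event": [1, 1, 0],
        }
    )
    sp = tg.episode_split(df, 7.0).set_index(["patient_id", "interval"])
    assert sp.loc[("death10", "early")][["start", "stop", "event"]].tolist() == [0.0, 7.0, 0]
    assert sp.loc[("death10", "late")][["start", "stop", "event"]].tolist() == [7.0, 10.0, 1]
    assert sp.loc[("death3", "early")][["start", "stop", "event"]].tolist() == [0.0, 3.0, 1]
    # exactly at the cutpoint: single early row with the terminal status
    assert sp.loc[("discharge7", "early")][["start", "stop", "event"]].tolist() == [0.0, 7.0, 0]
    assert ("discharge7", "late") not in sp.index
    death7 = tg.episode_split(
        pd.DataFrame({"patient_id": ["d7"], "followup_days": [7.0], "event": [1]}), 7.0
    )
    assert len(death7) == 1 and death7["event"].iloc[0] == 1


def test_episode_split_conserves_person_time_and_beta():
    df = make_survival_frame(np.random.default_rng(10), n=400, log_hr=0.5)
    sp = tg.episode_split(df, 7.0)
    assert (sp["stop"] - sp["start"]).sum() == pytest.approx(
        df["followup_days"].sum(), abs=0.0
    )
    beta_unsplit = tg.fit_cox(df, ["x"]).beta[0]
    beta_split = tg.fit_cox(sp, ["x"], start_col="start", stop_col="stop").beta[0]
    assert beta_split == pytest.approx(beta_unsplit, abs=1e-8)


# ---------------------------------------------------------------------------
# Schoenfeld diagnostics
# ---------------------------------------------------------------------------


def test_schoenfeld_two_events_finite():
    df = pd.DataFrame(
        {
            "followup_days": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 0, 1, 0],
            "x": [1.0, 0.0, 0.0, 1.0],
        }
    )
    fit = tg.fit_cox(df, ["x"])
    ph = tg.schoenfeld_ph_test(fit)
    assert np.isfinite(ph.table["chi2"]).all()
    assert np.isfinite(ph.table["p"]).all()


def test_schoenfeld_detects_strong_step_violation():
    rng = np.random.default_rng(12)
    n = 3000
    x = rng.binomial(1, 0.5, n).astype(float)
    u = -np.log(rng.uniform(size=n))
    lam1 = np.full(n, 0.05)
    lam2 = 0.05 * np.exp(np.log(2.5) * x)
    t_ev = np.where(u <= lam1 * 7, u / lam1, 7 + (u - lam1 * 7) / lam2)
    df = pd.DataFrame({"followup_days": t_ev, "event": np.ones(n, dtype=int), "x": x})
    fit = tg.fit_cox(df, ["x"])
    assert tg.schoenfeld_ph_test(fit).table.loc["x", "p"] < 0.01
    # after episode splitting with per-interval coefficients the violation is gone
    sp = tg.episode_split(df, 7.0)
    sp["x_early"] = sp["x"] * (sp["interval"] == "early")
    sp["x_late"] = sp["x"] * (sp["interval"] == "late")
    fit2 = tg.fit_cox(
        sp, ["x_early", "x_late"], start_col="start", stop_col="stop",
        strata_col="interval",
    )
    ph2 = tg.schoenfeld_ph_test(fit2, block=["x_early", "x_late"])
    assert ph2.table.loc["BLOCK", "p"] > 0.05


def test_schoenfeld_errors_when_underdetermined():
    df = pd.DataFrame(
        {
            "followup_days": [1.0, 2.0, 3.0],
            "event": [1, 0, 0],
            "x1": [1.0, 0.0, 1.0],
            "x2": [0.3, -0.2, 0.1],
        }
    )
    with pytest.raises(ValueError):
        fit = tg.fit_cox(df, ["x1", "x2"])
        tg.schoenfeld_ph_test(fit)


# ---------------------------------------------------------------------------
# Two-interval model and subgroups
# ---------------------------------------------------------------------------


def _null_trajectory_frame(rng, n=900):
    df = make_survival_frame(rng, n=n, base_rate=0.05, censor_scale=20.0)
    df["trajectory"] = rng.choice(["LSI", "MI", "PH"], size=n)
    df["sg"] = rng.binomial(1, 0.5, n)
    return df


def test_time_stratified_null_exposure_covers_one():
    rng = np.random.default_rng(13)
    covered = total = 0
    for _ in range(10):
        df = _null_trajectory_frame(rng)
        res = tg.time_stratified_model(df, "trajectory", include_unstratified=False)
        assert set(res.table["interval"]) == {"0-7 days", ">7 days"}
        assert len(res.table) == 4  # MI and PH in each interval, LSI reference
        covered += ((res.table["hr_lo95"] < 1.0) & (res.table["hr_hi95"] > 1.0)).sum()
        total += len(res.table)
    # nominal 95% coverage of the null across 40 interval-level CIs
    assert covered / total >= 0.85


def test_time_stratified_recovers_interval_specific_effect():
    cfg = tg.SyntheticCohortConfig(n_patients=4000, seed=31)
    coh = tg.generate_cohort(cfg)
    df = coh.outcomes.merge(coh.truth[["patient_id", "true_class"]], on="patient_id")
    df["trajectory"] = np.array(["LSI", "MI", "PH"])[df["true_class"]]
    res = tg.time_stratified_model(
        df, "trajectory", covariates=["age", "male", "dm", "htn", "sofa", "mv"]
    )
    t = res.table.set_index(["level", "interval"])
    early = t.loc[("PH", "0-7 days")]
    late = t.loc[("PH", ">7 days")]
    assert early["hr_lo95"] < 1.0 < early["hr_hi95"]
    assert late["hr_lo95"] < 1.51 < late["hr_hi95"]


def test_tbm_exposure_is_modeled_per_unit():
    df = _null_trajectory_frame(np.random.default_rng(14))
    df["TBM8p7"] = np.random.default_rng(15).exponential(0.3, len(df))
    res = tg.time_stratified_model(df, "TBM8p7")
    assert set(res.table["level"]) == {"per 1-unit"}
    assert len(res.table) == 2


def test_missing_covariates_error_names_them():
    df = _null_trajectory_frame(np.random.default_rng(16))
    with pytest.raises(ValueError, match="nope"):
        tg.time_stratified_model(df, "trajectory", covariates=["nope"])


def test_duplicated_database_subgroup_is_exactly_symmetric():
    df = _null_trajectory_frame(np.random.default_rng(17), n=500)
    dup = pd.concat(
        [df.assign(source="one"), df.assign(source="two")], ignore_index=True
    )
    res = tg.subgroup_scan(dup, "trajectory", ["source"])
    t = res.table.set_index(["subgroup_level", "level", "interval"])["hr"]
    for (lev, itv) in {(l, i) for (_, l, i) in t.index}:
        assert t.loc[("one", lev, itv)] == pytest.approx(t.loc[("two", lev, itv)], rel=1e-10)
    assert res.interactions["p"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_subgroup_interaction_detects_heterogeneity():
    rng = np.random.default_rng(18)
    n = 4000
    x = rng.binomial(1, 0.5, n).astype(float)
    sg = rng.binomial(1, 0.5, n)
    u = -np.log(rng.uniform(size=n))
    lam1 = np.full(n, 0.02)
    lam2 = 0.03 * np.exp(np.log(2.0) * x * sg)  # late effect only in sg=1
    t_ev = np.where(u <= lam1 * 7, u / lam1, 7 + (u - lam1 * 7) / lam2)
    c = rng.exponential(25, n)
    df = pd.DataFrame(
        {
            "followup_days": np.minimum(t_ev, c),
            "event": (t_ev <= c).astype(int),
            "exposed": np.where(x > 0, "yes", "no"),
            "sg": sg,
        }
    )
    res = tg.subgroup_scan(df, "exposed", ["sg"], reference="no")
    assert res.interactions["p"].iloc[0] < 0.05


def test_descriptives_table_layout(small_cohort):
    df = small_cohort.outcomes.copy()
    df["trajectory"] = np.array(["LSI", "MI", "PH"])[
        small_cohort.truth.set_index("patient_id").loc[df["patient_id"], "true_class"]
    ]
    table = tg.descriptives_by_class(
        df, "trajectory", continuous=["age", "sofa"], binary=["dm", "htn"]
    )
    assert list(table["variable"]) == ["age", "sofa", "dm", "htn"]
    assert {"LSI", "MI", "PH"} <= set(table.columns)
    assert table["p"].between(0, 1).all()
    # diabetes prevalence rises across classes by construction
    dm_row = table.set_index("variable").loc["dm"]
    assert dm_row["p"] < 0.05
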