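"""Growth-mixture EM: degenerate closed forms, enumeration oracles,
entropy, labeling, and class recovery on separated data."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import tygdyn as tg
from tygdyn.lcgm import _INDEX_CENTER


def _z_series(values, pid="P"):
    s = tg.BiomarkerSeries(pid, "DB", values)
    s.z_values = np.asarray(values, dtype=float)
    return s


def _two_class_series(n=200, sep=3.0, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    truth = rng.integers(0, 2, size=n)
    series = []
    for i in range(n):
        m = rng.integers(2, 8)
        mu = sep if truth[i] else -sep
        series.append(_z_series(mu + rng.normal(0, sd, m), pid=f"P{i}"))
    return series, truth


def test_k1_fit_equals_pooled_ols_closed_form():
    rng = np.random.default_rng(1)
    series = [
        _z_series(rng.normal(0.2 * np.arange(1, m + 1), 0.5), pid=f"P{i}")
        for i, m in enumerate(rng.integers(2, 8, size=60))
    ]
    model = tg.fit_lcgm(series, K=1, degree=2, seed=0, n_starts=1)
    # pooled OLS on the same centered polynomial basis
    t = np.concatenate([np.arange(1, s.n + 1, dtype=float) for s in series])
    z = np.concatenate([s.z_values for s in series])
    X = np.vander(t - _INDEX_CENTER, 3, increasing=True)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    np.testing.assert_allclose(model.coeffs[0], beta, atol=1e-8)
    resid = z - X @ beta
    sigma2 = float(np.mean(resid**2))
    ll = -0.5 * len(z) * np.log(2 * np.pi * sigma2) - len(z) / 2.0
    assert model.loglik == pytest.approx(ll, abs=1e-6)


def test_em_loglik_monotone_every_iteration():
    series, _ = _two_class_series(n=150, sep=1.0, sd=0.8, seed=2)
    model = tg.fit_lcgm(series, K=2, degree=1, seed=0, n_starts=3)
    assert len(model.loglik_path) >= 2
    assert np.all(np.diff(model.loglik_path) >= -1e-8)


def test_two_subject_two_class_enumeration_oracle():
    """Observed-data likelihood equals exhaustive summation over the
    joint latent class assignments of both subjects."""
    series = [_z_series([0.1, -0.2, 0.3], "A"), _z_series([1.2, 1.4], "B")]
    model = tg.TrajectoryModel(
        K=2, degree=1,
        mixing_weights=np.array([0.4, 0.6]),
        coeffs=np.array([[0.0, 0.05], [1.3, -0.02]]),
        residual_var=0.2,
        loglik=np.nan, n_params=6, aic=np.nan, bic=np.nan, sabic=np.nan,
        entropy=np.nan, min_class_fraction=np.nan, converged=True,
        n_iter=0, n_subjects=2,
    )
    ll = tg.mixture_loglik(model, series)

    def normpdf(x, mu, var):
        return np.exp(-((x - mu) ** 2) / (2 * var)) / np.sqrt(2 * np.pi * var)

    total = 0.0
    pi = model.mixing_weights
    for k1 in range(2):
        for k2 in range(2):
            prob = pi[k1] * pi[k2]
            for s, k in zip(series, (k1, k2)):
                t = np.arange(1, s.n + 1) - model.center
                mu = model.coeffs[k, 0] + model.coeffs[k, 1] * t
                prob *= np.prod(normpdf(s.z_values, mu, model.residual_var))
            total += prob
    assert ll == pytest.approx(np.log(total), abs=1e-10)


def test_relative_entropy_limits_and_brute_force():
    assert tg.relative_entropy(np.eye(4)[np.array([0, 1, 2, 3, 0])]) == 1.0
    assert tg.relative_entropy(np.full((10, 3), 1 / 3)) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(0)
    R = rng.dirichlet(np.ones(3), size=25)
    direct = 1.0 - sum(-p * np.log(p) for row in R for p in row if p > 0) / (25 * np.log(3))
    assert tg.relative_entropy(R) == pytest.approx(direct, abs=1e-12)


def test_well_separated_classes_recovered_perfectly():
    series, truth = _two_class_series(n=300, sep=3.0, sd=0.3, seed=4)
    model = tg.fit_lcgm(series, K=2, degree=1, seed=0, n_starts=3)
    assigned = [a.modal_class for a in tg.assign_and_label(model, series)]
    assert adjusted_rand_score(truth, assigned) == 1.0
    assert all(a.posterior.max() > 0.99 for a in tg.assign_and_label(model, series))


def test_labels_follow_trajectory_level_ranks():
    rng = np.random.default_rng(5)
    series = []
    for i, mu in enumerate([-1.0, 0.0, 1.0] * 60):
        series.append(_z_series(mu + rng.normal(0, 0.1, 4), pid=f"P{i}"))
    model = tg.fit_lcgm(series, K=3, degree=1, seed=0, n_starts=3)
    assignments = tg.assign_and_label(model, series)
    for i, mu in enumerate([-1.0, 0.0, 1.0] * 60):
        expected = {-1.0: "LSI", 0.0: "MI", 1.0: "PH"}[mu]
        assert assignments[i].label == expected


def test_labels_invariant_to_class_permutation():
    series, _ = _two_class_series(n=120, sep=2.0, sd=0.4, seed=6)
    model = tg.fit_lcgm(series, K=2, degree=1, seed=0, n_starts=2)
    labels = [a.label for a in tg.assign_and_label(model, series)]
    import dataclasses

    perm = dataclasses.replace(
        model,
        mixing_weights=model.mixing_weights[::-1].copy(),
        coeffs=model.coeffs[::-1].copy(),
    )
    labels_perm = [a.label for a in tg.assign_and_label(perm, series)]
    assert labels == labels_perm


def test_posteriors_sum_to_one_and_no_nan_for_extreme_series():
    series, _ = _two_class_series(n=50, sep=2.0, sd=0.4, seed=8)
    series.append(_z_series([40.0, -40.0], pid="extreme"))
    model = tg.fit_lcgm(series[:-1], K=2, degree=1, seed=0, n_starts=2)
    R = tg.posterior_matrix(model, series)
    assert np.all(np.isfinite(R))
    np.testing.assert_allclose(R.sum(axis=1), 1.0, atol=1e-10)


def test_select_classes_single_candidate_and_floors():
    series, _ = _two_class_series(n=150, sep=2.0, sd=0.5, seed=9)
    sel = tg.select_classes(series, K_range=(3,), n_starts=2, seed=0)
    assert sel.model.K == 3  # single candidate returned unconditionally
    # an impossible entropy floor prunes everything and raises the flag
    with pytest.warns(UserWarning, match="floors"):
        sel2 = tg.select_classes(series, K_range=(2, 3), n_starts=2, seed=0, entropy_floor=1.1)
    assert not sel2.constraints_met


def test_fit_rejects_bad_arguments():
    series, _ = _two_class_series(n=20, seed=10)
    with pytest.raises(ValueError):
        tg.fit_lcgm(series, K=0)
    with pytest.raises(ValueError):
        tg.fit_lcgm(series, K=2, degree=3)
    raw = [tg.BiomarkerSeries("A", "DB", [8.0, 8.1]), tg.BiomarkerSeries("B", "DB", [8.2, 8.3])]
    with pytest.raises(ValueError, match="standardized"):
        tg.fit_lcgm(raw, K=1)
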