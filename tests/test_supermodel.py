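"""Cause-specific Cox supermodel: likelihood oracle, CIF algebra, inference."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from icuai.config import CovariateSpec, LandmarkGrid
from icuai.landmarks import StackedDataset
from icuai.supermodel import (
    CauseSpecificFit,
    constant_hazard_fit,
    fit_cause_specific,
    fit_supermodel,
    lr_test,
    predict_cif,
    predict_cif_batch,
    wald_chi2,
)


def naive_log_partial_likelihood(beta, X, time, event):
    """Textbook tie-free Cox log partial likelihood, O(n^2), independent of
    the fitting code path."""
    ll = 0.0
    eta = X @ beta
    for i in range(len(time)):
        if not event[i]:
            continue
        risk = time >= time[i]
        ll += eta[i] - math.log(np.exp(eta[risk]).sum())
    return ll


def sim_rows(rng, n=200, beta=(0.7,), binary=True, cause="infection", max_u=48.0):
    p = len(beta)
    if binary:
        X = rng.binomial(1, 0.5, (n, p)).astype(float)
    else:
        X = rng.normal(size=(n, p))
    lam = 0.02 * np.exp(X @ np.array(beta))
    tt = rng.exponential(1.0 / lam)
    time = np.minimum(tt, max_u)
    event = tt <= max_u
    df = pd.DataFrame({
        "outcome_time": time,
        "outcome_type": np.where(event, cause, "censored"),
        "t_lm": 48.0,
        "patient_id": [f"p{i}" for i in range(n)],
    })
    for j in range(p):
        df[f"x{j}"] = X[:, j]
    return df


def test_matches_direct_maximisation_on_tie_free_data():
    """Newton solution equals brute-force maximisation of the hand-coded
    log partial likelihood on small tie-free datasets."""
    rng = np.random.default_rng(5)
    for _ in range(5):
        df = sim_rows(rng, n=45, beta=(0.5, -0.8), binary=False)
        assert df.loc[df.outcome_type == "infection", "outcome_time"].is_unique
        fit = fit_cause_specific(df, "infection", covariates=["x0", "x1"])
        X = df[["x0", "x1"]].to_numpy() - fit.centers
        time = df["outcome_time"].to_numpy()
        event = (df["outcome_type"] == "infection").to_numpy()
        res = optimize.minimize(
            lambda b: -naive_log_partial_likelihood(b, X, time, event),
            np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert np.allclose(fit.beta, res.x, atol=1e-6)


def test_duplicated_rows_same_beta_half_variance():
    rng = np.random.default_rng(8)
    df = sim_rows(rng, n=300)
    fit1 = fit_cause_specific(df, "infection", covariates=["x0"])
    df2 = pd.concat([df, df], ignore_index=True)
    fit2 = fit_cause_specific(df2, "infection", covariates=["x0"])
    assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=0.02)
    assert fit2.cov[0, 0] == pytest.approx(fit1.cov[0, 0] / 2.0, rel=0.05)


def test_covariate_shift_invariance():
    """Adding a constant to a covariate changes neither coefficients nor
    predictions (the centred baseline absorbs it)."""
    rng = np.random.default_rng(3)
    df = sim_rows(rng, n=250, beta=(0.6,))
    fit1 = fit_cause_specific(df, "infection", covariates=["x0"])
    shifted = df.copy()
    shifted["x0"] = shifted["x0"] + 100.0
    fit2 = fit_cause_specific(shifted, "infection", covariates=["x0"])
    assert fit2.beta[0] == pytest.approx(fit1.beta[0], abs=1e-9)
    t1, l1 = fit1.baseline[None]
    t2, l2 = fit2.baseline[None]
    assert np.allclose(l1, l2)


def test_cif_closed_form_constant_hazards():
    model = constant_hazard_fit({"infection": 0.01, "death": 0.02}, 48.0)
    pred = predict_cif(model, pd.Series({"t_lm": 48.0}))
    exact = (0.01 / 0.03) * (1 - math.exp(-0.03 * 48))
    assert pred.cif_infection == pytest.approx(exact, abs=1e-3)


def test_cif_zero_hazards_and_single_cause_reduction():
    model = constant_hazard_fit({}, 48.0)
    assert predict_cif(model, pd.Series({"t_lm": 48.0})).cif_infection == 0.0
    lam = 0.015
    model = constant_hazard_fit({"infection": lam}, 48.0)
    pred = predict_cif(model, pd.Series({"t_lm": 48.0}))
    assert pred.cif_infection == pytest.approx(1 - math.exp(-lam * 48), abs=1e-3)


def test_cif_additivity_and_monotonicity():
    """Per-cause CIFs plus overall survival telescope to exactly one, and
    the infection CIF is non-decreasing in the horizon."""
    rng = np.random.default_rng(11)
    df = sim_rows(rng, n=400)
    # add competing causes
    comp = rng.random(len(df))
    df.loc[(comp < 0.25) & (df.outcome_type == "censored"), "outcome_type"] = "death"
    df.loc[(comp > 0.75) & (df.outcome_type == "censored"), "outcome_type"] = "discharge"
    grid = LandmarkGrid()
    stacked = StackedDataset(df.assign(s=0.0, s2=0.0),
                             CovariateSpec(static=("x0",), dynamic=()), grid, 0.0)
    sm = fit_supermodel(stacked, CovariateSpec(static=("x0",), dynamic=(),
                                               include_landmark_terms=False))
    row = df.iloc[0]
    pred = predict_cif(sm, row)
    total = sum(pred.cif_by_cause.values()) + pred.survival[-1]
    assert total == pytest.approx(1.0, abs=1e-10)
    cifs = [predict_cif(sm, row, horizon_h=w).cif_infection for w in (8, 16, 24, 36, 48)]
    assert all(b >= a - 1e-12 for a, b in zip(cifs, cifs[1:]))


def test_cross_check_against_lifelines():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(21)
    df = sim_rows(rng, n=500, beta=(0.7, -0.4), binary=False)
    df["outcome_time"] = np.round(df["outcome_time"] * 4) / 4 + 0.25  # ties
    fit = fit_cause_specific(df, "infection", covariates=["x0", "x1"])
    ldf = pd.DataFrame({
        "T": df["outcome_time"], "E": (df["outcome_type"] == "infection").astype(int),
        "x0": df["x0"], "x1": df["x1"],
    })
    cph = CoxPHFitter().fit(ldf, "T", "E")
    assert np.allclose(fit.beta, cph.params_.values, atol=1e-6)
    assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-6)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)


def test_zero_events_and_collinear_errors():
    rng = np.random.default_rng(2)
    df = sim_rows(rng, n=50)
    with pytest.raises(ValueError):
        fit_cause_specific(df, "death", covariates=["x0"])
    df["x0_copy"] = df["x0"]
    with pytest.raises(np.linalg.LinAlgError) as e:
        fit_cause_specific(df, "infection", covariates=["x0", "x0_copy"])
    assert "x0" in str(e.value)
    df["const"] = 1.0
    with pytest.raises(ValueError):
        fit_cause_specific(df, "infection", covariates=["x0", "const"])


def test_wald_chi2_arithmetic_and_ranking_stability():
    fit = CauseSpecificFit(
        cause="infection", covariates=["a", "b"], beta=np.array([0.5, 0.0]),
        cov=np.diag([0.0625, 0.04]), baseline={None: (np.array([]), np.array([]))},
        loglik=0.0, loglik_null=0.0, n_events=10, converged=True, grad_norm=0.0,
        centers=np.zeros(2), train_min=np.zeros(2), train_max=np.ones(2),
        stratified=False,
    )
    w = wald_chi2(fit)
    assert w["a"] == pytest.approx(4.0)  # (0.5 / 0.25)^2
    assert w["b"] == pytest.approx(0.0)
    rng = np.random.default_rng(4)
    df = sim_rows(rng, n=400, beta=(0.9, 0.1), binary=False)
    f1 = fit_cause_specific(df, "infection", covariates=["x0", "x1"])
    f2 = fit_cause_specific(df, "infection", covariates=["x1", "x0"])
    r1 = wald_chi2(f1).rank(ascending=False)
    r2 = wald_chi2(f2).rank(ascending=False)
    assert r1.sort_index().equals(r2.sort_index())


def _stacked_from(df, include_lm_terms=False):
    spec = CovariateSpec(static=("x0",), dynamic=(), include_landmark_terms=include_lm_terms)
    return StackedDataset(df.assign(s=0.0, s2=0.0), spec, LandmarkGrid(), 0.0), spec


def test_lr_test_nesting_and_null_distribution():
    rng = np.random.default_rng(9)
    pvals = []
    for _ in range(60):
        df = sim_rows(rng, n=150)
        cens = df["outcome_type"] == "censored"
        u = rng.random(len(df))
        df.loc[cens & (u < 0.2), "outcome_type"] = "death"
        df.loc[cens & (u > 0.8), "outcome_type"] = "discharge"
        df["cnn_score"] = rng.random(len(df))  # independent noise score
        stacked, spec = _stacked_from(df)
        base = fit_supermodel(stacked, spec)
        deep = fit_supermodel(stacked, spec.with_cnn(True))
        stat, dof, p = lr_test(base, deep)
        assert dof == 1 and stat >= -1e-9
        pvals.append(p)
    # under the null the LR p-value is uniform
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
    with pytest.raises(ValueError):
        lr_test(deep, base)


def test_stratified_mode_drops_landmark_terms_and_fits():
    rng = np.random.default_rng(13)
    parts = []
    for i, t_lm in enumerate((48.0, 56.0, 64.0)):
        df = sim_rows(rng, n=150)
        df["t_lm"] = t_lm
        df["patient_id"] = df["patient_id"] + f"_{i}"
        parts.append(df)
    df = pd.concat(parts, ignore_index=True)
    df["lm_level"] = df["t_lm"]
    df["s"] = df["t_lm"] / 24.0 - (df["t_lm"] / 24.0).mean()
    df["s2"] = df["s"] ** 2
    spec = CovariateSpec(static=("x0",), dynamic=(), include_landmark_terms=True)
    fit = fit_cause_specific(df, "infection", spec=spec, baseline_mode="stratified")
    assert fit.covariates == ["x0"]  # s, s2 constant within strata -> dropped
    assert set(fit.baseline) == {48.0, 56.0, 64.0}
    pooled = fit_cause_specific(df, "infection", spec=spec, baseline_mode="pooled")
    assert {"s", "s2"} <= set(pooled.covariates)  # pooled keeps configured terms
    assert fit.beta[0] == pytest.approx(pooled.beta[pooled.covariates.index("x0")], abs=0.15)


def test_baseline_cumulative_hazard_is_monotone(events_bundle, spec, grid):
    from icuai.landmarks import ImputationState, build_stacked_dataset

    stacked = build_stacked_dataset(events_bundle, grid, spec)
    df = ImputationState().fit(stacked.df, spec.dynamic).transform(stacked.df)
    stacked = StackedDataset(df, spec, grid, stacked.s_center)
    sm = fit_supermodel(stacked, spec)
    for cause, fit in sm.fits.items():
        times, cum = fit.cumulative_baseline()
        assert np.all(np.diff(cum) >= 0)
        assert np.all(times > 0) and np.all(times <= grid.horizon_h)
        assert fit.converged
    # covariance symmetric PSD
    f = sm.fits["infection"]
    assert np.allclose(f.cov, f.cov.T)
    assert np.all(np.linalg.eigvalsh(f.cov) > -1e-10)
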