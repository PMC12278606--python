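"""Evaluation suite: c-index oracle, Brier algebra, calibration, folds, alerts."""

import numpy as np
import pandas as pd
import pytest

from icuai.config import CovariateSpec, GeneratorConfig, LandmarkGrid
from icuai.cohort import simulate_cohort
from icuai.metrics import (
    CrossValConfig,
    FoldPlan,
    alert_analysis,
    brier,
    calibration,
    cross_validate,
    harrell_c,
    importance_heatmaps,
)

from conftest import make_bundle, make_timeline

W = 48.0


def brute_force_c(pred, time, event):
    """Exhaustive Harrell pair enumeration (the oracle definition)."""
    conc = ties = comp = 0.0
    n = len(pred)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                comp += 1
                if pred[i] > pred[j]:
                    conc += 1
                elif pred[i] == pred[j]:
                    ties += 0.5
    return (conc + ties) / comp if comp else None


def rows_from(time, outcome):
    return pd.DataFrame({"outcome_time": time, "outcome_type": outcome})


def random_rows(rng, n):
    outcome = rng.choice(
        ["infection", "death", "discharge", "censored"], size=n, p=[0.3, 0.15, 0.25, 0.3]
    )
    time = np.where(
        outcome == "censored", W, np.round(rng.uniform(0.5, W, n) * 2) / 2
    )
    pred = np.round(rng.random(n), 2)  # coarse -> prediction ties occur
    return pred, rows_from(time, outcome)


class TestHarrellC:
    def test_perfect_ordering_gives_one(self):
        rows = rows_from([8.0, 16.0, 32.0], ["infection"] * 3)
        assert harrell_c([0.9, 0.5, 0.1], rows, W) == 1.0

    def test_hand_built_four_rows_match_oracle(self):
        rows = rows_from([8.0, 40.0, 20.0, 48.0],
                         ["infection", "infection", "discharge", "censored"])
        pred = np.array([0.7, 0.3, 0.4, 0.2])
        # administrative censoring moves the discharge row to t = 48
        time = np.array([8.0, 40.0, 48.0, 48.0])
        event = np.array([True, True, False, False])
        assert harrell_c(pred, rows, W) == brute_force_c(pred, time, event)

    def test_matches_exhaustive_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            pred, rows = random_rows(rng, rng.integers(20, 120))
            ev = (rows.outcome_type == "infection").to_numpy()
            time = rows.outcome_time.to_numpy().copy()
            time[(rows.outcome_type != "infection") & (rows.outcome_type != "censored")] = W
            assert harrell_c(pred, rows, W) == pytest.approx(
                brute_force_c(pred, time, ev), abs=1e-12
            )

    def test_competing_mode_event_time(self):
        rows = rows_from([8.0, 4.0], ["infection", "discharge"])
        # discharge before the infection: comparable under horizon-censoring,
        # not comparable when censored at its event time
        assert harrell_c([0.9, 0.1], rows, W, competing="horizon") == 1.0
        assert harrell_c([0.9, 0.1], rows, W, competing="event_time") is None

    def test_no_comparable_pairs_returns_none(self):
        rows = rows_from([48.0, 48.0], ["censored", "censored"])
        assert harrell_c([0.3, 0.4], rows, W) is None


class TestBrier:
    def test_perfect_and_uninformative(self):
        rows = rows_from([8.0, 48.0, 30.0], ["infection", "censored", "discharge"])
        assert brier([1.0, 0.0, 0.0], rows) == 0.0
        assert brier([0.5, 0.5, 0.5], rows) == 0.25

    def test_hand_arithmetic(self):
        rows = rows_from([48.0, 8.0, 48.0], ["censored", "infection", "censored"])
        assert brier([0.2, 0.7, 0.1], rows) == pytest.approx((0.04 + 0.09 + 0.01) / 3)

    def test_pooled_equals_weighted_mean_of_per_landmark(self):
        rng = np.random.default_rng(1)
        pred, rows = random_rows(rng, 200)
        rows["lm_level"] = rng.choice([48.0, 56.0, 64.0], size=len(rows))
        pooled = brier(pred, rows)
        parts = [
            (len(grp), brier(pred[rows.lm_level.to_numpy() == lm], grp))
            for lm, grp in rows.groupby("lm_level")
        ]
        weighted = sum(n * b for n, b in parts) / sum(n for n, _ in parts)
        assert pooled == pytest.approx(weighted, abs=1e-12)


class TestCalibration:
    def test_two_point_identity_line(self):
        rows_a = rows_from([48.0] * 9 + [10.0], ["censored"] * 9 + ["infection"])
        rows_b = rows_from([48.0] * 7 + [10.0] * 3, ["censored"] * 7 + ["infection"] * 3)
        rows = pd.concat([rows_a, rows_b], ignore_index=True)
        pred = np.r_[np.full(10, 0.1), np.full(10, 0.3)]
        res = calibration(pred, rows, W, n_bins=2)
        assert res.slope == pytest.approx(1.0, abs=1e-9)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictions_reported_absent(self):
        rows = rows_from([48.0] * 10, ["censored"] * 10)
        res = calibration(np.full(10, 0.2), rows, W)
        assert res.slope is None and res.reason == "constant predictions"

    def test_overconfident_predictions_halve_the_slope(self):
        rng = np.random.default_rng(2)
        n = 8000
        p = rng.uniform(0.02, 0.4, n)
        y = rng.random(n) < p
        rows = rows_from(np.where(y, rng.uniform(1, W, n), W),
                         np.where(y, "infection", "censored"))
        res = calibration(np.minimum(2 * p, 1.0), rows, W)
        assert res.slope == pytest.approx(0.5, abs=0.06)


class TestFoldPlan:
    def test_patients_grouped_and_balanced(self):
        patients = [f"p{i}" for i in range(103)]
        plan = FoldPlan.build(patients, k=5, repeats=2, seed=1)
        for rep in range(2):
            folds = plan.fold_of(rep, patients)
            counts = np.bincount(folds, minlength=5)
            assert counts.max() - counts.min() <= 1
        rows_patients = ["p1"] * 4 + ["p2"] * 3
        f = plan.fold_of(0, rows_patients)
        assert len(set(f[:4])) == 1 and len(set(f[4:])) == 1


class TestAlerts:
    def make_oof(self):
        return pd.DataFrame({
            "admission_id": ["a1"] * 5,
            "series_id": [0] * 5,
            "t_lm": [48.0, 56.0, 64.0, 72.0, 80.0],
            "prediction": [0.02, 0.2, 0.3, 0.05, 0.01],
        })

    def test_hand_built_lead_time(self):
        tl = make_timeline("a1", onsets=[120.0], terminal_time=200.0)
        rep = alert_analysis(self.make_oof(), [tl], threshold=0.10)
        assert rep.lead_times_h == [120.0 - 56.0]
        assert rep.median_lead_h == 64.0
        assert rep.fraction_ever_alerted == 1.0

    def test_threshold_extremes(self):
        tl = make_timeline("a1", onsets=[120.0], terminal_time=200.0)
        rep0 = alert_analysis(self.make_oof(), [tl], threshold=0.0)
        assert rep0.fraction_above == 1.0
        assert rep0.lead_times_h == [120.0 - 48.0]  # first landmark alerts
        rep1 = alert_analysis(self.make_oof(), [tl], threshold=1.0)
        assert rep1.fraction_above == 0.0 and rep1.median_lead_h is None

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            alert_analysis(self.make_oof(), [], threshold=1.5)


@pytest.fixture(scope="module")
def cv_setup():
    bundle = simulate_cohort(GeneratorConfig(n_admissions=150, seed=31),
                             with_vitals=False)
    cfg = CrossValConfig(grid=LandmarkGrid(), spec=CovariateSpec(),
                         use_cnn=False, seed=5)
    return bundle, cfg


class TestCrossValidate:
    def test_deterministic_given_seed(self, cv_setup):
        bundle, cfg = cv_setup
        r1 = cross_validate(bundle, cfg)
        r2 = cross_validate(bundle, cfg)
        assert r1.reports["base"].global_c == r2.reports["base"].global_c
        pd.testing.assert_frame_equal(
            r1.oof[["pred_base"]], r2.oof[["pred_base"]]
        )

    def test_out_of_fold_purity(self, cv_setup):
        """Every out-of-fold row's patient is excluded from the fold's
        training data, and fold fits use only training events."""
        bundle, cfg = cv_setup
        res = cross_validate(bundle, cfg)
        oof = res.oof
        for (rep, fold), grp in oof.groupby(["repeat", "fold"]):
            plan_folds = res.foldplan.fold_of(rep, grp["patient_id"])
            assert (plan_folds == fold).all()
            train_rows = oof[res.foldplan.fold_of(rep, oof["patient_id"]) != fold]
            fit = res.fold_models[(rep, fold)]["base"].fits["infection"]
            assert fit.n_events == (train_rows["outcome_type"] == "infection").sum()

    def test_fold_without_events_refused(self):
        bundle = simulate_cohort(
            GeneratorConfig(n_admissions=12, seed=3, lambda_inf=0.004),
            with_vitals=False,
        )
        cfg = CrossValConfig(grid=LandmarkGrid(), spec=CovariateSpec(),
                             use_cnn=False, seed=1)
        with pytest.raises(ValueError):
            cross_validate(bundle, cfg)


def test_importance_identifies_dominant_covariate():
    """With one strong generator effect and otherwise exchangeable noise,
    the dominant covariate gets the largest permutation c-index drop."""
    rng = np.random.default_rng(6)
    bundle = simulate_cohort(
        GeneratorConfig(n_admissions=250, seed=17,
                        beta_inf={"surgical_admission": 1.5},
                        covariate_drift={}),
        with_vitals=False,
    )
    spec = CovariateSpec(static=("age", "male", "surgical_admission"), dynamic=())
    cfg = CrossValConfig(grid=LandmarkGrid(), spec=spec, use_cnn=False, seed=2)
    res = cross_validate(bundle, cfg)
    from icuai.landmarks import build_stacked_dataset

    stacked = build_stacked_dataset(bundle, cfg.grid, spec)
    oof = res.oof.copy()
    oof["prediction"] = oof["pred_base"]
    imp = importance_heatmaps(
        stacked, list(spec.covariates), oof=oof,
        predict_fn=res.predict_fn("base"), horizon_h=48.0,
        n_permutations=5, seed=3,
    )
    assert imp.delta_c.idxmax() == "surgical_admission"
    # permuting near-noise covariates barely moves the c-index
    assert abs(imp.delta_c["male"]) < 0.02
    if len(imp.wald_ranks):
        # dominant covariate most often ranks first across landmarks
        top = (imp.wald_ranks["surgical_admission"] == 1.0).mean()
        assert top >= 0.5
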