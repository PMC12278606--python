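"""Dynamic model evaluation.

Repeated patient-grouped 5-fold cross-validation and the metric suite for
landmark prediction under competing risks: Harrell's c-index with
administrative censoring of competing events, Brier score, calibration
against nonparametric Aalen-Johansen cumulative incidence, Wald and
permutation importance matrices, and the alert / lead-time analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter

from .cnn import extract_window, fit_cnn
from .cohort import CohortBundle
from .config import CnnConfig, CovariateSpec, LandmarkGrid, derive_seed
from .landmarks import ImputationState, StackedDataset, build_stacked_dataset
from .supermodel import SupermodelFit, fit_cause_specific, fit_supermodel, lr_test, \
    predict_cif_batch, wald_chi2


# ---------------------------------------------------------------------------
# fold plan


@dataclass
class FoldPlan:
    """Patient-grouped fold assignment, balanced within one patient."""

    k: int = 5
    repeats: int = 1
    seed: int = 0
    assignment: list = field(default_factory=list)  # per repeat: {patient: fold}

    @classmethod
    def build(cls, patient_ids, k: int = 5, repeats: int = 1, seed: int = 0) -> "FoldPlan":
        patients = np.array(sorted(set(patient_ids)))
        rng = np.random.default_rng(seed)
        assignment = []
        for _ in range(repeats):
            perm = rng.permutation(len(patients))
            folds = np.arange(len(patients)) % k
            assignment.append(dict(zip(patients[perm], folds)))
        return cls(k=k, repeats=repeats, seed=seed, assignment=assignment)

    def fold_of(self, repeat: int, patient_ids) -> np.ndarray:
        amap = self.assignment[repeat]
        return np.array([amap[p] for p in patient_ids])


# ---------------------------------------------------------------------------
# core metrics


def harrell_c(
    predictions,
    rows: pd.DataFrame,
    horizon_h: float,
    competing: str = "horizon",
) -> Optional[float]:
    """Harrell's c-index for infection within the window.

    ``competing="horizon"`` administratively censors competing events at
    the horizon (a patient who dies or is discharged mid-window counts as
    infection-free through the whole window); ``competing="event_time"``
    censors them when they occur.  Tied predictions count 1/2; no
    comparable pairs returns None.
    """
    pred = np.asarray(predictions, float)
    ev = (rows["outcome_type"] == "infection").to_numpy()
    time = rows["outcome_time"].to_numpy(float).copy()
    if competing == "horizon":
        other = ~ev & (rows["outcome_type"] != "censored").to_numpy()
        time[other] = horizon_h
    elif competing != "event_time":
        raise ValueError(f"unknown competing mode {competing!r}")
    conc = ties = 0.0
    n_comp = 0
    for i in np.nonzero(ev)[0]:
        comparable = (time > time[i]) | ((time == time[i]) & ~ev)
        n = int(comparable.sum())
        if n == 0:
            continue
        pj = pred[comparable]
        conc += float((pred[i] > pj).sum())
        ties += float((pred[i] == pj).sum())
        n_comp += n
    if n_comp == 0:
        return None
    return (conc + 0.5 * ties) / n_comp


def brier(predictions, rows: pd.DataFrame, exclude_competing: bool = False) -> float:
    """Mean squared error of the predicted infection probability.

    Competing events and rows censored at the horizon count as
    non-events; ``exclude_competing`` drops competing-event rows instead.
    """
    pred = np.asarray(predictions, float)
    y = (rows["outcome_type"] == "infection").to_numpy().astype(float)
    if exclude_competing:
        keep = ~rows["outcome_type"].isin(["death", "discharge"]).to_numpy()
        pred, y = pred[keep], y[keep]
    return float(np.mean((pred - y) ** 2))


@dataclass
class CalibrationResult:
    curve: Optional[pd.DataFrame]
    slope: Optional[float]
    intercept: Optional[float]
    reason: Optional[str] = None


def _aj_cif(rows: pd.DataFrame, horizon_h: float) -> float:
    """Aalen-Johansen infection CIF at the horizon for a set of rows."""
    code = rows["outcome_type"].map(
        {"infection": 1, "death": 2, "discharge": 2, "censored": 0}
    ).to_numpy()
    durations = rows["outcome_time"].to_numpy(float)
    if (code == 1).sum() == 0:
        return 0.0
    if (code == 0).all():
        return 0.0
    ajf = AalenJohansenFitter(calculate_variance=False)
    ajf.fit(durations, code, event_of_interest=1)
    cif = ajf.cumulative_density_
    vals = cif[cif.index <= horizon_h + 1e-9]
    return float(vals.iloc[-1, 0]) if len(vals) else 0.0


def calibration(
    predictions,
    rows: pd.DataFrame,
    horizon_h: float,
    n_bins: int = 10,
    method: str = "linear",
) -> CalibrationResult:
    """Decile calibration of predicted vs observed infection CIF.

    Rows are binned by predicted risk; observed risk per bin is the
    nonparametric Aalen-Johansen CIF at the horizon (competing events
    respected at their event times).  Slope and intercept come from least
    squares of observed on mean predicted, bins weighted by size
    (``method="cloglog"`` regresses on the complementary-log-log scale).
    """
    pred = np.asarray(predictions, float)
    if len(np.unique(pred)) < 2:
        return CalibrationResult(None, None, None, reason="constant predictions")
    try:
        bins = pd.qcut(pred, n_bins, labels=False, duplicates="drop")
    except ValueError:
        return CalibrationResult(None, None, None, reason="too few distinct predictions")
    if len(np.unique(bins)) < 2:
        return CalibrationResult(None, None, None, reason="fewer than two bins")
    recs = []
    for b in np.unique(bins):
        m = bins == b
        recs.append(
            {
                "bin": int(b),
                "n": int(m.sum()),
                "mean_predicted": float(pred[m].mean()),
                "observed": _aj_cif(rows.loc[m], horizon_h),
            }
        )
    curve = pd.DataFrame(recs)
    x = curve["mean_predicted"].to_numpy()
    y = curve["observed"].to_numpy()
    wgt = curve["n"].to_numpy(float)
    if method == "cloglog":
        keep = (x > 0) & (x < 1) & (y > 0) & (y < 1)
        if keep.sum() < 2:
            return CalibrationResult(curve, None, None, reason="degenerate bins for cloglog")
        x = np.log(-np.log(1 - x[keep]))
        y = np.log(-np.log(1 - y[keep]))
        wgt = wgt[keep]
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(wgt))
    return CalibrationResult(curve, float(slope), float(intercept))


# ---------------------------------------------------------------------------
# importance


@dataclass
class ImportanceReport:
    wald_chi2: pd.DataFrame  # landmark x covariate
    wald_ranks: pd.DataFrame  # 1 = strongest per landmark
    delta_c: Optional[pd.Series]
    excluded: dict


def importance_heatmaps(
    stacked: StackedDataset,
    covariates: list,
    oof: Optional[pd.DataFrame] = None,
    predict_fn: Optional[Callable] = None,
    horizon_h: Optional[float] = None,
    n_permutations: int = 20,
    seed: int = 0,
    min_events: int = 5,
) -> ImportanceReport:
    """Per-landmark Wald chi-square rankings and permutation c-index drops.

    The Wald view refits the infection cause on each landmark level
    separately.  The delta-c view permutes one covariate at a time across
    the out-of-fold rows, re-predicts through ``predict_fn`` and records
    the mean c-index drop over ``n_permutations`` seeded permutations.
    """
    df = stacked.df
    imput = ImputationState().fit(df, stacked.covariate_spec.dynamic)
    excluded: dict = {}
    wald_rows = {}
    lm_col = "lm_level" if "lm_level" in df.columns else "t_lm"
    for t_lm in stacked.landmark_levels:
        sub = imput.transform(df[df[lm_col] == t_lm])
        if (sub["outcome_type"] == "infection").sum() < min_events:
            excluded[f"landmark_{t_lm}"] = "too few infection events"
            continue
        cols = [c for c in covariates if c in sub.columns and sub[c].nunique() > 1]
        dropped = [c for c in covariates if c not in cols]
        for c in dropped:
            excluded[f"{c}@{t_lm}"] = "constant in the data at this landmark"
        try:
            fit = fit_cause_specific(sub, "infection", covariates=cols,
                                     baseline_mode="pooled")
            wald_rows[t_lm] = wald_chi2(fit)
        except Exception as e:  # singular / non-converged landmark
            excluded[f"landmark_{t_lm}"] = str(e)
    wald = pd.DataFrame(wald_rows).T if wald_rows else pd.DataFrame()
    wald.index.name = "t_lm"
    ranks = wald.rank(axis=1, ascending=False) if len(wald) else pd.DataFrame()

    delta_c = None
    if oof is not None and predict_fn is not None:
        rng = np.random.default_rng(seed)
        base_c = harrell_c(oof["prediction"], oof, horizon_h)
        drops = {}
        for cov in covariates:
            if cov not in oof.columns or oof[cov].nunique() <= 1:
                excluded.setdefault(cov, "constant or absent in out-of-fold rows")
                continue
            cs = []
            for _ in range(n_permutations):
                perm = oof.copy()
                perm[cov] = rng.permutation(perm[cov].to_numpy())
                cs.append(harrell_c(predict_fn(perm), oof, horizon_h))
            drops[cov] = base_c - float(np.mean([c for c in cs if c is not None]))
        delta_c = pd.Series(drops, name="delta_c")
    return ImportanceReport(wald_chi2=wald, wald_ranks=ranks, delta_c=delta_c,
                            excluded=excluded)


# ---------------------------------------------------------------------------
# alerts


@dataclass
class AlertReport:
    threshold: float
    fraction_above: float
    lead_times_h: list
    median_lead_h: Optional[float]
    iqr_lead_h: tuple
    fraction_ever_alerted: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "fraction_above": self.fraction_above,
            "median_lead_h": self.median_lead_h,
            "iqr_lead_h": list(self.iqr_lead_h),
            "fraction_ever_alerted": self.fraction_ever_alerted,
            "n_lead_times": len(self.lead_times_h),
        }


def alert_analysis(
    oof: pd.DataFrame, timelines, threshold: float = 0.10
) -> AlertReport:
    """Alert fractions and lead times at a risk threshold.

    For each admission's first infection, the lead time is onset minus the
    first pre-onset landmark whose prediction exceeds the threshold
    (initial series only — alerts after a previous infection concern
    recurrences and are not pooled into first-infection lead times).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be within [0, 1]")
    pred = oof["prediction"].to_numpy(float)
    frac = float((pred > threshold).mean()) if len(pred) else 0.0
    tl_map = {t.admission_id: t for t in timelines}
    leads = []
    n_inf = 0
    n_alerted = 0
    for adm, grp in oof.groupby("admission_id"):
        tl = tl_map.get(adm)
        if tl is None or not tl.infection_onsets:
            continue
        onset = tl.infection_onsets[0]
        pre = grp[(grp["series_id"] == 0) & (grp["t_lm"] < onset)]
        if not len(pre):
            continue
        n_inf += 1
        hits = pre[pre["prediction"] > threshold]
        if len(hits):
            n_alerted += 1
            leads.append(float(onset - hits["t_lm"].min()))
    med = float(np.median(leads)) if leads else None
    iqr = (
        (float(np.percentile(leads, 25)), float(np.percentile(leads, 75)))
        if leads
        else (math.nan, math.nan)
    )
    return AlertReport(
        threshold=threshold,
        fraction_above=frac,
        lead_times_h=leads,
        median_lead_h=med,
        iqr_lead_h=iqr,
        fraction_ever_alerted=(n_alerted / n_inf) if n_inf else 0.0,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CrossValConfig:
    grid: LandmarkGrid
    spec: CovariateSpec
    use_cnn: bool = True
    cnn_config: Optional[CnnConfig] = None
    baseline_mode: str = "pooled"
    seed: int = 0
    exclude_competing_brier: bool = False
    competing_cindex: str = "horizon"


@dataclass
class MetricReport:
    model: str
    horizon_h: float
    global_c: Optional[float]
    global_c_ci: tuple
    global_brier: float
    global_brier_ci: tuple
    calibration_slope: Optional[float]
    calibration_intercept: Optional[float]
    calibration_curve: Optional[pd.DataFrame]
    per_landmark: pd.DataFrame
    fold_c: list
    fold_brier: list
    lr_stat: Optional[float] = None
    lr_df: Optional[int] = None
    lr_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "horizon_h": self.horizon_h,
            "global_c": self.global_c,
            "global_c_ci": list(self.global_c_ci),
            "global_brier": self.global_brier,
            "global_brier_ci": list(self.global_brier_ci),
            "calibration_slope": self.calibration_slope,
            "calibration_intercept": self.calibration_intercept,
            "fold_c": self.fold_c,
            "fold_brier": self.fold_brier,
            "lr_stat": self.lr_stat,
            "lr_df": self.lr_df,
            "lr_p": self.lr_p,
            "per_landmark": self.per_landmark.to_dict(orient="records"),
        }
        if self.calibration_curve is not None:
            d["calibration_curve"] = self.calibration_curve.to_dict(orient="records")
        return d


@dataclass
class CrossValResult:
    reports: dict  # model name -> MetricReport
    oof: pd.DataFrame
    fold_models: dict  # (repeat, fold) -> {"base": SupermodelFit, "deep": ...}
    foldplan: FoldPlan

    def predict_fn(self, model: str = "deep") -> Callable:
        """Route rows to the supermodel of the fold they were held out from."""

        def fn(rows: pd.DataFrame) -> np.ndarray:
            out = np.zeros(len(rows))
            key = list(zip(rows["repeat"], rows["fold"]))
            rows = rows.reset_index(drop=True)
            for (rep, fold), grp in rows.groupby(["repeat", "fold"]):
                sm = self.fold_models[(rep, fold)][model]
                out[grp.index.to_numpy()] = predict_cif_batch(sm, grp)
            return out

        return fn


def _fold_ci(values) -> tuple:
    vals = np.array([v for v in values if v is not None and np.isfinite(v)])
    if len(vals) == 0:
        return (math.nan, math.nan)
    half = 1.96 * vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
    return (float(vals.mean() - half), float(vals.mean() + half))


def _extract_windows_for_rows(bundle: CohortBundle, rows: pd.DataFrame,
                              window_minutes: int) -> np.ndarray:
    streams = {v.admission_id: v for v in bundle.vitals}
    out = np.empty((len(rows), 5, window_minutes))
    for j, (adm, t_lm, sid) in enumerate(
        zip(rows["admission_id"], rows["t_lm"], rows["series_id"])
    ):
        out[j] = extract_window(streams[adm], t_lm, window_minutes, series_id=sid).values
    return out


def _report_for(
    name, oof, pred_col, horizon_h, folds_c, folds_b, cv_cfg
) -> MetricReport:
    pred = oof[pred_col].to_numpy(float)
    per_lm = []
    lm_col = "lm_level" if "lm_level" in oof.columns else "t_lm"
    for t_lm, grp in oof.groupby(lm_col):
        per_lm.append(
            {
                "t_lm": float(t_lm),
                "n": len(grp),
                "events": int((grp["outcome_type"] == "infection").sum()),
                "c": harrell_c(grp[pred_col], grp, horizon_h, cv_cfg.competing_cindex),
                "brier": brier(grp[pred_col], grp, cv_cfg.exclude_competing_brier),
            }
        )
    cal = calibration(pred, oof, horizon_h)
    return MetricReport(
        model=name,
        horizon_h=horizon_h,
        global_c=harrell_c(pred, oof, horizon_h, cv_cfg.competing_cindex),
        global_c_ci=_fold_ci(folds_c),
        global_brier=brier(pred, oof, cv_cfg.exclude_competing_brier),
        global_brier_ci=_fold_ci(folds_b),
        calibration_slope=cal.slope,
        calibration_intercept=cal.intercept,
        calibration_curve=cal.curve,
        per_landmark=pd.DataFrame(per_lm),
        fold_c=[c for c in folds_c],
        fold_brier=[b for b in folds_b],
    )


def cross_validate(
    bundle: CohortBundle,
    cv_cfg: CrossValConfig,
    foldplan: Optional[FoldPlan] = None,
) -> CrossValResult:
    """Repeated patient-grouped cross-validation of base and deep models.

    Per fold everything is fitted on training patients only: imputation
    medians, landmark-time centring, CNN weights and preprocessing
    constants, and the Cox supermodels; held-out rows are scored and
    predicted out of fold.  Metrics are reported pooled over out-of-fold
    predictions and as mean with a normal-approximation 95% CI over folds.
    """
    spec = cv_cfg.spec
    stacked = build_stacked_dataset(bundle, cv_cfg.grid, spec)
    df = stacked.df
    if foldplan is None:
        foldplan = FoldPlan.build(df["patient_id"], k=5, repeats=1, seed=cv_cfg.seed)
    horizon = cv_cfg.grid.horizon_h
    models = ["base", "deep"] if cv_cfg.use_cnn else ["base"]
    oof_parts = []
    fold_models = {}
    folds_c = {m: [] for m in models}
    folds_b = {m: [] for m in models}
    for rep in range(foldplan.repeats):
        fold_of = foldplan.fold_of(rep, df["patient_id"])
        for fold in range(foldplan.k):
            te_mask = fold_of == fold
            tr = df[~te_mask].copy()
            te = df[te_mask].copy()
            if (tr["outcome_type"] == "infection").sum() == 0 or (
                te["outcome_type"] == "infection"
            ).sum() == 0:
                raise ValueError(
                    "a fold lacks infection events; enlarge the cohort or reduce k"
                )
            # landmark-time centring from training rows only
            s_center = float((tr["t_lm"] / 24.0).mean())
            for part in (tr, te):
                part["s"] = part["t_lm"] / 24.0 - s_center
                part["s2"] = part["s"] ** 2
            imput = ImputationState().fit(tr, spec.dynamic)
            tr = imput.transform(tr)
            te = imput.transform(te)
            entry = {}
            if cv_cfg.use_cnn:
                cnn_cfg = cv_cfg.cnn_config or CnnConfig()
                wtr = _extract_windows_for_rows(bundle, tr, cnn_cfg.window_minutes)
                wte = _extract_windows_for_rows(bundle, te, cnn_cfg.window_minutes)
                ytr = (tr["outcome_type"] == "infection").to_numpy().astype(float)
                cnn = fit_cnn(wtr, ytr, cnn_cfg,
                              seed=derive_seed(cv_cfg.seed, f"cnn:{rep}:{fold}"))
                tr["cnn_score"] = cnn.scores(wtr)
                te["cnn_score"] = cnn.scores(wte)
                entry["cnn"] = cnn
            tr_stacked = StackedDataset(tr, spec, cv_cfg.grid, s_center)
            base_sm = fit_supermodel(tr_stacked, spec.with_cnn(False), cv_cfg.baseline_mode)
            te["pred_base"] = predict_cif_batch(base_sm, te)
            entry["base"] = base_sm
            if cv_cfg.use_cnn:
                deep_sm = fit_supermodel(tr_stacked, spec.with_cnn(True), cv_cfg.baseline_mode)
                te["pred_deep"] = predict_cif_batch(deep_sm, te)
                entry["deep"] = deep_sm
            fold_models[(rep, fold)] = entry
            te["repeat"] = rep
            te["fold"] = fold
            for m in models:
                folds_c[m].append(harrell_c(te[f"pred_{m}"], te, horizon,
                                            cv_cfg.competing_cindex))
                folds_b[m].append(brier(te[f"pred_{m}"], te, cv_cfg.exclude_competing_brier))
            oof_parts.append(te)
    oof = pd.concat(oof_parts, ignore_index=True)
    reports = {
        m: _report_for(m, oof, f"pred_{m}", horizon, folds_c[m], folds_b[m], cv_cfg)
        for m in models
    }
    if cv_cfg.use_cnn:
        # LR test on the full stacked data with out-of-fold CNN scores as the
        # ancillary predictor (scores never come from a model that saw the row)
        full = oof.copy()
        full_stacked = StackedDataset(full, spec, cv_cfg.grid, stacked.s_center)
        base_fit = fit_supermodel(full_stacked, spec.with_cnn(False), cv_cfg.baseline_mode)
        deep_fit = fit_supermodel(full_stacked, spec.with_cnn(True), cv_cfg.baseline_mode)
        stat, dof, p = lr_test(base_fit, deep_fit)
        reports["deep"].lr_stat, reports["deep"].lr_df, reports["deep"].lr_p = stat, dof, p
    return CrossValResult(reports=reports, oof=oof, fold_models=fold_models,
                          foldplan=foldplan)
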