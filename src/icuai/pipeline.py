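"""End-to-end orchestration: simulate -> landmarks -> CNN -> supermodels -> report.

A run is described by a :class:`RunConfig` (JSON round-trip, one master
seed).  Module seeds are derived by hashing (master seed, stage name), so
adding a stage never shifts another stage's random stream.  Each stage
writes its documented artifacts into the run directory and a manifest
records the config hash and file checksums; rerunning a stage with
identical inputs reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as iomod
from .cnn import train_cnn
from .cohort import simulate_cohort, summarize_incidence
from .config import (
    CnnConfig,
    CovariateSpec,
    GeneratorConfig,
    LandmarkGrid,
    config_hash,
    derive_seed,
)
from .landmarks import ImputationState, StackedDataset, build_stacked_dataset
from .metrics import CrossValConfig, FoldPlan, alert_analysis, cross_validate, \
    importance_heatmaps
from .supermodel import fit_supermodel, lr_test, predict_cif_batch

log = logging.getLogger("icuai")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    grid: LandmarkGrid = field(default_factory=LandmarkGrid)
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    cnn_grid: list = field(default_factory=list)  # optional list of CnnConfig
    use_cnn: bool = True
    baseline_mode: str = "pooled"
    folds: int = 5
    repeats: int = 1
    seed: int = 0
    alert_threshold: float = 0.10

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "grid": self.grid.to_dict(),
            "covariate_spec": self.covariate_spec.to_dict(),
            "cnn": self.cnn.to_dict(),
            "cnn_grid": [c.to_dict() for c in self.cnn_grid],
            "use_cnn": self.use_cnn,
            "baseline_mode": self.baseline_mode,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "alert_threshold": self.alert_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            generator=GeneratorConfig.from_dict(d.get("generator", {})),
            grid=LandmarkGrid.from_dict(d.get("grid", {})),
            covariate_spec=CovariateSpec.from_dict(d["covariate_spec"])
            if "covariate_spec" in d
            else CovariateSpec(),
            cnn=CnnConfig.from_dict(d["cnn"]) if "cnn" in d else CnnConfig(),
            cnn_grid=[CnnConfig.from_dict(c) for c in d.get("cnn_grid", [])],
            use_cnn=d.get("use_cnn", True),
            baseline_mode=d.get("baseline_mode", "pooled"),
            folds=d.get("folds", 5),
            repeats=d.get("repeats", 1),
            seed=d.get("seed", 0),
            alert_threshold=d.get("alert_threshold", 0.10),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _update_manifest(outdir: Path, config: RunConfig, stage: str, files: list) -> None:
    man_path = outdir / "manifest.json"
    manifest = json.loads(man_path.read_text()) if man_path.exists() else {
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "stages": {},
    }
    manifest["stages"][stage] = {
        str(f.relative_to(outdir)): _checksum(f) for f in files if f.exists()
    }
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def stage_simulate(config: RunConfig, outdir, include_vitals: bool = True):
    """Generate the cohort and its incidence summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gen = dataclasses.replace(config.generator, seed=derive_seed(config.seed, "simulate"))
    bundle = simulate_cohort(gen, with_vitals=include_vitals and config.use_cnn)
    iomod.write_cohort(bundle, out, include_vitals=False)  # vitals stay in memory
    summary = summarize_incidence(bundle)
    (out / "incidence.json").write_text(json.dumps(summary.to_dict(), indent=1))
    summary.per_day_composition.to_csv(out / "per_day_composition.csv", index=False)
    log.info("simulate: %d admissions, %d onsets", summary.n_admissions, summary.n_onsets)
    _update_manifest(out, config, "simulate",
                     [out / "admissions.csv", out / "events.csv", out / "clinical.csv",
                      out / "incidence.json"])
    return bundle


def stage_build(config: RunConfig, bundle, outdir) -> StackedDataset:
    out = Path(outdir)
    stacked = build_stacked_dataset(bundle, config.grid, config.covariate_spec)
    iomod.write_stacked(stacked, out / "stacked.csv")
    log.info("build: %d landmark rows, %d landmarks", len(stacked),
             len(stacked.landmark_levels))
    _update_manifest(out, config, "build", [out / "stacked.csv"])
    return stacked


def stage_train_cnn(config: RunConfig, bundle, stacked: StackedDataset, outdir):
    """Hyperparameter selection by grouped 5-fold mean AUC, then refit."""
    from .metrics import _extract_windows_for_rows

    out = Path(outdir)
    df = stacked.df
    windows = _extract_windows_for_rows(bundle, df, config.cnn.window_minutes)
    labels = (df["outcome_type"] == "infection").to_numpy().astype(float)
    grid = config.cnn_grid or [config.cnn]
    model, report = train_cnn(windows, labels, df["patient_id"].to_numpy(), grid,
                              k=config.folds, seed=derive_seed(config.seed, "cnn"))
    scores = df[["admission_id", "series_id", "t_lm"]].copy()
    scores["cnn_score"] = model.scores(windows)
    scores.to_csv(out / "scores.csv", index=False)
    model.save(out / "cnn_model.npz")
    (out / "cnn_selection.json").write_text(json.dumps(report, indent=1))
    log.info("train-cnn: selected config %d", report["selected"])
    _update_manifest(out, config, "train-cnn", [out / "scores.csv"])
    return model, scores


def stage_fit(config: RunConfig, stacked: StackedDataset, outdir,
              scores: Optional[pd.DataFrame] = None) -> dict:
    out = Path(outdir)
    df = stacked.df.copy()
    if scores is not None:
        from .landmarks import join_scores

        df = join_scores(df, scores)
        if df["cnn_score"].isna().any():
            raise ValueError("scores.csv does not cover every landmark row")
    imput = ImputationState().fit(df, config.covariate_spec.dynamic)
    df = imput.transform(df)
    full = StackedDataset(df, config.covariate_spec, config.grid, stacked.s_center)
    fits = {"base": fit_supermodel(full, config.covariate_spec.with_cnn(False),
                                   config.baseline_mode)}
    iomod.write_fit_json(fits["base"], out / "fit_base.json")
    files = [out / "fit_base.json"]
    if config.use_cnn and scores is not None:
        fits["deep"] = fit_supermodel(full, config.covariate_spec.with_cnn(True),
                                      config.baseline_mode)
        iomod.write_fit_json(fits["deep"], out / "fit_deep.json")
        stat, dof, p = lr_test(fits["base"], fits["deep"])
        (out / "lr_test.json").write_text(
            json.dumps({"stat": stat, "df": dof, "p": p}, indent=1))
        files += [out / "fit_deep.json", out / "lr_test.json"]
        preds = predict_cif_batch(fits["deep"], df)
    else:
        preds = predict_cif_batch(fits["base"], df)
    pred_df = df[["admission_id", "series_id", "t_lm"]].copy()
    pred_df["cif_infection"] = preds
    pred_df.to_csv(out / "predictions.csv", index=False)
    coef_rows = []
    for name, sm in fits.items():
        for cause, fit in sm.fits.items():
            hr = fit.hazard_ratios()
            hr.insert(0, "cause", cause)
            hr.insert(0, "model", name)
            coef_rows.append(hr)
    pd.concat(coef_rows, ignore_index=True).to_csv(out / "coefficients.csv", index=False)
    log.info("fit: base%s fitted", " + deep" if "deep" in fits else "")
    _update_manifest(out, config, "fit", files + [out / "coefficients.csv",
                                                  out / "predictions.csv"])
    return fits


def stage_evaluate(config: RunConfig, bundle, outdir):
    out = Path(outdir)
    cv_cfg = CrossValConfig(
        grid=config.grid,
        spec=config.covariate_spec,
        use_cnn=config.use_cnn,
        cnn_config=config.cnn,
        baseline_mode=config.baseline_mode,
        seed=derive_seed(config.seed, "evaluate"),
    )
    foldplan = FoldPlan.build(
        [a.patient_id for a in bundle.admissions],
        k=config.folds, repeats=config.repeats,
        seed=derive_seed(config.seed, "folds"),
    )
    result = cross_validate(bundle, cv_cfg, foldplan)
    model_for_alerts = "deep" if config.use_cnn else "base"
    oof = result.oof.copy()
    oof["prediction"] = oof[f"pred_{model_for_alerts}"]
    alerts = alert_analysis(oof, bundle.timelines, config.alert_threshold)
    stacked = build_stacked_dataset(bundle, config.grid, config.covariate_spec)
    imp = importance_heatmaps(
        stacked,
        list(config.covariate_spec.covariates)
        + (["cnn_score"] if config.use_cnn else []),
        oof=oof,
        predict_fn=result.predict_fn(model_for_alerts),
        horizon_h=config.grid.horizon_h,
        seed=derive_seed(config.seed, "importance"),
    )
    report = {
        "horizon_h": config.grid.horizon_h,
        "models": {m: r.to_dict() for m, r in result.reports.items()},
        "alerts": alerts.to_dict(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    rows = []
    for m, r in result.reports.items():
        pl = r.per_landmark.copy()
        pl.insert(0, "model", m)
        rows.append(pl)
    pd.concat(rows, ignore_index=True).to_csv(out / "metrics_by_landmark.csv", index=False)
    if result.reports[model_for_alerts].calibration_curve is not None:
        result.reports[model_for_alerts].calibration_curve.to_csv(
            out / "calibration_curve.csv", index=False)
    if len(imp.wald_chi2):
        imp.wald_chi2.to_csv(out / "importance_wald.csv")
    if imp.delta_c is not None:
        imp.delta_c.to_csv(out / "importance_deltac.csv", header=True)
    pd.DataFrame({"lead_time_h": alerts.lead_times_h}).to_csv(out / "alerts.csv", index=False)
    log.info("evaluate: global c (base) = %s",
             result.reports["base"].global_c)
    _update_manifest(out, config, "evaluate",
                     [out / "report.json", out / "metrics_by_landmark.csv"])
    return result, alerts, imp


def run_full(config: RunConfig, outdir) -> dict:
    """Run every stage in order and return the in-memory artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(config.to_dict(), indent=1))
    bundle = stage_simulate(config, out)
    stacked = stage_build(config, bundle, out)
    scores = None
    if config.use_cnn:
        _, scores = stage_train_cnn(config, bundle, stacked, out)
    fits = stage_fit(config, stacked, out, scores)
    result, alerts, imp = stage_evaluate(config, bundle, out)
    return {
        "bundle": bundle,
        "stacked": stacked,
        "fits": fits,
        "cv": result,
        "alerts": alerts,
        "importance": imp,
    }
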