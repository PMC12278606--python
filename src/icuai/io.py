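"""Readers and writers for the pipeline's file interfaces.

All artifacts are plain delimited text (CSV) or JSON; column layouts are
documented in ``schema.json`` shipped with the package.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AdmissionRecord, ClinicalSeries, CohortBundle, EventTimeline, VitalStream
from .config import GeneratorConfig, VITAL_CHANNELS
from .landmarks import StackedDataset


def write_cohort(bundle: CohortBundle, outdir, include_vitals: bool = True) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.admissions_frame().to_csv(out / "admissions.csv", index=False)
    ev = pd.DataFrame(
        {
            "admission_id": [t.admission_id for t in bundle.timelines],
            "onset_times": [";".join(f"{x:.10g}" for x in t.infection_onsets)
                            for t in bundle.timelines],
            "terminal_event": [t.terminal_event for t in bundle.timelines],
            "terminal_time_h": [t.terminal_time for t in bundle.timelines],
        }
    )
    ev.to_csv(out / "events.csv", index=False)
    parts = []
    for c in bundle.clinical:
        for name, vals in c.channels.items():
            m = ~np.isnan(vals)
            parts.append(pd.DataFrame({
                "admission_id": c.admission_id,
                "time_h": c.grid[m],
                "channel": name,
                "value": vals[m],
            }))
    (pd.concat(parts, ignore_index=True) if parts else
     pd.DataFrame(columns=["admission_id", "time_h", "channel", "value"])
     ).to_csv(out / "clinical.csv", index=False)
    if include_vitals and bundle.vitals:
        with open(out / "vitals.csv", "w") as fh:
            fh.write("admission_id,minute,channel,value\n")
            for v in bundle.vitals:
                for j, name in enumerate(v.channels):
                    col = v.values[:, j]
                    m = ~np.isnan(col)
                    idx = np.nonzero(m)[0]
                    for i in idx:
                        fh.write(f"{v.admission_id},{i},{name},{col[i]:.4f}\n")
    with open(out / "generator_config.json", "w") as fh:
        json.dump(bundle.config_echo.to_dict(), fh, indent=1)
    if bundle.latents is not None:
        bundle.latents.to_csv(out / "latents.csv", index=False)


def read_cohort(indir) -> CohortBundle:
    ind = Path(indir)
    adm_df = pd.read_csv(ind / "admissions.csv")
    admissions = [
        AdmissionRecord(
            patient_id=r.pop("patient_id"),
            admission_id=r.pop("admission_id"),
            covariates=r,
        )
        for r in adm_df.to_dict(orient="records")
    ]
    ev = pd.read_csv(ind / "events.csv", keep_default_na=False)
    timelines = [
        EventTimeline(
            admission_id=row["admission_id"],
            infection_onsets=[float(x) for x in str(row["onset_times"]).split(";") if x],
            terminal_event=row["terminal_event"],
            terminal_time=float(row["terminal_time_h"]),
        )
        for _, row in ev.iterrows()
    ]
    clin_df = pd.read_csv(ind / "clinical.csv")
    clinical = []
    for adm, grp in clin_df.groupby("admission_id", sort=False):
        tmax = next(t.terminal_time for t in timelines if t.admission_id == adm)
        grid = np.arange(0.0, tmax, 8.0)
        channels = {}
        for ch, g in grp.groupby("channel", sort=False):
            vals = np.full(len(grid), np.nan)
            pos = np.searchsorted(grid, g["time_h"].to_numpy())
            vals[pos] = g["value"].to_numpy()
            channels[ch] = vals
        clinical.append(ClinicalSeries(admission_id=adm, grid=grid, channels=channels))
    vitals = []
    vit_path = ind / "vitals.csv"
    if vit_path.exists():
        vit_df = pd.read_csv(vit_path)
        for adm, grp in vit_df.groupby("admission_id", sort=False):
            tmax = next(t.terminal_time for t in timelines if t.admission_id == adm)
            n_min = int(tmax * 60.0)
            values = np.full((n_min, len(VITAL_CHANNELS)), np.nan, dtype=np.float32)
            for j, name in enumerate(VITAL_CHANNELS):
                g = grp[grp["channel"] == name]
                values[g["minute"].to_numpy(int), j] = g["value"].to_numpy()
            vitals.append(VitalStream(admission_id=adm, values=values))
    with open(ind / "generator_config.json") as fh:
        cfg = GeneratorConfig.from_dict(json.load(fh))
    lat = None
    if (ind / "latents.csv").exists():
        lat = pd.read_csv(ind / "latents.csv")
    return CohortBundle(admissions=admissions, timelines=timelines, clinical=clinical,
                        vitals=vitals, config_echo=cfg, latents=lat)


def write_stacked(stacked: StackedDataset, path) -> None:
    stacked.df.to_csv(path, index=False)


def write_fit_json(supermodel, path) -> None:
    out = {"baseline_mode": supermodel.baseline_mode, "horizon_h": supermodel.horizon_h,
           "causes": {}}
    for cause, fit in supermodel.fits.items():
        hr = fit.hazard_ratios()
        out["causes"][cause] = {
            "covariates": fit.covariates,
            "coef": [float(b) for b in fit.beta],
            "se": [float(s) for s in fit.se],
            "hr": hr["hr"].tolist(),
            "hr_lo": hr["hr_lo"].tolist(),
            "hr_hi": hr["hr_hi"].tolist(),
            "loglik": fit.loglik,
            "loglik_null": fit.loglik_null,
            "n_events": fit.n_events,
            "converged": bool(fit.converged),
        }
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
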