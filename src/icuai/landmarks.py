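"""Landmark dataset construction.

Turns a cohort into the stacked landmark dataset used by the supermodel:
at-risk segments (24-h run-in excluded, 48-h post-onset blackout, reset
series treated as independent), 8-hourly landmark placement, outcome
labelling within the sliding prediction window with death and discharge as
competing events, and covariate assembly (last observation carried forward
within a lookback, then training-fold medians).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import CohortBundle, EventTimeline
from .config import CovariateSpec, LandmarkGrid

OUTCOMES = ("infection", "death", "discharge", "censored")


@dataclass
class AtRiskSegment:
    admission_id: str
    series_id: int  # 0 = initial series, k = after k-th onset
    start_h: float
    end_h: float
    end_reason: str  # infection | death | discharge | administrative


def segment_at_risk_periods(timeline: EventTimeline, grid: LandmarkGrid) -> list:
    """Split a timeline into at-risk segments.

    Segment 0 runs from the end of the run-in exclusion to the first onset
    (or terminal event); segment k starts when the k-th blackout ends.  A
    segment entirely swallowed by the preceding blackout is omitted.
    """
    if any(t >= timeline.terminal_time for t in timeline.infection_onsets):
        raise ValueError("malformed timeline: onset at or after terminal time")
    segments = []
    bounds = list(timeline.infection_onsets) + [timeline.terminal_time]
    start = grid.runin_exclusion_h
    for k, end in enumerate(bounds):
        reason = "infection" if k < len(timeline.infection_onsets) else timeline.terminal_event
        if start < end:
            segments.append(
                AtRiskSegment(timeline.admission_id, k, start, end, reason)
            )
        if k < len(timeline.infection_onsets):
            start = timeline.infection_onsets[k] + grid.blackout_h
    return segments


def place_landmarks(segment: AtRiskSegment, grid: LandmarkGrid) -> np.ndarray:
    """Landmark times inside a segment, strictly before its end.

    The initial series uses the admission-wide grid starting at
    ``first_landmark_h``.  Reset series restart the 8-h clock at blackout
    end (optionally re-aligned to the admission grid, optionally after an
    extra observation run-in).
    """
    if segment.series_id == 0:
        first = grid.first_landmark_h
    else:
        first = segment.start_h + grid.reset_runin_h
        if grid.realign_resets:
            offset = (first - grid.first_landmark_h) % grid.spacing_h
            if offset > 0:
                first = first + (grid.spacing_h - offset)
    if first >= segment.end_h:
        return np.array([])
    n = int(np.ceil((segment.end_h - first) / grid.spacing_h))
    ts = first + grid.spacing_h * np.arange(n + 1)
    ts = ts[(ts >= segment.start_h) & (ts < segment.end_h - 1e-9)]
    return ts


def label_window(t_lm: float, timeline: EventTimeline, grid: LandmarkGrid) -> tuple:
    """Outcome of the prediction window (t_lm, t_lm + horizon].

    The first event in the window wins; exact ties resolve
    infection > death > discharge.  No event and still in ICU at the window
    end means censored at the horizon; administrative end of follow-up
    censors at its time.
    """
    segs = segment_at_risk_periods(timeline, grid)
    if not any(s.start_h <= t_lm < s.end_h for s in segs):
        raise ValueError(f"t_lm={t_lm} is not inside an at-risk segment")
    w = grid.horizon_h
    candidates = []
    for onset in timeline.infection_onsets:
        if t_lm < onset <= t_lm + w:
            candidates.append((onset - t_lm, 0, "infection"))
    if t_lm < timeline.terminal_time <= t_lm + w:
        ev = timeline.terminal_event
        if ev == "death":
            candidates.append((timeline.terminal_time - t_lm, 1, "death"))
        elif ev == "discharge":
            candidates.append((timeline.terminal_time - t_lm, 2, "discharge"))
        else:  # administrative truncation inside the window: censored there
            candidates.append((timeline.terminal_time - t_lm, 3, "censored"))
    if not candidates:
        return "censored", w
    u, _, outcome = min(candidates)
    return outcome, u


class ImputationState:
    """Training-fold medians for dynamic covariates.

    Fitted on training rows only so that covariate imputation never leaks
    information from evaluated patients.
    """

    def __init__(self) -> None:
        self.medians: dict = {}
        self.fitted = False

    def fit(self, rows: pd.DataFrame, channels) -> "ImputationState":
        for ch in channels:
            med = rows[ch].median()
            self.medians[ch] = float(med) if np.isfinite(med) else 0.0
        self.fitted = True
        return self

    def transform(self, rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for ch, med in self.medians.items():
            if ch in out.columns:
                out[ch] = out[ch].fillna(med)
        return out


def assemble_covariates(
    bundle: CohortBundle,
    admission_id: str,
    t_lm: float,
    lookback_h: float,
    spec: CovariateSpec,
    imputation_state: Optional[ImputationState] = None,
) -> tuple:
    """Covariate vector for one landmark: statics + LOCF dynamics + flags.

    Per dynamic channel the last observation in [t_lm - lookback_h, t_lm]
    is used; when none exists the value is NaN (or the training median if
    an imputation state is supplied) and the flag is set.
    """
    adm = next(a for a in bundle.admissions if a.admission_id == admission_id)
    series = next(c for c in bundle.clinical if c.admission_id == admission_id)
    values: dict = {name: adm.covariates[name] for name in spec.static}
    flags: dict = {}
    for ch in spec.dynamic:
        if ch not in series.channels:
            raise KeyError(f"unknown dynamic channel {ch!r}")
        x = series.channels[ch]
        m = (series.grid >= t_lm - lookback_h) & (series.grid <= t_lm) & ~np.isnan(x)
        if m.any():
            values[ch] = float(x[np.nonzero(m)[0][-1]])
            flags[ch] = False
        else:
            values[ch] = np.nan
            flags[ch] = True
    if imputation_state is not None and imputation_state.fitted:
        for ch in spec.dynamic:
            if flags[ch]:
                values[ch] = imputation_state.medians.get(ch, 0.0)
    return values, flags


@dataclass
class StackedDataset:
    """Stacked landmark rows: one row per (admission, series, landmark)."""

    df: pd.DataFrame
    covariate_spec: CovariateSpec
    grid: LandmarkGrid
    s_center: float = 0.0

    @property
    def landmark_levels(self) -> np.ndarray:
        col = "lm_level" if "lm_level" in self.df.columns else "t_lm"
        return np.sort(self.df[col].unique())

    def __len__(self) -> int:
        return len(self.df)


def build_stacked_dataset(
    bundle: CohortBundle,
    grid: LandmarkGrid,
    spec: CovariateSpec,
    cnn_scores: Optional[pd.DataFrame] = None,
) -> StackedDataset:
    """Assemble the stacked landmark dataset.

    Dynamic covariates are LOCF values within ``spec.lookback_h``; missing
    entries stay NaN with their ``imputed_*`` flag set, to be filled by a
    fold-specific :class:`ImputationState`.  Landmark time enters as s
    (days, centred at the stacked mean) and s^2.  CNN scores, when given,
    are joined on (admission_id, series_id, t_lm).
    """
    grid.validate()
    adm_index = {a.admission_id: a for a in bundle.admissions}
    clin_index = {c.admission_id: c for c in bundle.clinical}
    pat_index = {a.admission_id: a.patient_id for a in bundle.admissions}
    rows = []
    for tl in bundle.timelines:
        adm = adm_index[tl.admission_id]
        series = clin_index.get(tl.admission_id)
        for seg in segment_at_risk_periods(tl, grid):
            for t_lm in place_landmarks(seg, grid):
                outcome, u = label_window(t_lm, tl, grid)
                row = {
                    "admission_id": tl.admission_id,
                    "patient_id": pat_index[tl.admission_id],
                    "series_id": seg.series_id,
                    "t_lm": float(t_lm),
                    "outcome_type": outcome,
                    "outcome_time": float(u),
                }
                for name in spec.static:
                    row[name] = adm.covariates[name]
                if series is not None:
                    for ch in spec.dynamic:
                        x = series.channels[ch]
                        m = (
                            (series.grid >= t_lm - spec.lookback_h)
                            & (series.grid <= t_lm)
                            & ~np.isnan(x)
                        )
                        if m.any():
                            row[ch] = float(x[np.nonzero(m)[0][-1]])
                            row[f"imputed_{ch}"] = False
                        else:
                            row[ch] = np.nan
                            row[f"imputed_{ch}"] = True
                rows.append(row)
    cols = (
        ["admission_id", "patient_id", "series_id", "t_lm", "outcome_type", "outcome_time"]
        + list(spec.static)
        + list(spec.dynamic)
        + [f"imputed_{ch}" for ch in spec.dynamic]
    )
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        dup = df.duplicated(subset=["admission_id", "series_id", "t_lm"])
        if dup.any():
            raise ValueError("duplicate (admission, series, t_lm) landmark rows")
        df = df.sort_values(["admission_id", "series_id", "t_lm"], kind="mergesort")
        df = df.reset_index(drop=True)
    s = df["t_lm"] / 24.0 if len(df) else pd.Series(dtype=float)
    s_center = float(s.mean()) if len(df) else 0.0
    df["s"] = s - s_center
    df["s2"] = df["s"] ** 2
    # nominal landmark level: t_lm binned to the admission-wide 8-h grid
    # (reset-series landmarks are off-grid unless realign_resets is set);
    # used for stratified baselines and per-landmark reporting
    df["lm_level"] = (
        grid.first_landmark_h
        + grid.spacing_h * np.round((df["t_lm"] - grid.first_landmark_h) / grid.spacing_h)
        if len(df)
        else pd.Series(dtype=float)
    )
    if cnn_scores is not None:
        df = join_scores(df, cnn_scores)
    return StackedDataset(df=df, covariate_spec=spec, grid=grid, s_center=s_center)


def join_scores(df: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join CNN scores on (admission_id, series_id, t_lm).

    The landmark time is matched on integer minutes: reset-series landmark
    times are irrational-looking floats whose last bit does not survive a
    CSV round-trip.
    """
    left = df.copy()
    right = scores[["admission_id", "series_id", "t_lm", "cnn_score"]].copy()
    left["_t_min"] = (left["t_lm"] * 60).round().astype(np.int64)
    right["_t_min"] = (right["t_lm"] * 60).round().astype(np.int64)
    merged = left.merge(
        right.drop(columns=["t_lm"]),
        on=["admission_id", "series_id", "_t_min"],
        how="left",
    )
    return merged.drop(columns=["_t_min"])
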