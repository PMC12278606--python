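"""Landmark construction: segments, placement, labelling, covariates, leakage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icuai.config import CovariateSpec, LandmarkGrid
from icuai.landmarks import (
    ImputationState,
    assemble_covariates,
    build_stacked_dataset,
    label_window,
    place_landmarks,
    segment_at_risk_periods,
)

from conftest import make_bundle, make_clinical, make_timeline


GRID = LandmarkGrid()


class TestSegments:
    def test_onset_then_discharge(self):
        tl = make_timeline(onsets=[120.0], terminal="discharge", terminal_time=200.0)
        segs = segment_at_risk_periods(tl, GRID)
        assert [(s.start_h, s.end_h, s.end_reason) for s in segs] == [
            (24.0, 120.0, "infection"),
            (168.0, 200.0, "discharge"),
        ]
        assert [s.series_id for s in segs] == [0, 1]

    def test_death_without_onset(self):
        tl = make_timeline(terminal="death", terminal_time=60.0)
        segs = segment_at_risk_periods(tl, GRID)
        assert [(s.start_h, s.end_h, s.end_reason) for s in segs] == [(24.0, 60.0, "death")]

    def test_death_inside_blackout_swallows_reset(self):
        tl = make_timeline(onsets=[100.0], terminal="death", terminal_time=130.0)
        segs = segment_at_risk_periods(tl, GRID)
        assert len(segs) == 1
        assert (segs[0].start_h, segs[0].end_h) == (24.0, 100.0)

    def test_malformed_timeline_raises(self):
        tl = make_timeline(onsets=[250.0], terminal_time=200.0)
        with pytest.raises(ValueError):
            segment_at_risk_periods(tl, GRID)


class TestPlacement:
    def test_initial_series_count(self):
        tl = make_timeline(onsets=[120.0], terminal_time=200.0)
        seg0 = segment_at_risk_periods(tl, GRID)[0]
        ts = place_landmarks(seg0, GRID)
        assert list(ts) == [48, 56, 64, 72, 80, 88, 96, 104, 112]

    def test_reset_series_restarts_clock(self):
        tl = make_timeline(onsets=[120.0], terminal_time=200.0)
        seg1 = segment_at_risk_periods(tl, GRID)[1]
        assert list(place_landmarks(seg1, GRID)) == [168, 176, 184, 192]

    def test_boundary_landmark_dropped(self):
        tl = make_timeline(terminal_time=48.0 + 1e-12)
        # segment [24, 48]: landmark 48 is not strictly inside
        from icuai.landmarks import AtRiskSegment

        seg = AtRiskSegment("a1", 0, 24.0, 48.0, "discharge")
        assert len(place_landmarks(seg, GRID)) == 0

    def test_realigned_resets_snap_to_admission_grid(self):
        grid = LandmarkGrid(realign_resets=True)
        tl = make_timeline(onsets=[121.0], terminal_time=220.0)
        seg1 = segment_at_risk_periods(tl, grid)[1]  # starts at 169
        ts = place_landmarks(seg1, grid)
        assert ts[0] == 176.0  # next admission-grid point (48 + 8k) after 169
        assert all((t - 48.0) % 8.0 == 0 for t in ts)


class TestLabels:
    def test_infection_inside_window(self):
        tl = make_timeline(onsets=[120.0], terminal_time=200.0)
        assert label_window(112.0, tl, GRID) == ("infection", 8.0)

    def test_censored_at_horizon(self):
        tl = make_timeline(terminal="discharge", terminal_time=200.0)
        assert label_window(48.0, tl, GRID) == ("censored", 48.0)

    def test_discharge_inside_window(self):
        tl = make_timeline(terminal="discharge", terminal_time=200.0)
        assert label_window(192.0, tl, GRID) == ("discharge", 8.0)

    def test_outside_segment_raises(self):
        tl = make_timeline(onsets=[120.0], terminal_time=200.0)
        with pytest.raises(ValueError):
            label_window(140.0, tl, GRID)  # inside the blackout

    def test_tie_precedence_infection_over_death(self):
        # onset and death effectively tied at u = 8 after the landmark
        tl = make_timeline(onsets=[56.0], terminal="death", terminal_time=56.0 + 1e-12)
        outcome, u = label_window(48.0, tl, GRID)
        assert outcome == "infection"
        assert u == pytest.approx(8.0)

    def test_administrative_end_censors_at_its_time(self):
        tl = make_timeline(terminal="administrative", terminal_time=80.0)
        assert label_window(48.0, tl, GRID) == ("censored", 32.0)


class TestCovariates:
    def make(self):
        tl = make_timeline(terminal_time=200.0)
        crp = lambda t: np.where(t <= 96.0, 120.0, np.nan)
        clin = make_clinical("a1", 200.0, values={"crp": crp})
        return make_bundle([tl], clinical=[clin])

    def test_recent_observation_used(self):
        b = self.make()
        vals, flags = assemble_covariates(b, "a1", 100.0, 24.0, CovariateSpec())
        assert vals["crp"] == 120.0 and flags["crp"] is False

    def test_recency_rule_prefers_latest(self):
        tl = make_timeline(terminal_time=200.0)
        crp = lambda t: np.where(t == 88.0, 50.0, np.where(t == 96.0, 99.0, np.nan))
        clin = make_clinical("a1", 200.0, values={"crp": crp})
        b = make_bundle([tl], clinical=[clin])
        vals, _ = assemble_covariates(b, "a1", 98.0, 24.0, CovariateSpec())
        assert vals["crp"] == 99.0

    def test_missing_lookback_uses_training_median_and_flag(self):
        b = self.make()
        state = ImputationState()
        state.medians = {"crp": 77.0}
        state.fitted = True
        vals, flags = assemble_covariates(b, "a1", 190.0, 24.0, CovariateSpec(), state)
        assert vals["crp"] == 77.0 and flags["crp"] is True

    def test_unknown_channel_errors(self):
        b = self.make()
        bad = CovariateSpec(dynamic=("nope",))
        with pytest.raises(KeyError):
            assemble_covariates(b, "a1", 100.0, 24.0, bad)


class TestStacked:
    def test_row_count_single_admission(self, spec):
        tl = make_timeline(onsets=[120.0], terminal_time=200.0)
        b = make_bundle([tl])
        ds = build_stacked_dataset(b, GRID, spec)
        assert len(ds) == 13  # 9 initial + 4 reset landmarks

    def test_empty_cohort(self, spec):
        ds = build_stacked_dataset(make_bundle([]), GRID, spec)
        assert len(ds) == 0
        assert ds.covariate_spec is spec

    def test_deterministic_row_count(self, events_bundle, spec):
        d1 = build_stacked_dataset(events_bundle, GRID, spec)
        d2 = build_stacked_dataset(events_bundle, GRID, spec)
        assert len(d1) == len(d2)
        pd.testing.assert_frame_equal(d1.df, d2.df)

    def test_no_future_leakage(self, spec):
        """A poisoned future CRP value must not reach any earlier landmark row."""
        tl = make_timeline(terminal_time=200.0)
        poison_at = 104.0
        crp = lambda t: np.where(t >= poison_at, 1e9, 100.0)
        clin = make_clinical("a1", 200.0, values={"crp": crp})
        b = make_bundle([tl], clinical=[clin])
        ds = build_stacked_dataset(b, GRID, spec)
        early = ds.df[ds.df["t_lm"] < poison_at]
        assert (early["crp"] < 1e6).all()

    def test_blackout_has_no_landmarks(self, events_bundle, spec):
        ds = build_stacked_dataset(events_bundle, GRID, spec)
        tmap = {t.admission_id: t for t in events_bundle.timelines}
        for adm, grp in ds.df.groupby("admission_id"):
            for onset in tmap[adm].infection_onsets:
                inside = (grp["t_lm"] > onset) & (grp["t_lm"] < onset + 48.0)
                assert not inside.any()

    def test_label_consistency(self, events_bundle, spec):
        ds = build_stacked_dataset(events_bundle, GRID, spec)
        tmap = {t.admission_id: t for t in events_bundle.timelines}
        inf = ds.df[ds.df["outcome_type"] == "infection"]
        for _, row in inf.iterrows():
            ons = tmap[row["admission_id"]].infection_onsets
            assert any(row["t_lm"] < o <= row["t_lm"] + 48.0 for o in ons)
        assert (ds.df["outcome_time"] <= 48.0).all()
        assert (ds.df["outcome_time"] > 0.0).all()

    def test_landmark_time_terms(self, events_bundle, spec):
        ds = build_stacked_dataset(events_bundle, GRID, spec)
        s_raw = ds.df["t_lm"] / 24.0
        assert ds.df["s"].to_numpy() == pytest.approx((s_raw - s_raw.mean()).to_numpy())
        assert ds.df["s2"].to_numpy() == pytest.approx((ds.df["s"] ** 2).to_numpy())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    onset1=st.floats(50.0, 300.0),
    gap=st.floats(48.5, 200.0),
    tail=st.floats(0.1, 300.0),
)
def test_segments_partition_property(onset1, gap, tail):
    """Segments never overlap blackouts, stay ordered, and landmarks lie
    strictly inside their segment."""
    onsets = [onset1, onset1 + gap]
    tl = make_timeline(onsets=onsets, terminal_time=onsets[-1] + tail)
    segs = segment_at_risk_periods(tl, GRID)
    prev_end = 0.0
    for s in segs:
        assert s.start_h < s.end_h
        assert s.start_h >= prev_end
        prev_end = s.end_h
        for onset in onsets:
            assert not (onset < s.start_h < onset + 48.0 - 1e-9) or s.start_h == onset + 48.0
        for t_lm in place_landmarks(s, GRID):
            assert s.start_h <= t_lm < s.end_h
            for onset in onsets:
                # blackout is half-open: landmarking resumes exactly at +48 h
                assert not (onset < t_lm < onset + 48.0)
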