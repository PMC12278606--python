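import numpy as np
import pandas as pd
import pytest

from icuai.cohort import (
    AdmissionRecord,
    ClinicalSeries,
    CohortBundle,
    EventTimeline,
    simulate_cohort,
)
from icuai.config import (
    CLINICAL_CHANNELS,
    CovariateSpec,
    GeneratorConfig,
    LandmarkGrid,
    STATIC_COVARIATES,
)


@pytest.fixture(scope="session")
def grid():
    return LandmarkGrid()


@pytest.fixture(scope="session")
def spec():
    return CovariateSpec()


@pytest.fixture(scope="session")
def small_bundle():
    """Small cohort with vitals, reused by read-only tests."""
    cfg = GeneratorConfig(n_admissions=40, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def events_bundle():
    """Medium event-only cohort (no vitals) for landmark/Cox tests."""
    cfg = GeneratorConfig(n_admissions=300, seed=7)
    return simulate_cohort(cfg, with_vitals=False)


def default_covariates():
    return {name: (1.0 if name in ("male",) else 60.0 if name == "age" else 0.0)
            for name in STATIC_COVARIATES}


def make_timeline(admission_id="a1", onsets=(), terminal="discharge", terminal_time=200.0):
    return EventTimeline(
        admission_id=admission_id,
        infection_onsets=list(onsets),
        terminal_event=terminal,
        terminal_time=terminal_time,
    )


def make_clinical(admission_id, terminal_time, values=None):
    """Dense 8-hourly series; ``values`` overrides {channel: callable(grid)}."""
    t = np.arange(0.0, terminal_time, 8.0)
    channels = {}
    for name, (base, *_rest) in CLINICAL_CHANNELS.items():
        channels[name] = np.full(len(t), float(base))
    if values:
        for name, fn in values.items():
            channels[name] = np.asarray(fn(t), float)
    return ClinicalSeries(admission_id=admission_id, grid=t, channels=channels)


def make_bundle(timelines, clinical=None):
    admissions = [
        AdmissionRecord(patient_id=f"p_{t.admission_id}", admission_id=t.admission_id,
                        covariates=default_covariates())
        for t in timelines
    ]
    if clinical is None:
        clinical = [make_clinical(t.admission_id, t.terminal_time) for t in timelines]
    return CohortBundle(
        admissions=admissions,
        timelines=timelines,
        clinical=clinical,
        vitals=[],
        config_echo=GeneratorConfig(n_admissions=len(timelines)),
        latents=pd.DataFrame(
            {"admission_id": [t.admission_id for t in timelines],
             "frailty": 1.0, "inf_multiplier": 1.0}
        ),
    )
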