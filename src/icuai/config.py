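"""Configuration objects shared across the pipeline.

All configs are plain dataclasses that round-trip losslessly through JSON
(`to_dict` / `from_dict`), so a run is fully described by one file plus a
master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

VITAL_CHANNELS = ("heart_rate", "map", "pulse_pressure", "respiratory_rate", "spo2")

#: default clinical channels: name -> (baseline, between-patient SD, noise SD,
#: observation cadence in hours, lower clip, upper clip)
CLINICAL_CHANNELS = {
    "crp": (50.0, 30.0, 15.0, 24.0, 0.0, 600.0),
    "temperature": (37.0, 0.4, 0.3, 8.0, 30.0, 43.0),
    "wbc": (11.0, 3.5, 1.5, 24.0, 0.1, 80.0),
    "platelets": (220.0, 70.0, 20.0, 24.0, 5.0, 1200.0),
    "creatinine": (90.0, 35.0, 10.0, 24.0, 10.0, 1200.0),
    "fio2": (0.40, 0.08, 0.04, 8.0, 0.21, 1.0),
    "sofa": (7.0, 3.0, 0.8, 8.0, 0.0, 24.0),
}

STATIC_COVARIATES = (
    "age",
    "male",
    "surgical_admission",
    "immunodeficiency",
    "diabetes",
    "malignancy",
    "cardiovascular_insufficiency",
    "renal_insufficiency",
    "respiratory_insufficiency",
    "prior_icu_admission",
    "sepsis_at_admission",
    "apache_iv",
    "sofa_baseline",
)

#: marginal sampling model for static covariates: ("binary", prevalence) or
#: ("normal", mean, sd, lo, hi).  Prevalences follow the published cohort
#: description of a mixed medical-surgical tertiary ICU.
STATIC_MARGINALS = {
    "age": ("normal", 61.0, 14.0, 18.0, 95.0),
    "male": ("binary", 0.64),
    "surgical_admission": ("binary", 0.43),
    "immunodeficiency": ("binary", 0.163),
    "diabetes": ("binary", 0.161),
    "malignancy": ("binary", 0.165),
    "cardiovascular_insufficiency": ("binary", 0.180),
    "renal_insufficiency": ("binary", 0.085),
    "respiratory_insufficiency": ("binary", 0.078),
    "prior_icu_admission": ("binary", 0.153),
    "sepsis_at_admission": ("binary", 0.429),
    "apache_iv": ("normal", 80.0, 28.0, 0.0, 220.0),
    "sofa_baseline": ("normal", 7.0, 3.0, 0.0, 24.0),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic ICU cohort generator.

    Hazards are per ICU day; times inside the generated objects are hours
    from ICU admission.  The shipped defaults are calibrated so that the
    simulated cohort reproduces the incidence statistics of the reference
    cohort: ~3.5% daily infection incidence among at-risk days, ~18.8% of
    admissions with at least one ICU-acquired infection, first onset at a
    median of ~7 days, recurrent onsets at a median of ~14.5 days and ~4.4%
    of patients with recurrence.
    """

    n_admissions: int = 1000
    seed: int = 0
    lambda_inf: float = 0.035
    lambda_disch: float = 0.20
    lambda_death: float = 0.023
    frailty_sigma: float = 0.88
    post_infection_disch_factor: float = 0.55
    post_infection_death_factor: float = 2.0
    beta_inf: dict = field(
        default_factory=lambda: {
            "surgical_admission": 0.30,
            "immunodeficiency": 0.35,
            "apache_iv": 0.20,  # per SD of APACHE-IV
        }
    )
    signature_lead_h: float = 24.0
    signature_amplitudes: dict = field(
        default_factory=lambda: {
            "heart_rate": 15.0,
            "respiratory_rate": 6.0,
            "map": -10.0,
            "pulse_pressure": -5.0,
            "spo2": -2.0,
        }
    )
    signature_jitter: float = 0.30
    #: channel -> (delta at onset, ramp length hours); platelets delta is relative
    covariate_drift: dict = field(
        default_factory=lambda: {
            "crp": (80.0, 48.0),
            "temperature": (1.2, 24.0),
            "platelets": (-0.30, 72.0),
        }
    )
    missingness_rate: float = 0.02
    max_followup_days: float = 23.0
    extra_clinical_channels: dict = field(default_factory=dict)
    #: scales the AR(1) innovation SD of every vital channel (0 = noise-free
    #: vitals, useful for isolating the deterioration signature)
    vital_noise_scale: float = 1.0

    def validate(self) -> None:
        if self.n_admissions <= 0:
            raise ValueError("n_admissions must be positive")
        for name in ("lambda_inf", "lambda_disch", "lambda_death"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_disch == 0 and self.lambda_death == 0:
            raise ValueError(
                "terminal hazards are all zero: admissions would never terminate"
            )
        if self.frailty_sigma < 0:
            raise ValueError("frailty_sigma must be >= 0")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.max_followup_days <= 2:
            raise ValueError("max_followup_days must exceed 2 (inclusion criterion)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_drift"] = {k: list(v) for k, v in self.covariate_drift.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "covariate_drift" in d:
            d["covariate_drift"] = {k: tuple(v) for k, v in d["covariate_drift"].items()}
        return cls(**d)


@dataclass
class LandmarkGrid:
    """Landmarking layout: 8-hourly landmarks, sliding prediction window.

    Observation starts 24 h after ICU admission (run-in exclusion) and the
    first landmark sits at 48 h.  After an infection onset a 48-h blackout
    applies; landmarking then resumes on a fresh series whose clock starts
    at blackout end (``realign_resets`` re-aligns reset landmarks to the
    admission-wide 8-h grid instead).
    """

    spacing_h: float = 8.0
    horizon_h: float = 48.0
    first_landmark_h: float = 48.0
    runin_exclusion_h: float = 24.0
    blackout_h: float = 48.0
    realign_resets: bool = False
    reset_runin_h: float = 0.0

    def validate(self) -> None:
        if self.horizon_h <= 0:
            raise ValueError("horizon must be positive")
        if self.spacing_h <= 0:
            raise ValueError("spacing must be positive")
        if self.first_landmark_h < self.runin_exclusion_h:
            raise ValueError("first landmark precedes run-in exclusion")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkGrid":
        return cls(**d)


@dataclass
class CnnConfig:
    """Architecture and training hyperparameters of the 1-D CNN.

    Each block is (convolution, max-pool, dropout); the flattened feature
    map feeds a dense sigmoid output.  The reference preset uses five such
    blocks.
    """

    filters: tuple = (16, 16, 32, 32, 64)
    kernel_size: int = 7
    pool_size: int = 2
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    patience: int = 3
    val_fraction: float = 0.15
    window_minutes: int = 480
    class_weighting: bool = True

    @property
    def n_blocks(self) -> int:
        return len(self.filters)

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("at least one convolution block required")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolutions)")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        t = self.window_minutes
        for _ in range(self.n_blocks):
            t = t // self.pool_size
        if t < 1:
            raise ValueError("window too short for the pooling cascade")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filters"] = list(self.filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CnnConfig":
        d = dict(d)
        d["filters"] = tuple(d["filters"])
        return cls(**d)

    @classmethod
    def reference_preset(cls) -> "CnnConfig":
        """Five blocks of (conv, pool, dropout) + dense sigmoid output."""
        return cls()


@dataclass
class CovariateSpec:
    """Which covariates enter the landmark rows and the Cox designs.

    ``static`` are copied from the admission record; ``dynamic`` are
    last-observation-carried-forward values of the 8-hourly clinical
    channels.  ``include_landmark_terms`` adds centred landmark time s and
    s^2 to the Cox design (pooled-baseline supermodels only — within a
    landmark stratum they are constant and are dropped automatically).
    ``include_cnn_score`` distinguishes the deep model from the base model.
    """

    static: tuple = (
        "age",
        "male",
        "surgical_admission",
        "immunodeficiency",
        "sepsis_at_admission",
        "apache_iv",
    )
    dynamic: tuple = ("crp", "temperature", "wbc", "platelets", "creatinine", "fio2", "sofa")
    lookback_h: float = 24.0
    include_landmark_terms: bool = True
    include_cnn_score: bool = False

    @property
    def covariates(self) -> tuple:
        return tuple(self.static) + tuple(self.dynamic)

    def cox_covariates(self, cause: str, stratified: bool) -> list:
        cols = list(self.covariates)
        if self.include_landmark_terms and not stratified:
            cols += ["s", "s2"]
        if self.include_cnn_score and cause == "infection":
            cols += ["cnn_score"]
        return cols

    def with_cnn(self, flag: bool = True) -> "CovariateSpec":
        return dataclasses.replace(self, include_cnn_score=flag)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["static"] = list(self.static)
        d["dynamic"] = list(self.dynamic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSpec":
        d = dict(d)
        d["static"] = tuple(d["static"])
        d["dynamic"] = tuple(d["dynamic"])
        return cls(**d)


def derive_seed(master_seed: int, module: str) -> int:
    """Derive a module seed from the master seed by hashing.

    Hash-based derivation keeps streams independent and stable: adding a
    module never shifts another module's stream.  Result < 2**31.
    """
    h = hashlib.sha256(f"{master_seed}:{module}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def config_hash(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]
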