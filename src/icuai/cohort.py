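"""Synthetic ICU cohort generator.

Emulates the statistical structure the dynamic-prediction analysis assumes:
per-admission static covariates, recurrent infection onsets competing with
death and ICU discharge, 8-hourly clinical series that drift before onset,
and 1-minute vital-sign streams carrying a pre-onset deterioration
signature.

Event mechanics
---------------
Times are hours from ICU admission.  Events are sampled from competing
exponential cause-specific hazards, piecewise-constant over regimes:

* before 48 h: all hazards zero — the inclusion criterion (ICU stay > 48 h)
  holds by construction, and infections with onset <= 48 h are not
  ICU-acquired by definition;
* at risk (past 48 h, outside blackouts): infection hazard
  ``lambda_inf * r`` where ``r`` is a mean-one multiplier driven by static
  covariates, plus terminal hazards ``lambda_death * Z`` and
  ``lambda_disch * Z`` with a per-patient log-normal frailty ``Z`` (mean 1);
* blackout, the 48 h after an onset: infection hazard suppressed, terminal
  hazards active;
* after any infection: discharge hazard multiplied by
  ``post_infection_disch_factor`` (< 1, infected patients stay longer) and
  death hazard by ``post_infection_death_factor`` (> 1).

Follow-up is administratively truncated at ``max_followup_days``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .config import (
    CLINICAL_CHANNELS,
    GeneratorConfig,
    STATIC_COVARIATES,
    STATIC_MARGINALS,
    VITAL_CHANNELS,
)

TERMINAL_EVENTS = ("death", "discharge", "administrative")

#: per-channel vital-sign model: (baseline, between-patient SD,
#: circadian amplitude, AR(1) innovation SD, lower clip, upper clip)
VITAL_MODEL = {
    "heart_rate": (80.0, 8.0, 3.0, 1.0, 20.0, 220.0),
    "map": (75.0, 7.0, 2.0, 1.2, 30.0, 160.0),
    "pulse_pressure": (45.0, 6.0, 1.0, 0.9, 10.0, 120.0),
    "respiratory_rate": (16.0, 2.5, 0.8, 0.5, 4.0, 60.0),
    "spo2": (97.0, 1.0, 0.3, 0.25, 50.0, 100.0),
}
_AR_PHI = 0.97


@dataclass
class AdmissionRecord:
    patient_id: str
    admission_id: str
    covariates: dict  # name -> value, keys = STATIC_COVARIATES


@dataclass
class EventTimeline:
    admission_id: str
    infection_onsets: list  # hours, ordered
    terminal_event: str  # death | discharge | administrative
    terminal_time: float  # hours

    def validate(self, blackout_h: float = 48.0) -> None:
        if self.terminal_event not in TERMINAL_EVENTS:
            raise ValueError(f"unknown terminal event {self.terminal_event!r}")
        if self.terminal_time <= 48.0:
            raise ValueError("inclusion criterion violated: terminal_time <= 48 h")
        prev = None
        for t in self.infection_onsets:
            if t >= self.terminal_time:
                raise ValueError("infection onset at or after terminal time")
            if prev is not None and t - prev <= blackout_h:
                raise ValueError("two onsets within the blackout window")
            prev = t


@dataclass
class ClinicalSeries:
    admission_id: str
    grid: np.ndarray  # hours, 8-hourly
    channels: dict  # name -> np.ndarray aligned to grid, NaN = unobserved


@dataclass
class VitalStream:
    admission_id: str
    values: np.ndarray  # (n_minutes, 5) float32, NaN = missing minute
    channels: tuple = VITAL_CHANNELS

    @property
    def n_minutes(self) -> int:
        return self.values.shape[0]


@dataclass
class CohortBundle:
    admissions: list
    timelines: list
    clinical: list
    vitals: list
    config_echo: GeneratorConfig
    latents: Optional[pd.DataFrame] = None  # admission_id, frailty Z, infection multiplier r

    def timeline(self, admission_id: str) -> EventTimeline:
        return self._tl_index()[admission_id]

    def _tl_index(self) -> dict:
        if not hasattr(self, "_tl_cache"):
            self._tl_cache = {t.admission_id: t for t in self.timelines}
        return self._tl_cache

    def admissions_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.admissions:
            row = {"patient_id": a.patient_id, "admission_id": a.admission_id}
            row.update(a.covariates)
            rows.append(row)
        return pd.DataFrame(rows)


def _infection_multiplier(cov: dict, beta: dict) -> float:
    """Mean-one covariate multiplier on the infection hazard.

    Continuous covariates (age, apache_iv, sofa_baseline) take their effect
    per SD.  The analytic normaliser keeps E[r] = 1 so that ``lambda_inf``
    remains the marginal cause-specific hazard.
    """
    log_r = 0.0
    log_norm = 0.0
    for name, b in beta.items():
        kind = STATIC_MARGINALS[name]
        if kind[0] == "binary":
            p = kind[1]
            log_r += b * (cov[name] - p)
            log_norm += math.log(math.exp(-b * p) * (1 - p + p * math.exp(b)))
        else:
            _, mu, sd, _, _ = kind
            z = (cov[name] - mu) / sd
            log_r += b * z
            log_norm += b * b / 2.0  # E[exp(bZ)] for standard normal Z
    return math.exp(log_r - log_norm)


def _sample_static(rng: np.random.Generator) -> dict:
    cov = {}
    for name in STATIC_COVARIATES:
        spec = STATIC_MARGINALS[name]
        if spec[0] == "binary":
            cov[name] = int(rng.random() < spec[1])
        else:
            _, mu, sd, lo, hi = spec
            cov[name] = float(np.clip(rng.normal(mu, sd), lo, hi))
    cov["apache_iv"] = round(cov["apache_iv"], 1)
    cov["sofa_baseline"] = round(cov["sofa_baseline"])
    cov["age"] = round(cov["age"], 1)
    return cov


def _simulate_timeline(
    rng: np.random.Generator, cfg: GeneratorConfig, z: float, r: float
) -> tuple:
    """Sample one admission's event timeline (hours)."""
    lam_inf = cfg.lambda_inf / 24.0 * r
    lam_death = cfg.lambda_death / 24.0 * z
    lam_disch = cfg.lambda_disch / 24.0 * z
    t_max = cfg.max_followup_days * 24.0

    t = 48.0
    onsets: list = []
    infected = False
    while True:
        ld = lam_death * (cfg.post_infection_death_factor if infected else 1.0)
        ls = lam_disch * (cfg.post_infection_disch_factor if infected else 1.0)
        lam_term = ld + ls
        lam_tot = lam_inf + lam_term
        if lam_tot <= 0:
            return onsets, "administrative", t_max
        gap = rng.exponential(1.0 / lam_tot)
        if t + gap >= t_max:
            return onsets, "administrative", t_max
        t = t + gap
        u = rng.random() * lam_tot
        if u < lam_inf:
            onsets.append(t)
            infected = True
            # blackout: infection hazard suppressed for blackout_h, terminal active
            ld = lam_death * cfg.post_infection_death_factor
            ls = lam_disch * cfg.post_infection_disch_factor
            lam_term = ld + ls
            if lam_term > 0:
                gap_term = rng.exponential(1.0 / lam_term)
            else:
                gap_term = math.inf
            if t + gap_term <= t + 48.0:
                tt = t + gap_term
                if tt >= t_max:
                    return onsets, "administrative", t_max
                ev = "death" if rng.random() * lam_term < ld else "discharge"
                return onsets, ev, tt
            t = t + 48.0
            if t >= t_max:
                return onsets, "administrative", t_max
        elif u < lam_inf + ld:
            return onsets, "death", t
        else:
            return onsets, "discharge", t


def _ar1(rng: np.random.Generator, n: int, innov_sd: float) -> np.ndarray:
    eps = rng.normal(0.0, innov_sd, size=n)
    # stationary AR(1): x_t = phi x_{t-1} + eps_t
    x = _signal.lfilter([1.0], [1.0, -_AR_PHI], eps)
    x[0] = rng.normal(0.0, innov_sd / math.sqrt(1 - _AR_PHI**2))
    return x


def _ramp_profile(t: np.ndarray, onset: float, lead: float, decay: float) -> np.ndarray:
    """0->1 linear ramp over [onset-lead, onset], linear decay over [onset, onset+decay]."""
    up = np.clip((t - (onset - lead)) / max(lead, 1e-9), 0.0, 1.0)
    down = np.where(t > onset, np.clip(1.0 - (t - onset) / max(decay, 1e-9), 0.0, 1.0), 1.0)
    return up * down


def _simulate_clinical(
    rng: np.random.Generator, cfg: GeneratorConfig, tl: EventTimeline, adm: AdmissionRecord
) -> ClinicalSeries:
    grid = np.arange(0.0, tl.terminal_time, 8.0)
    channels = {}
    chan_specs = dict(CLINICAL_CHANNELS)
    for name, (base, bsd) in cfg.extra_clinical_channels.items():
        chan_specs[name] = (base, bsd, bsd * 0.3, 8.0, -np.inf, np.inf)
    for name, (base, bsd, nsd, cadence, lo, hi) in chan_specs.items():
        if name == "sofa":
            level = float(adm.covariates["sofa_baseline"])
        else:
            level = base + rng.normal(0.0, bsd)
        x = level + _ar1(rng, len(grid), nsd)
        drift = cfg.covariate_drift.get(name)
        if drift is not None:
            delta, ramp_h = drift
            for onset in tl.infection_onsets:
                prof = _ramp_profile(grid, onset, ramp_h, 48.0)
                if name == "platelets":
                    x = x * (1.0 + delta * prof)  # relative drop
                else:
                    x = x + delta * prof
        x = np.clip(x, lo, hi)
        # observation cadence: labs ~daily, bedside channels 8-hourly
        observed = np.isclose(np.mod(grid, cadence), 0.0)
        x = np.where(observed, x, np.nan)
        channels[name] = x
    return ClinicalSeries(admission_id=tl.admission_id, grid=grid, channels=channels)


def _simulate_vitals(
    rng: np.random.Generator, cfg: GeneratorConfig, tl: EventTimeline
) -> VitalStream:
    n_min = int(tl.terminal_time * 60.0)
    t_h = np.arange(n_min) / 60.0
    out = np.empty((n_min, len(VITAL_CHANNELS)), dtype=np.float32)
    phase = rng.random() * 2 * math.pi
    jitters = {
        onset: 1.0 + cfg.signature_jitter * (2 * rng.random() - 1.0)
        for onset in tl.infection_onsets
    }
    for j, name in enumerate(VITAL_CHANNELS):
        base, bsd, camp, innov, lo, hi = VITAL_MODEL[name]
        innov = innov * cfg.vital_noise_scale
        level = base + rng.normal(0.0, bsd)
        x = level + camp * np.sin(2 * math.pi * t_h / 24.0 + phase)
        if innov > 0:
            x = x + _ar1(rng, n_min, innov)
        amp = cfg.signature_amplitudes.get(name, 0.0)
        if amp != 0.0:
            for onset, jit in jitters.items():
                x = x + amp * jit * _ramp_profile(t_h, onset, cfg.signature_lead_h, 48.0)
        np.clip(x, lo, hi, out=x)
        out[:, j] = x
    if cfg.missingness_rate > 0:
        drop = rng.random(n_min) < cfg.missingness_rate
        out[drop, :] = np.nan
        # a few device-disconnect gaps of 5-30 minutes across all channels
        for _ in range(rng.poisson(2.0)):
            g0 = rng.integers(0, max(n_min - 30, 1))
            out[g0 : g0 + rng.integers(5, 31), :] = np.nan
    return VitalStream(admission_id=tl.admission_id, values=out)


def simulate_cohort(
    config: GeneratorConfig,
    with_clinical: bool = True,
    with_vitals: bool = True,
) -> CohortBundle:
    """Generate a synthetic cohort; the seed fully determines the output.

    ``with_clinical`` / ``with_vitals`` skip generation of the heavy
    longitudinal components (e.g. for incidence-only studies); event
    timelines are identical either way because every admission draws its
    component RNG streams from dedicated spawned seeds.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_admissions)
    admissions, timelines, clinical, vitals = [], [], [], []
    lat_rows = []
    for i, child in enumerate(children):
        ss_cov, ss_ev, ss_clin, ss_vit = child.spawn(4)
        rng_cov = np.random.default_rng(ss_cov)
        cov = _sample_static(rng_cov)
        z = (
            math.exp(
                config.frailty_sigma * rng_cov.standard_normal()
                - config.frailty_sigma**2 / 2.0
            )
            if config.frailty_sigma > 0
            else 1.0
        )
        r = _infection_multiplier(cov, config.beta_inf) if config.beta_inf else 1.0
        adm_id = f"adm{i:06d}"
        adm = AdmissionRecord(patient_id=f"pat{i:06d}", admission_id=adm_id, covariates=cov)
        onsets, ev, tt = _simulate_timeline(np.random.default_rng(ss_ev), config, z, r)
        tl = EventTimeline(adm_id, onsets, ev, tt)
        admissions.append(adm)
        timelines.append(tl)
        lat_rows.append({"admission_id": adm_id, "frailty": z, "inf_multiplier": r})
        if with_clinical:
            clinical.append(_simulate_clinical(np.random.default_rng(ss_clin), config, tl, adm))
        if with_vitals:
            vitals.append(_simulate_vitals(np.random.default_rng(ss_vit), config, tl))
    return CohortBundle(
        admissions=admissions,
        timelines=timelines,
        clinical=clinical,
        vitals=vitals,
        config_echo=config,
        latents=pd.DataFrame(lat_rows),
    )


# ---------------------------------------------------------------------------
# incidence summary


@dataclass
class IncidenceSummary:
    """Cohort-level infection incidence, computed as in the study report.

    ``daily_incidence`` is onsets per at-risk patient-day, where at-risk
    exposure is the exact time (in days) spent in ICU past 48 h and outside
    post-onset blackouts.  The CI is the exact (Garwood) Poisson interval
    for the event count divided by exposure.
    """

    n_admissions: int
    patient_days_at_risk: float
    n_onsets: int
    daily_incidence: float
    daily_incidence_ci: tuple
    cumulative_infected_pct: float
    median_first_onset_day: Optional[float]
    median_recurrent_onset_day: Optional[float]
    recurrence_pct: float
    per_day_composition: pd.DataFrame = field(repr=False, default=None)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "n_admissions": self.n_admissions,
            "patient_days_at_risk": self.patient_days_at_risk,
            "n_onsets": self.n_onsets,
            "daily_incidence": self.daily_incidence,
            "daily_incidence_ci": list(self.daily_incidence_ci),
            "ci_method": "exact Poisson (Garwood)",
            "cumulative_infected_pct": self.cumulative_infected_pct,
            "median_first_onset_day": self.median_first_onset_day,
            "median_recurrent_onset_day": self.median_recurrent_onset_day,
            "recurrence_pct": self.recurrence_pct,
            "degenerate": self.degenerate,
        }


def at_risk_days(tl: EventTimeline, blackout_h: float = 48.0, start_h: float = 48.0) -> float:
    """Exact at-risk exposure in days: in ICU, past ``start_h``, outside blackouts."""
    exposure = max(tl.terminal_time - start_h, 0.0)
    for onset in tl.infection_onsets:
        exposure -= max(min(onset + blackout_h, tl.terminal_time) - onset, 0.0)
    return exposure / 24.0


def summarize_incidence(bundle: CohortBundle) -> IncidenceSummary:
    tls = bundle.timelines
    n = len(tls)
    if n == 0:
        return IncidenceSummary(0, 0.0, 0, 0.0, (0.0, 0.0), 0.0, None, None, 0.0,
                                pd.DataFrame(), degenerate=True)
    exposure = sum(at_risk_days(tl) for tl in tls)
    onsets_all = [t for tl in tls for t in tl.infection_onsets]
    k = len(onsets_all)
    rate = k / exposure if exposure > 0 else 0.0
    if exposure > 0:
        lo = stats.chi2.ppf(0.025, 2 * k) / 2.0 / exposure if k > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * k + 2) / 2.0 / exposure
    else:
        lo = hi = 0.0
    firsts = [tl.infection_onsets[0] / 24.0 for tl in tls if tl.infection_onsets]
    recurrents = [t / 24.0 for tl in tls for t in tl.infection_onsets[1:]]
    n_infected = sum(1 for tl in tls if tl.infection_onsets)
    n_recurrent = sum(1 for tl in tls if len(tl.infection_onsets) >= 2)

    max_day = int(math.ceil(max(tl.terminal_time for tl in tls) / 24.0))
    days = np.arange(1, max_day + 1)
    comp = pd.DataFrame({"day": days})
    term_t = np.array([tl.terminal_time for tl in tls])
    term_e = np.array([tl.terminal_event for tl in tls])
    comp["n_in_icu"] = [(term_t > (d - 1) * 24.0).sum() for d in days]
    on_arr = np.array(onsets_all) if onsets_all else np.array([])
    comp["n_onsets"] = [
        int(((on_arr > (d - 1) * 24.0) & (on_arr <= d * 24.0)).sum()) for d in days
    ]
    for ev in ("death", "discharge"):
        tt = term_t[term_e == ev]
        comp[f"n_{ev}"] = [int(((tt > (d - 1) * 24.0) & (tt <= d * 24.0)).sum()) for d in days]

    return IncidenceSummary(
        n_admissions=n,
        patient_days_at_risk=exposure,
        n_onsets=k,
        daily_incidence=rate,
        daily_incidence_ci=(lo, hi),
        cumulative_infected_pct=100.0 * n_infected / n,
        median_first_onset_day=float(np.median(firsts)) if firsts else None,
        median_recurrent_onset_day=float(np.median(recurrents)) if recurrents else None,
        recurrence_pct=100.0 * n_recurrent / n,
        per_day_composition=comp,
        degenerate=(k == 0 and n == 0),
    )


def true_infection_risk(
    bundle: CohortBundle, admission_ids, series_ids, horizon_h: float = 48.0
) -> np.ndarray:
    """Generator-truth infection CIF over the next ``horizon_h`` hours.

    Uses each admission's latent frailty and infection multiplier; the
    at-risk regime is determined by the series index (series >= 1 means a
    previous infection happened, so post-infection terminal factors apply).
    Serves as a perfectly informed reference predictor in evaluations.
    """
    cfg = bundle.config_echo
    lat = bundle.latents.set_index("admission_id")
    z = lat.loc[list(admission_ids), "frailty"].to_numpy()
    r = lat.loc[list(admission_ids), "inf_multiplier"].to_numpy()
    post = np.asarray(series_ids) >= 1
    lam_inf = cfg.lambda_inf / 24.0 * r
    lam_term = (
        cfg.lambda_death / 24.0 * z * np.where(post, cfg.post_infection_death_factor, 1.0)
        + cfg.lambda_disch / 24.0 * z * np.where(post, cfg.post_infection_disch_factor, 1.0)
    )
    lam_tot = lam_inf + lam_term
    with np.errstate(divide="ignore", invalid="ignore"):
        cif = np.where(
            lam_tot > 0,
            lam_inf / lam_tot * (1.0 - np.exp(-lam_tot * horizon_h)),
            0.0,
        )
    return cif
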