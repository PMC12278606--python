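# icuai — dynamic prediction of ICU-acquired infection

`icuai` implements a landmarking pipeline for predicting ICU-acquired
infection (ICU-AI) — infection with onset more than 48 h after ICU
admission — up to 48 h ahead, in the presence of death and ICU discharge
as competing risks. It is aimed at biostatisticians and clinical
data scientists working on dynamic prediction from electronic health
record streams.

## The model

At 8-hourly landmark times t_LM, each patient still in the ICU and at
risk contributes a prediction instance carrying static admission
covariates and the most recent clinical measurements. Cause-specific
Cox models for infection, death and discharge are fitted on the stacked
landmark dataset (a supermodel with linear and quadratic landmark-time
terms s, s², or stratified baselines), with the window time
u = t − t_LM as the time axis. The absolute infection risk within the
horizon w is the cumulative incidence function

    F_inf(w | x) = Σ_{u_j ≤ w} S(u_j− | x) · dΛ_inf(u_j | x),

with S the all-cause survival built from all three fits. A 1-D
convolutional network (five blocks of convolution / max-pool / dropout,
sigmoid output) maps the five-channel window of 1-minute vitals — heart
rate, mean arterial pressure, pulse pressure, respiratory rate, SpO₂ —
ending at t_LM to an infection probability; this score enters the
infection cause as an ancillary predictor ("deep" model), and a
likelihood-ratio test compares deep vs base.

After an infection onset, the following 48 h are excluded (blackout) and
landmarking resumes on a fresh series treated as an independent
observation unit, so recurrent infections are predicted too.

Because individual-level ICU data cannot be shared, the package includes
a synthetic cohort generator (competing exponential hazards with
per-patient frailty, pre-onset covariate drifts, and a vital-sign
deterioration signature) calibrated to published cohort statistics:
3.5% daily incidence, 18.8% of admissions ever infected, first onset at
median day 7, recurrences at median day 14.5, 4.4% of patients with
recurrence. See `docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the full study at desk scale
(300 admissions, shared run directory `results/run_default`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_landmarks.py
python analysis/03_train_cnn.py
python analysis/04_fit_supermodels.py
python analysis/05_evaluate_models.py
python analysis/06_alert_analysis.py
```

Output of a run (seed 20250721):

```
simulated 300 admissions (2062 at-risk patient-days)
daily incidence: 4.02% (95% CI 3.21-4.99)
ever infected: 22.0% of admissions
...
6367 landmark rows from 300 admissions
window outcomes: {'censored': 0.731, 'discharge': 0.178, 'infection': 0.065, 'death': 0.025}
...
strongest infection-cause associations (deep model):
  cnn_score              HR 1260.062 (95% CI 706.697-2246.727)
  fio2                   HR 2.074 (95% CI 1.096-3.926)
  sepsis_at_admission    HR 1.460 (95% CI 1.172-1.818)
LR test deep vs base: stat 521.4, df 1, p = 2.09e-115
...
base: c = 0.662 (fold 95% CI 0.642-0.717), Brier = 0.059, calibration slope = 0.66, intercept = +0.023
deep: c = 0.707 (fold 95% CI 0.670-0.750), Brier = 0.062, calibration slope = 0.42, intercept = +0.034
largest permutation c-index drops: {'cnn_score': 0.1021, 'platelets': 0.0277, 'crp': 0.0215, ...}
...
18.5% of all predictions raise an alert
lead time: median 19 h (IQR 9-97)
```

Reading this: at a 300-admission scale the cohort statistics carry
visible Monte-Carlo error (4.0% vs the calibrated 3.5%/day; the n = 5,000
run below is on target). Out-of-fold discrimination is moderate
(c ≈ 0.66–0.71 — each comparable pair asks whether the row that develops
infection sooner received the higher 48-h risk), the Brier score is
small because infection within any single window is rare, and the
calibration slope < 1 flags overconfident high-risk predictions. The CNN
score dominates the importance views because the synthetic vitals carry
a genuine pre-onset signature; its huge hazard ratio is per unit of a
score bounded in (0, 1). At a 10% risk threshold about a fifth of
predictions raise an alert.

The same pipeline is scriptable via the CLI:

```bash
icuai run --out results/cli_run --seed 7 --horizon 48
icuai run --out results/cli_run24 --seed 7 --horizon 24 --no-cnn
```

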