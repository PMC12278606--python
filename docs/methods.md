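# Methods

`icuai` implements a dynamic-prediction pipeline for ICU-acquired
infection (ICU-AI): a landmarking competing-risk Cox supermodel over
8-hourly prediction moments, optionally augmented with a 1-D convolutional
network score computed from 1-minute vital-sign streams. Because
individual-level ICU data cannot be redistributed, the package ships a
synthetic cohort generator calibrated to published cohort-level incidence
statistics; every stage of the pipeline is exercised end-to-end on
generated data.

## The prediction problem

At each landmark time t_LM (hours from ICU admission) we ask: what is the
probability that a patient still in the ICU and infection-free develops an
ICU-AI within the next w hours (w = 48 by default, 24 as a sensitivity
setting)? Death and ICU discharge are competing events — they remove the
patient from risk — so the quantity of interest is a cumulative incidence
function (CIF), not a naive survival probability.

Conventions, all configurable in `LandmarkGrid`:

* time unit: hours from ICU admission; day d = hours / 24;
* data from the first 24 h are excluded (run-in); the first landmark sits
  at 48 h (ICU-AI is by definition an infection with onset > 48 h);
* landmarks every 8 h, strictly inside the patient's at-risk period;
* after an onset, the 48 h of data that follow are excluded (blackout) and
  landmarking resumes on a fresh series at blackout end. Reset series are
  treated as independent observation units during model development.
  The blackout is half-open: the first reset landmark sits exactly at
  onset + 48 h. Two variants are switchable: re-aligning reset landmarks
  to the admission-wide 8-h grid (`realign_resets`), and an extra
  observation run-in before the first reset landmark (`reset_runin_h`).

## Synthetic cohort generator

Events are sampled from competing exponential cause-specific hazards,
piecewise-constant over regimes (pre-48 h: all zero; at risk; blackout:
infection hazard suppressed; post-infection: terminal hazards modified).
A per-patient log-normal frailty Z (mean 1, `frailty_sigma`) multiplies
the terminal hazards only; a mean-one multiplier r = exp(beta' (x - mu)),
normalised analytically, couples static covariates to the infection
hazard. After any infection the discharge hazard is multiplied by
`post_infection_disch_factor` (< 1: infected patients stay longer) and the
death hazard by `post_infection_death_factor` (> 1). Follow-up is
administratively truncated at `max_followup_days`.

The shipped defaults were calibrated so that a 5,000-admission cohort
reproduces five published cohort statistics: daily ICU-AI incidence 3.5%
of at-risk patient-days, 18.8% of admissions ever infected, first onset at
median day 7, recurrent onsets at median day 14.5, and 4.4% of patients
with more than one episode:

| parameter | value | units |
|---|---|---|
| `lambda_inf` | 0.035 | /day, cause-specific infection hazard |
| `lambda_disch` | 0.20 | /day, baseline discharge hazard |
| `lambda_death` | 0.023 | /day, baseline death hazard |
| `frailty_sigma` | 0.88 | SD of log frailty on terminal hazards |
| `post_infection_disch_factor` | 0.55 | multiplier after first onset |
| `post_infection_death_factor` | 2.0 | multiplier after first onset |
| `max_followup_days` | 23 | administrative truncation |

Two calibration notes. First, within this process family the pair
(18.8% ever infected, median first onset day 7) pins down the pre-infection
terminal hazard and the frailty spread jointly; matching the onset median
exactly would require frailty spreads (sigma > 1.4) that destabilise the
recurrence-timing statistics. The shipped compromise yields a median first
onset near day 6.3 (within the +/- 1 day band) with all other statistics
centred. Second, the administrative cap at 23 days is what keeps recurrent
onsets at median ~14.5 days: without it, low-frailty long-stayers
accumulate late recurrences (median drifts past day 20), which the
reference cohort does not show.

Longitudinal data are synthetic stand-ins with documented structure, not
fits to real waveforms:

* clinical series (8-h grid): stationary AR(1) noise around per-patient
  levels; labs (CRP, WBC, platelets, creatinine) observed daily, bedside
  channels (temperature, FiO2, SOFA) 8-hourly. Before each onset the
  configured drifts ramp in linearly (defaults: CRP +80 mg/L over 48 h,
  temperature +1.2 degC over 24 h, platelets -30% over 72 h) and decay
  over the blackout;
* vital streams (1-min): per-patient baseline + 24-h circadian sinusoid +
  AR(1) noise (phi = 0.97); a pre-onset deterioration signature ramps in
  over `signature_lead_h` (default 24 h; HR +15 bpm, RR +6 /min,
  MAP -10 mmHg, PP -5 mmHg, SpO2 -2%) with +/-30% per-onset amplitude
  jitter, and decays over the blackout. Missing minutes are marked NaN
  (Bernoulli dropout plus occasional multi-minute device gaps), never
  silently interpolated at generation time.

What passing tests therefore show: that the pipeline recovers structure
of exactly this kind — smooth pre-onset drifts, a level-shift vital
signature, proportional covariate effects. Real ICU data add regime
changes from interventions, informative measurement times, and far
messier missingness; performance numbers obtained here do not transfer.

## Landmark dataset

One row per (admission, series, landmark). Dynamic covariates are the
last observation within a 24-h lookback (the lab cadence); older values
are considered stale; missing values fall back to training-fold medians
(`ImputationState`), with per-covariate flags. Landmark time enters as
s = t_LM / 24 centred at the stacked mean, plus s^2 (centring
decorrelates the two terms). The window outcome is the first event in
(t_LM, t_LM + w]; exact ties resolve infection > death > discharge
(infection is the outcome of interest and its reference time is therapy
start). A patient whose event falls exactly on a landmark contributes no
row there.

## Supermodel

Three cause-specific Cox models (infection, death, discharge) are fitted
on the stacked rows with window time u = outcome time as the time axis
and competing causes censored at their event times. The partial
likelihood uses Efron's tie correction (the 8-h grid plus hour-resolution
events produce ties); Newton-Raphson on an internally standardised design
with step-halving, convergence at max |gradient| < 1e-9 (plus a
machine-precision escape for flat likelihoods). Baselines are Breslow
increments d / S0(t), either pooled (default: one baseline, s and s^2 in
the design — the landmark supermodel form that yields smooth risk over
landmarks) or stratified on the nominal landmark level (s, s^2 dropped
within strata, where they are constant). Reset-series landmarks are
off-grid by construction, so stratification and per-landmark reporting
bin t_LM to the nearest admission-grid level.

Rows from one patient are treated as independent in the likelihood, as
the landmarking framework prescribes; optional cluster-by-patient
sandwich standard errors are available (`robust=True`, off in the default
preset).

The absolute 48-h infection risk is the Aalen-Johansen product form over
the merged baseline event times,

    F_inf(w | x) = sum_{u_j <= w} S(u_j- | x) * dLambda_inf(u_j | x),
    S(u | x) = prod_{u_j <= u} (1 - sum_k dLambda_k(u_j | x)),

which makes the per-cause CIFs and overall survival sum to one exactly
(tested to 1e-10). With covariate-free constant hazards the prediction
reproduces the closed form (lambda_inf / lambda_tot)(1 - e^{-lambda_tot w})
to the discretisation error of the baseline grid.

The deep model adds the CNN score to the infection cause only; the
likelihood-ratio test (1 df) compares the two infection-cause partial
likelihoods on identical rows. One subtlety worth recording: a score
built from the true infection *CIF* adds nothing to this test when the
base design already explains the infection *hazard* — the CIF's extra
dependence on frailty enters only through the competing hazards, which
the infection-cause partial likelihood ignores. Power simulations must
put hazard signal in the score that the base design lacks.

## CNN risk score

Input: the five-channel window [t_LM - window, t_LM) of 1-minute vitals
(default 480 min — the inter-landmark spacing; the input length is not
pinned down by the reference description and is configurable). Gap
policy: interior gaps <= 5 min are linearly interpolated, longer gaps
carry the last value forward, leading gaps take the channel's window
median; the original missingness mask is preserved.

Architecture: N blocks of (same-padding convolution, ReLU, max-pool,
inverted dropout) followed by a flattened dense sigmoid output; the
reference preset uses five blocks (kernel 7, filters 16-16-32-32-64, pool
2, dropout 0.2). Training: Adam on class-weighted binary cross-entropy
(weighting rather than resampling, to preserve the ranking), early
stopping on a seeded validation slice. The implementation is plain numpy
(im2col convolutions); all randomness flows from one seed and training is
bit-reproducible. Per-channel standardisation constants come from the
training fold only and are stored with the model, so scoring never uses
statistics of the scored data, and adding a constant to a channel is
absorbed exactly.

Hyperparameters are selected by mean AUC over patient-grouped 5-fold
cross-validation (ties break in grid order), then the winner is refit on
all training data. Inside outer evaluation folds the configuration is
taken as given (`fit_cnn`) — nesting the selection would multiply cost
without changing the comparison.

## Evaluation

Repeated patient-grouped 5-fold cross-validation; per fold, imputation
medians, landmark-time centring, CNN weights/preprocessing and all Cox
fits are learned on training patients only. Metrics are reported pooled
over out-of-fold predictions and as fold means with normal-approximation
95% CIs (mean +/- 1.96 SD / sqrt(folds)).

* c-index: Harrell's, with competing events administratively censored at
  the horizon — a patient discharged or dying mid-window counts as
  infection-free through the whole window (the alternative, censoring at
  the event time, is a switch). Tied predictions count 1/2; implementation
  is tested for exact equality against exhaustive pair enumeration.
* Brier score: mean squared difference between the predicted CIF and the
  infection-within-window indicator; competing events and horizon-censored
  rows count as non-events (an exclude-competing switch covers the other
  reading).
* Calibration: deciles of predicted risk; observed risk per bin is the
  nonparametric Aalen-Johansen infection CIF at the horizon (competing
  events at their actual times); slope and intercept by size-weighted
  least squares of observed on mean predicted, with a complementary
  log-log variant behind a flag. The linear probability-scale summary is
  the default because the predictions of interest live on [0, 0.5).
* Importance: per-landmark Wald chi-square rankings from refits at each
  landmark level, and a permutation delta-c view — permute one covariate
  across out-of-fold rows, re-predict through the fold models, record the
  mean c-index drop over 20 seeded permutations. Permutation was chosen
  over leave-one-covariate-out refitting: it asks the same "relative
  contribution" question at a small fraction of the cost.
* Alerts: fraction of predictions above a 10% risk threshold and, for
  each first infection, the lead time from the first alerting landmark
  (initial series only) to onset, with median and IQR.

## Problem sizes and numerical choices

Shipped analysis scripts run at 300 admissions with a 240-min CNN window
and a two-block network; the test suite uses 120-2,000 admissions
depending on what a check needs (20,000 for hazard-fidelity Monte Carlo).
These sizes were chosen so each analysis completes in minutes on a single
CPU while leaving Monte-Carlo error well inside the asserted tolerances;
they are not fits to any external constraint. Degenerate inputs are
handled explicitly: empty cohorts produce flagged zero summaries, folds
without infection events are refused with instructions to enlarge the
cohort, constant predictions make the calibration slope undefined (with a
recorded reason), and landmarks coinciding with segment ends are dropped.

## Known limitations

* The generator models one admission per patient; readmissions share no
  frailty. Covariates are sampled independently (no Table-1 correlation
  structure), and there is no microbiology, antibiotic exposure, or
  adjudication noise.
* The real predictor set (38 covariates) is approximated by a
  configurable representative set; the exact list lives in an unavailable
  supplement.
* Cause-specific hazards are time-constant within regimes; true ICU
  hazards drift with care intensity.
* The CNN input length, gap handling and hyperparameter grid of the
  original model are not published in the main text; defaults are our
  choices, all configurable.
* Cohort-dependent headline numbers (c-index 0.69, Brier 0.05, HR 8.62,
  calibration slope 0.58) are properties of the private cohort and are
  not reproduction targets; the suite checks property-based analogues
  (oracle equalities, self-consistency, directional comparisons) instead.
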