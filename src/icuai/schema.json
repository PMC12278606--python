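{
  "admissions.csv": {
    "description": "One row per ICU admission with static covariates.",
    "columns": {
      "patient_id": "string, unique patient identifier",
      "admission_id": "string, unique admission identifier",
      "age": "years",
      "male": "0/1",
      "surgical_admission": "0/1",
      "immunodeficiency": "0/1",
      "diabetes": "0/1",
      "malignancy": "0/1",
      "cardiovascular_insufficiency": "0/1",
      "renal_insufficiency": "0/1",
      "respiratory_insufficiency": "0/1",
      "prior_icu_admission": "0/1",
      "sepsis_at_admission": "0/1",
      "apache_iv": "APACHE-IV score points (>= 0)",
      "sofa_baseline": "SOFA score points (0-24)"
    }
  },
  "events.csv": {
    "description": "One row per admission: infection onsets and the terminal event.",
    "columns": {
      "admission_id": "string",
      "onset_times": "semicolon-delimited onset times, hours from admission",
      "terminal_event": "death | discharge | administrative",
      "terminal_time_h": "hours from admission (> 48 by inclusion)"
    }
  },
  "clinical.csv": {
    "description": "Long-format 8-hourly clinical series; only observed entries are written.",
    "columns": {
      "admission_id": "string",
      "time_h": "hours from admission, aligned to the 8-h grid",
      "channel": "crp (mg/L) | temperature (degC) | wbc (1e9/L) | platelets (1e9/L) | creatinine (umol/L) | fio2 (fraction) | sofa (points)",
      "value": "numeric"
    }
  },
  "vitals.csv": {
    "description": "Long-format 1-minute vital signs; only observed minutes are written.",
    "columns": {
      "admission_id": "string",
      "minute": "integer minute from admission",
      "channel": "heart_rate (bpm) | map (mmHg) | pulse_pressure (mmHg) | respiratory_rate (/min) | spo2 (%)",
      "value": "numeric"
    }
  },
  "stacked.csv": {
    "description": "Stacked landmark dataset: one row per (admission, series, landmark).",
    "columns": {
      "admission_id": "string",
      "patient_id": "string",
      "series_id": "integer, 0 = initial series, k = after k-th onset",
      "t_lm": "landmark time, hours from admission",
      "outcome_type": "infection | death | discharge | censored (first event in (t_lm, t_lm + horizon])",
      "outcome_time": "hours from the landmark, in (0, horizon]",
      "s": "landmark time in days, centred at the stacked mean",
      "s2": "s squared",
      "<static covariates>": "copied from admissions.csv",
      "<dynamic covariates>": "last observation in the lookback window; NaN when none",
      "imputed_<channel>": "True where the dynamic value was missing before imputation",
      "cnn_score": "optional CNN risk score joined on (admission_id, series_id, t_lm)"
    }
  },
  "scores.csv": {
    "description": "CNN risk scores keyed by landmark row.",
    "columns": {
      "admission_id": "string",
      "series_id": "integer",
      "t_lm": "hours",
      "cnn_score": "probability in (0, 1)"
    }
  },
  "predictions.csv": {
    "description": "Predicted infection CIF within the horizon per landmark row.",
    "columns": {
      "admission_id": "string",
      "series_id": "integer",
      "t_lm": "hours",
      "cif_infection": "probability in [0, 1]"
    }
  },
  "coefficients.csv": {
    "description": "Cause-specific Cox coefficients with hazard ratios and 95% CIs.",
    "columns": {
      "model": "base | deep",
      "cause": "infection | death | discharge",
      "covariate": "string",
      "coef": "log hazard ratio",
      "se": "standard error",
      "hr": "hazard ratio",
      "hr_lo": "lower 95% CI",
      "hr_hi": "upper 95% CI"
    }
  },
  "report.json": {
    "description": "Machine-readable metric report: per-model global and per-landmark c-index, Brier, calibration, LR test, alert summary."
  }
}
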