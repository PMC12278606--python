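#!/usr/bin/env python
"""Fit the base and deep landmark competing-risk Cox supermodels.

The base model uses static + last-observed clinical covariates plus linear
and quadratic landmark-time terms; the deep model adds the CNN risk score
to the infection cause.  Prints the strongest infection-cause hazard
ratios and the likelihood-ratio test of deep vs base; writes
coefficients.csv, fit_base.json, fit_deep.json, lr_test.json and
predictions.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, run_config

from icuai.pipeline import stage_build, stage_fit, stage_simulate


def main() -> None:
    cfg = run_config()
    bundle = stage_simulate(cfg, RUN_DIR)
    stacked = stage_build(cfg, bundle, RUN_DIR)
    scores_path = RUN_DIR / "scores.csv"
    scores = pd.read_csv(scores_path) if scores_path.exists() else None
    if scores is None:
        print("scores.csv not found - fitting the base model only "
              "(run 03_train_cnn.py first for the deep model)")
        cfg.use_cnn = False
    fits = stage_fit(cfg, stacked, RUN_DIR, scores)
    model = "deep" if "deep" in fits else "base"
    hr = fits[model].fits["infection"].hazard_ratios()
    hr = hr.reindex(hr["coef"].abs().sort_values(ascending=False).index)
    print(f"strongest infection-cause associations ({model} model):")
    for _, r in hr.head(6).iterrows():
        print(f"  {r['covariate']:<22} HR {r['hr']:.3f} "
              f"(95% CI {r['hr_lo']:.3f}-{r['hr_hi']:.3f})")
    if (RUN_DIR / "lr_test.json").exists():
        lr = json.loads((RUN_DIR / "lr_test.json").read_text())
        print(f"LR test deep vs base: stat {lr['stat']:.1f}, df {lr['df']}, "
              f"p = {lr['p']:.2e}")


if __name__ == "__main__":
    main()
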