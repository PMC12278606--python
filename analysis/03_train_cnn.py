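#!/usr/bin/env python
"""Train the vital-sign CNN and score every landmark row.

Hyperparameters are selected by mean AUC over patient-grouped 5-fold
cross-validation on the landmark labels (infection within the horizon),
then the winning configuration is refit on all rows.  Writes scores.csv,
cnn_model.npz and cnn_selection.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import RUN_DIR, run_config

from icuai.pipeline import stage_build, stage_simulate, stage_train_cnn


def main() -> None:
    cfg = run_config()
    bundle = stage_simulate(cfg, RUN_DIR)
    stacked = stage_build(cfg, bundle, RUN_DIR)
    model, scores = stage_train_cnn(cfg, bundle, stacked, RUN_DIR)
    sel = json.loads((RUN_DIR / "cnn_selection.json").read_text())
    for i, rep in enumerate(sel["report"]):
        flag = " <= selected" if i == sel["selected"] else ""
        print(f"config {i}: mean CV AUC {rep['mean_auc']:.3f}{flag}")
    print(f"scored {len(scores)} landmark rows; "
          f"score range [{scores['cnn_score'].min():.3f}, "
          f"{scores['cnn_score'].max():.3f}]")


if __name__ == "__main__":
    main()
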