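"""Shared desk-scale run configuration for the numbered analysis scripts.

All scripts share one run directory (results/run_default) and one master
seed, so each stage can be re-run independently and reproduces the same
artifacts.  Sizes are chosen so the full sequence completes in minutes on
one CPU; scale ``N_ADMISSIONS`` up for tighter Monte-Carlo error.
"""

from pathlib import Path

from icuai.config import CnnConfig, GeneratorConfig
from icuai.pipeline import RunConfig

REPO = Path(__file__).resolve().parents[1]
RUN_DIR = REPO / "results" / "run_default"
SEED = 20250721
N_ADMISSIONS = 300


def run_config() -> RunConfig:
    return RunConfig(
        generator=GeneratorConfig(n_admissions=N_ADMISSIONS, seed=SEED),
        cnn=CnnConfig(filters=(8, 16), kernel_size=7, pool_size=4, dropout=0.1,
                      learning_rate=3e-3, batch_size=64, epochs=8,
                      window_minutes=240),
        use_cnn=True,
        seed=SEED,
    )
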