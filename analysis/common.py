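"""Shared configuration for the numbered analysis drivers.

All drivers are deterministic (fixed seeds) and write their tables under
``results/``.  Cohort sizes follow the study's groups (16 / 10 / 8 / 26);
the multi-FF trial schedules are run at 40% of the full session length,
which preserves the 1:2:1 training ratio and clamp fractions while keeping
each driver's runtime to seconds.
"""

from pathlib import Path

from reachplan.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

SEED = 2026

CONFIGS = {
    "expt1": RunConfig(experiment="expt1", seed=SEED, schedule_scale=0.4,
                       ground_truth="po"),
    "expt1_gen": RunConfig(experiment="expt1_gen", seed=SEED + 1,
                           schedule_scale=0.4),
    "expt2a": RunConfig(experiment="expt2a", seed=SEED + 2, ground_truth="po"),
    "expt2b": RunConfig(experiment="expt2b", seed=SEED + 3, ground_truth="po"),
}


def summaries_path(experiment: str) -> Path:
    cfg = CONFIGS[experiment]
    return DATA / f"{experiment}_seed{cfg.seed}_summaries.csv"


def trials_path(experiment: str) -> Path:
    cfg = CONFIGS[experiment]
    return DATA / f"{experiment}_seed{cfg.seed}_trials.csv"
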