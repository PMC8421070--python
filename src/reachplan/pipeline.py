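"""Run configuration, file I/O and end-to-end pipeline entry points.

Artifacts are inspectable text: trial and summary tables as CSV, analysis
reports as JSON (with the configuration and seed embedded for provenance),
run configurations read from YAML or JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ff_pipeline import (analyze_ff_cohort, final_adaptation_levels,
                          fit_generalization_from_cohort)
from .individuation import (VARIABLES, fit_one_param, fit_three_param,
                            partial_r2)
from .learner import LearnerParams, expt1_schedule, simulate_ff_participant
from .obstacle_cohort import GroundTruth, ObstacleCohortSpec, simulate_obstacle_cohort
from .obstacle_models import (Variant, cross_validate, direction_prediction_index,
                              evaluate_model, fit_alpha, fit_beta,
                              frame_to_summaries, population_prediction,
                              summaries_to_frame, weight_sweep)
from .trial import frame_to_trials, trials_to_frame

log = logging.getLogger("reachplan")

EXPERIMENTS = ("expt1", "expt1_gen", "expt2a", "expt2b")
#: Cohort sizes of the study's four groups.
DEFAULT_N = {"expt1": 16, "expt1_gen": 10, "expt2a": 8, "expt2b": 26}


@dataclass
class RunConfig:
    """Serializable configuration of a simulation/analysis run."""

    experiment: str = "expt2b"
    seed: int = 0
    n: int | None = None  # default: the experiment's group size
    ground_truth: str = "po"
    schedule_scale: float = 0.25  # multi-FF schedule size multiplier
    noise_scale: float = 1.0
    interval_convention: str = "movement_onset"  # PI interval start
    percentile_type: str = "linear"  # movement-time threshold percentile
    out_dir: str = "results"
    # obstacle-cohort distribution overrides (None = module defaults)
    mu1A_loc: float | None = None
    mu1A_scale: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.n is None:
            self.n = DEFAULT_N[self.experiment]
        if self.n < 1:
            raise ValueError("cohort size must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"config": config.as_dict(), "config_hash": config.digest(),
            "version": __version__}


def write_report(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _obstacle_spec(config: RunConfig) -> ObstacleCohortSpec:
    kwargs: dict = {}
    if config.experiment == "expt2a":
        # in the large-obstacle geometry the obstructed-target deflection is
        # rightward, positive in the shared frame, and larger on average
        kwargs.update(variant=Variant.EXPT2A, mu1A_loc=28.0, mu1A_scale=6.0)
    else:
        kwargs.update(variant=Variant.EXPT2B, mu1A_loc=-20.0, mu1A_scale=6.0)
    if config.mu1A_loc is not None:
        kwargs["mu1A_loc"] = config.mu1A_loc
    if config.mu1A_scale is not None:
        kwargs["mu1A_scale"] = config.mu1A_scale
    return ObstacleCohortSpec(n=config.n, ground_truth=GroundTruth(config.ground_truth),
                              noise_scale=config.noise_scale, seed=config.seed,
                              **kwargs)


def simulate_ff_cohort(config: RunConfig, full_series: bool = False) -> list[list]:
    """Simulate a multi-FF cohort per config; returns trials per participant."""
    gen_probes = config.experiment == "expt1_gen"
    cohort = []
    for i in range(config.n):
        rng = np.random.default_rng([config.seed, i])
        sched = expt1_schedule(rng, scale=config.schedule_scale, gen_probes=gen_probes)
        res = simulate_ff_participant(
            sched, LearnerParams(), seed=rng, k_center=1 if i % 2 == 0 else -1,
            ground_truth=config.ground_truth, participant=i, full_series=full_series)
        cohort.append(res.trials)
    return cohort


def cmd_simulate(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Generate the configured cohort and write its tables."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config.experiment}_seed{config.seed}"
    paths: dict[str, Path] = {}
    log.info("simulate %s (n=%d, seed=%d, hash=%s)", config.experiment,
             config.n, config.seed, config.digest())
    if config.experiment in ("expt1", "expt1_gen"):
        cohort = simulate_ff_cohort(config)
        frames = [trials_to_frame(trials) for trials in cohort]
        df = pd.concat(frames, ignore_index=True)
        paths["trials"] = out / f"{tag}_trials.csv"
        df.to_csv(paths["trials"], index=False)
    else:
        cohort = simulate_obstacle_cohort(_obstacle_spec(config))
        paths["summaries"] = out / f"{tag}_summaries.csv"
        summaries_to_frame(cohort.summaries).to_csv(paths["summaries"], index=False)
        paths["directions"] = out / f"{tag}_directions.csv"
        cohort.trials.to_csv(paths["directions"], index=False)
    paths["config"] = write_report(_provenance(config), out / f"{tag}_config.json")
    return paths


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def _load_trials_by_participant(path: str | Path) -> list[list]:
    df = pd.read_csv(path)
    trials = frame_to_trials(df)
    by_pid: dict[int, list] = {}
    for tr in trials:
        by_pid.setdefault(tr.participant, []).append(tr)
    return [sorted(v, key=lambda t: t.trial) for _, v in sorted(by_pid.items())]


def cmd_analyze_ff(config: RunConfig, trials_path: str | Path | None = None,
                   gen_trials_path: str | Path | None = None,
                   cohort=None, gen_cohort=None) -> dict:
    """Multi-FF analysis report: adaptation levels, T_RESP, raw/refined PIs.

    Inputs may be CSV paths or in-memory cohorts (trials per participant);
    the generalization cohort is optional and enables refined predictions.
    """
    if cohort is None:
        if trials_path is None:
            raise ValueError("need a trial table or an in-memory cohort")
        cohort = _load_trials_by_participant(trials_path)
    gen = None
    gen_info = None
    if gen_cohort is None and gen_trials_path is not None:
        gen_cohort = _load_trials_by_participant(gen_trials_path)
    if gen_cohort is not None:
        gen, gen_r2 = fit_generalization_from_cohort(gen_cohort)
        gen_info = {"A1": gen.A1, "A2": gen.A2, "A0": gen.A0,
                    "sigma": gen.sigma, "r2": gen_r2}
    from .kinematics import filter_trials

    report = analyze_ff_cohort(cohort, gen=gen)
    report["generalization"] = gen_info
    _, filt = filter_trials([tr for trials in cohort for tr in trials],
                            check_peak_speed=True)
    report["filter_report"] = filt.as_dict()
    report["adaptation_final"] = {
        str(k): v for k, v in final_adaptation_levels(cohort[0]).items()}
    report.update(_provenance(config))
    return report


def cmd_analyze_obstacle(config: RunConfig,
                         summaries_path: str | Path | None = None,
                         cohort=None,
                         cross_cohort=None) -> dict:
    """Obstacle-model report: baseline/refined predictions, fitted weights,
    per-participant MSEs, the direction prediction index and, given a second
    cohort, between-experiment cross-validation."""
    if cohort is None:
        cohort = frame_to_summaries(pd.read_csv(summaries_path))
    mu_ma = population_prediction(cohort, "ma", 0.5)
    mu_po = population_prediction(cohort, "po", 0.5)
    pi_mean, _ = direction_prediction_index(cohort, mu_po, mu_ma)
    ma_base = evaluate_model(cohort, "ma", 0.5, label="MA_baseline")
    po_base = evaluate_model(cohort, "po", 0.5, label="PO_baseline")
    alpha = fit_alpha(cohort)
    beta = fit_beta(cohort)
    report = {
        "n": len(cohort),
        "variant": cohort[0].variant.value,
        "observed_mu2_mean": float(np.mean([s.mu2 for s in cohort])),
        "observed_mu2_free_mean": float(np.nanmean([s.mu2_free for s in cohort])),
        "baseline": {
            "ma": {"prediction": ma_base.prediction, "mse": ma_base.mse, "sem": ma_base.sem},
            "po": {"prediction": po_base.prediction, "mse": po_base.mse, "sem": po_base.sem},
            "prediction_index": pi_mean,
        },
        "fitted": {"alpha": alpha, "beta": beta},
        "weight_sweep": {
            m: weight_sweep(cohort, m).to_dict(orient="records") for m in ("ma", "po")
        },
    }
    if cross_cohort is not None:
        report["cross_validation"] = {
            m: cross_validate(cross_cohort, cohort, m) for m in ("ma", "po")
        }
    report.update(_provenance(config))
    return report


def cmd_individuation(config: RunConfig,
                      summaries_path: str | Path | None = None,
                      cohort=None) -> dict:
    """Individuation report: one- and three-parameter fits, partial R^2s."""
    if cohort is None:
        cohort = frame_to_summaries(pd.read_csv(summaries_path))
    one = fit_one_param(cohort)
    three = fit_three_param(cohort)
    partials = {v: partial_r2(cohort, v, full=three) for v in VARIABLES}
    report = {
        "n": one.n,
        "one_param": {"k": one.indices["k"], "K0": one.K0, "r2": one.r2,
                      "F": one.F, "p": one.p},
        "three_param": {"km": three.indices["km"], "k2": three.indices["k2"],
                        "k1": three.indices["k1"], "K0": three.K0, "r2": three.r2},
        "partial_r2": {v: {"partial_r2": d["partial_r2"], "F": d["F"], "p": d["p"]}
                       for v, d in partials.items()},
    }
    report.update(_provenance(config))
    return report


# ---------------------------------------------------------------------------
# external data import
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ("participant", "variant", "mu1A", "mu1B", "sigma1A", "sigma2", "mu2")


def import_external(directory: str | Path, out_dir: str | Path | None = None
                    ) -> dict[str, pd.DataFrame]:
    """Normalize user-supplied summary tables into per-variant summary CSVs.

    Reads every ``*.csv`` in ``directory`` (each must carry the documented
    summary columns), validates the schema, splits mixed-variant tables, and
    optionally writes one normalized CSV per variant.  Never downloads
    anything.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no CSV tables found in {directory}")
    frames = []
    for f in files:
        df = pd.read_csv(f)
        missing = set(SUMMARY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{f.name}: missing columns {sorted(missing)}")
        frames.append(df[list(SUMMARY_COLUMNS)
                         + [c for c in ("mu2_free", "n_trials") if c in df.columns]])
    merged = pd.concat(frames, ignore_index=True)
    out: dict[str, pd.DataFrame] = {}
    for variant, g in merged.groupby("variant"):
        Variant(variant)  # validates
        out[str(variant)] = g.reset_index(drop=True)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            g.to_csv(Path(out_dir) / f"summaries_{variant}.csv", index=False)
    return out
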