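import numpy as np
import pytest

from reachplan.forcefield import CURL_GAIN_B, ClampMode, FFCondition
from reachplan.learner import minimum_jerk
from reachplan.trial import Epoch, ObstacleSide, Trial, TrialType, direction_unit


def make_reach_trial(direction_deg: float = 0.0, duration: float = 0.55,
                     ff: FFCondition | None = None, participant: int = 0,
                     trial: int = 0, epoch: Epoch = Epoch.TEST,
                     adaptation: float | None = None,
                     lateral_force: np.ndarray | None = None,
                     k_center: int = 1,
                     trial_type: TrialType = TrialType.ONE_TARGET) -> Trial:
    """Straight minimum-jerk reach with an optional adaptation-scaled
    clamp-trial lateral force (force = adaptation x ideal center-target
    compensation)."""
    t, s, v = minimum_jerk(duration)
    u = direction_unit(direction_deg)
    ff = ff or FFCondition(B=CURL_GAIN_B, k=k_center, clamp=ClampMode.FULL)
    if lateral_force is None:
        a = 0.0 if adaptation is None else adaptation
        lateral_force = a * (-k_center) * CURL_GAIN_B * v
    return Trial(
        participant=participant, trial=trial, epoch=epoch, trial_type=trial_type,
        target_set=(30.0, -30.0) if trial_type is TrialType.TWO_TARGET else (direction_deg,),
        cued_final_target=direction_deg if trial_type is TrialType.ONE_TARGET else 30.0,
        ff=ff, obstacle_side=ObstacleSide.NONE, sample_rate=200.0,
        t=t, pos=np.outer(s, u), vel=np.outer(v, u),
        lateral_force=np.asarray(lateral_force, dtype=float),
        movement_time=duration, planned_direction=direction_deg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ff_cohorts():
    """Session-shared small multi-FF cohorts (PO and MA ground truth) plus a
    generalization-probe cohort; reused by pipeline-level tests."""
    from reachplan.pipeline import RunConfig, simulate_ff_cohort

    po = simulate_ff_cohort(RunConfig(experiment="expt1", seed=3, n=6,
                                      schedule_scale=0.4, ground_truth="po"))
    ma = simulate_ff_cohort(RunConfig(experiment="expt1", seed=5, n=6,
                                      schedule_scale=0.4, ground_truth="ma"))
    gen = simulate_ff_cohort(RunConfig(experiment="expt1_gen", seed=7, n=4,
                                       schedule_scale=0.4))
    return {"po": po, "ma": ma, "gen": gen}


@pytest.fixture(scope="session")
def obstacle_cohorts():
    """Session-shared obstacle cohorts for both variants and ground truths."""
    from reachplan.pipeline import RunConfig, _obstacle_spec
    from reachplan.obstacle_cohort import simulate_obstacle_cohort

    out = {}
    for variant in ("expt2a", "expt2b"):
        for gt in ("po", "ma"):
            cfg = RunConfig(experiment=variant, seed=11 if gt == "po" else 12,
                            ground_truth=gt)
            out[(variant, gt)] = simulate_obstacle_cohort(_obstacle_spec(cfg))
    return out
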