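"""Trial-by-trial adaptation learner and the multi-FF experiment generator.

The learner is a linear state-space model over local motor primitives:
Gaussian direction-tuned basis functions whose weights hold the adapted
lateral-force output, expressed in *center-FF units* (+1 = full compensation
of the force field trained at the center target; the lateral targets are
trained with the opposite field, so their ideal is -1).

Update rule (retention first, then error-driven learning normalized by the
basis energy at the trial direction)::

    w <- A * w
    e  = d(theta) - w . b(theta)
    w <- w + r * e * b(theta) / ||b(theta)||^2

so that training a single direction follows the scalar recursion
``a <- A*(1-r)*a + r*d`` with fixed point ``a* = r*d / (1 - A*(1-r))``.
On error-clamp trials the error is clamped to ~0 and the weights are left
unchanged, but the learner's output is measured.

Trial kinematics use a minimum-jerk (bell-shaped) speed profile; clamp
trials are modeled as direct measurement of the planned lateral force plus
noise rather than integrating the channel's spring-damper dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefield import CURL_GAIN_B, ClampMode, FFCondition
from .trial import Epoch, ObstacleSide, Trial, TrialType, direction_unit

REACH_DISTANCE = 0.2  # m
TARGET_CUE_DISPLACEMENT = 0.03  # m, T_ON: one potential target is extinguished here
DEFAULT_SAMPLE_RATE = 200.0  # Hz


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def minimum_jerk(duration: float, sample_rate: float = DEFAULT_SAMPLE_RATE,
                 distance: float = REACH_DISTANCE) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk displacement and speed profiles.

    Returns ``(t, s, v)`` with ``s(0)=0``, ``s(T)=distance`` and a bell-shaped
    speed peaking at ``1.875 * distance / duration``.
    """
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    tau = np.clip(t / duration, 0.0, 1.0)
    s = distance * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    v = distance / duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return t, s, v


# ---------------------------------------------------------------------------
# learner
# ---------------------------------------------------------------------------

@dataclass
class AdaptationState:
    """Weights of the Gaussian motor-primitive basis (center-FF units)."""

    centers: np.ndarray
    width: float
    weights: np.ndarray

    @classmethod
    def zeros(cls, spacing: float = 7.5, span: float = 45.0, width: float = 15.0) -> "AdaptationState":
        centers = np.arange(-span, span + spacing / 2, spacing)
        return cls(centers=centers, width=width, weights=np.zeros(len(centers)))

    def basis(self, theta: float) -> np.ndarray:
        """Basis activation at direction ``theta`` (deg); values in [0, 1]."""
        return np.exp(-((theta - self.centers) ** 2) / (2.0 * self.width**2))

    def predict(self, theta: float) -> float:
        """Adapted output at direction ``theta`` in center-FF units."""
        return float(self.weights @ self.basis(theta))

    def copy(self) -> "AdaptationState":
        return replace(self, weights=self.weights.copy())


@dataclass(frozen=True)
class LearnerParams:
    """State-space learner parameters.

    retention:
        Trial-to-trial retention factor ``A`` in (0, 1].
    rate:
        Error-driven learning rate ``r`` > 0.
    primitive_width / primitive_spacing / primitive_span:
        Geometry of the Gaussian basis (deg).
    direction_noise:
        SD of planned-direction noise around the intended target (deg).
    force_noise:
        SD of measurement noise added to clamp-trial lateral force (N).
    """

    retention: float = 0.995
    rate: float = 0.15
    primitive_width: float = 7.5
    primitive_spacing: float = 7.5
    primitive_span: float = 45.0
    direction_noise: float = 6.0
    force_noise: float = 0.4
    feedback_gain: float = 0.5
    feedback_latency: float = 0.150  # s after T_ON

    def __post_init__(self) -> None:
        if not (0.0 < self.retention <= 1.0):
            raise ValueError("retention must be in (0, 1]")
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ValueError("learning rate must be finite and non-negative")
        if not (np.isfinite(self.direction_noise) and np.isfinite(self.force_noise)):
            raise ValueError("noise scales must be finite")


def learner_update(state: AdaptationState, theta: float, ideal: float,
                   params: LearnerParams) -> float:
    """Apply one decay + error-driven update in place; returns the error."""
    state.weights *= params.retention
    b = state.basis(theta)
    err = ideal - float(state.weights @ b)
    state.weights += params.rate * err * b / float(b @ b)
    return err


def single_target_fixed_point(params: LearnerParams, ideal: float = 1.0) -> float:
    """Closed-form asymptote of training one direction with target ``ideal``."""
    A, r = params.retention, params.rate
    return r * ideal / (1.0 - A * (1.0 - r))


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduledTrial:
    """One entry of a multi-FF experiment schedule."""

    epoch: Epoch
    trial_type: TrialType
    target: float  # intended direction (deg); 0 for 2-target trials
    ff_on: bool  # curl field active (never on clamp trials)
    clamp: ClampMode = ClampMode.NONE


def _mixed_block(rng: np.random.Generator, epoch: Epoch, targets: list[float],
                 n: int, clamp_frac: float, clamp: ClampMode, ff_on: bool,
                 trial_type: TrialType = TrialType.ONE_TARGET) -> list[ScheduledTrial]:
    """Block with interspersed clamp trials, avoiding consecutive clamps."""
    n_clamp = int(round(n * clamp_frac))
    flags = np.zeros(n, dtype=bool)
    # random clamp placement without adjacency
    slots = list(range(n))
    rng.shuffle(slots)
    placed = 0
    taken = np.zeros(n + 2, dtype=bool)
    for s in slots:
        if placed == n_clamp:
            break
        if not (taken[s] or taken[s + 1] or taken[s + 2]):
            flags[s] = True
            taken[s + 1] = True
            placed += 1
    if trial_type is TrialType.ONE_TARGET:
        tgts = [targets[i % len(targets)] for i in range(n)]
        rng.shuffle(tgts)  # type: ignore[arg-type]
        # guarantee every target direction is probed by at least one clamp
        for tgt in targets:
            idx = [i for i in range(n) if tgts[i] == tgt]
            if idx and not any(flags[i] for i in idx):
                flags[idx[-1]] = True
    else:
        tgts = [0.0] * n
    out = []
    for i in range(n):
        if flags[i]:
            out.append(ScheduledTrial(epoch, trial_type, tgts[i], ff_on=False, clamp=clamp))
        else:
            out.append(ScheduledTrial(epoch, trial_type, tgts[i], ff_on=ff_on))
    return out


def expt1_schedule(rng: np.random.Generator, scale: float = 1.0,
                   gen_probes: bool = False) -> list[ScheduledTrial]:
    """Baseline / training / test schedule of the multi-FF experiment.

    ``scale`` shrinks every block proportionally (minimum sizes keep each
    stage represented) so that reduced-size simulations preserve the 1:2:1
    left/center/right training ratio and the clamp fractions.  With
    ``gen_probes=True`` the 2-target probes of the test epoch are replaced by
    1-target error clamps at the nine probe directions (-30..30 deg every
    7.5), emulating the generalization variant of the experiment.
    """
    def sz(n: int, lo: int = 8) -> int:
        return max(lo, int(round(n * scale)))

    lateral = [30.0, -30.0]
    trained = [30.0, 0.0, -30.0]
    sched: list[ScheduledTrial] = []
    # baseline: null 2-target trials with partial clamps, then 1-target with clamps
    if not gen_probes:
        sched += _mixed_block(rng, Epoch.BASELINE, [0.0], sz(150), 0.20,
                              ClampMode.PARTIAL, ff_on=False, trial_type=TrialType.TWO_TARGET)
        sched += _mixed_block(rng, Epoch.BASELINE, trained, sz(85), 0.20,
                              ClampMode.FULL, ff_on=False)
    else:
        probes = list(np.arange(-30.0, 30.1, 7.5))
        sched += _mixed_block(rng, Epoch.BASELINE, probes, sz(90), 0.20,
                              ClampMode.FULL, ff_on=False)
    # training: 1:2:1 left/center/right, 80% FF / 20% error clamp
    n_train = sz(500, lo=60)
    weights_121 = [0.25, 0.5, 0.25]
    train_targets = [trained[int(rng.choice(3, p=weights_121))] for _ in range(n_train)]
    clamp_flags = _clamp_flags(rng, n_train, 0.20)
    for tgt, is_ec in zip(train_targets, clamp_flags):
        if is_ec:
            sched.append(ScheduledTrial(Epoch.TRAINING, TrialType.ONE_TARGET, tgt,
                                        ff_on=False, clamp=ClampMode.FULL))
        else:
            sched.append(ScheduledTrial(Epoch.TRAINING, TrialType.ONE_TARGET, tgt, ff_on=True))
    # test: 1-target FF (1:2:1) + 1-target EC + probe trials
    n_test = sz(400, lo=60)
    n_probe = max(6, int(round(n_test * 0.125)))
    n_ec = max(6, int(round(n_test * 0.125)))
    n_ff = n_test - n_probe - n_ec
    entries: list[ScheduledTrial] = []
    for _ in range(n_ff):
        tgt = trained[int(rng.choice(3, p=weights_121))]
        entries.append(ScheduledTrial(Epoch.TEST, TrialType.ONE_TARGET, tgt, ff_on=True))
    for i in range(n_ec):
        entries.append(ScheduledTrial(Epoch.TEST, TrialType.ONE_TARGET,
                                      trained[i % 3], ff_on=False, clamp=ClampMode.FULL))
    if gen_probes:
        probes = list(np.arange(-30.0, 30.1, 7.5))
        for i in range(n_probe):
            entries.append(ScheduledTrial(Epoch.TEST, TrialType.ONE_TARGET,
                                          probes[i % len(probes)], ff_on=False,
                                          clamp=ClampMode.FULL))
    else:
        for _ in range(n_probe):
            entries.append(ScheduledTrial(Epoch.TEST, TrialType.TWO_TARGET, 0.0,
                                          ff_on=False, clamp=ClampMode.PARTIAL))
    rng.shuffle(entries)  # type: ignore[arg-type]
    sched += entries
    return sched


def _clamp_flags(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    flags = np.zeros(n, dtype=bool)
    idx = rng.permutation(n)
    placed, want = 0, int(round(n * frac))
    for s in idx:
        if placed == want:
            break
        left = flags[s - 1] if s > 0 else False
        right = flags[s + 1] if s < n - 1 else False
        if not (left or right):
            flags[s] = True
            placed += 1
    return flags


# ---------------------------------------------------------------------------
# participant simulation
# ---------------------------------------------------------------------------

@dataclass
class FFParticipantResult:
    trials: list[Trial]
    history: list[AdaptationState]
    k_center: int  # sign of the field trained at the center target


def simulate_ff_participant(schedule: list[ScheduledTrial],
                            params: LearnerParams | None = None,
                            seed: int | np.random.Generator = 0,
                            k_center: int = 1,
                            ground_truth: str = "po",
                            participant: int = 0,
                            full_series: bool = True) -> FFParticipantResult:
    """Simulate one participant through a multi-FF schedule.

    ``ground_truth`` selects how the feedforward force on 2-target partial
    clamp trials is planned: ``"po"`` expresses the adaptation appropriate
    for the intermediate (center-directed) plan; ``"ma"`` averages the
    adapted outputs for the two lateral potential targets.

    With ``full_series=False``, non-clamp trials carry a single-sample
    placeholder series (their kinematic detail is not consumed by the force
    analysis, which only needs their movement directions).
    """
    if not schedule:
        raise ValueError("empty schedule")
    params = params or LearnerParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ground_truth not in ("po", "ma"):
        raise ValueError(f"unknown ground truth {ground_truth!r}")
    if any(abs(st.target) > 42.5 for st in schedule):
        raise ValueError("schedule directions must be within +/-42.5 deg")

    state = AdaptationState.zeros(params.primitive_spacing, params.primitive_span,
                                  params.primitive_width)
    trials: list[Trial] = []
    history: list[AdaptationState] = []

    for i, st in enumerate(schedule):
        duration = float(np.clip(rng.normal(0.55, 0.05), 0.40, 0.70))
        t, s, v = minimum_jerk(duration)
        # --- plan ---
        if st.clamp is ClampMode.NONE:
            theta_move = st.target + rng.normal(0.0, params.direction_noise)
        else:
            theta_move = st.target  # channel constrains motion straight
        # expressed adaptation (center-FF units)
        if st.trial_type is TrialType.TWO_TARGET:
            if ground_truth == "po":
                theta_plan = rng.normal(0.0, params.direction_noise)
                a_expr = state.predict(theta_plan)
            else:
                a_expr = 0.5 * (state.predict(rng.normal(30.0, params.direction_noise))
                                + state.predict(rng.normal(-30.0, params.direction_noise)))
        else:
            a_expr = state.predict(theta_move)
        # --- measured lateral force ---
        ideal_center = -k_center * CURL_GAIN_B * v  # compensation of the center-target FF
        if st.clamp is not ClampMode.NONE:
            f_lat = a_expr * ideal_center + rng.normal(0.0, params.force_noise, size=len(t))
            if st.trial_type is TrialType.TWO_TARGET:
                # target-specific feedback response after T_ON + latency
                cued = 30.0 if rng.random() < 0.5 else -30.0
                t_on = float(np.interp(TARGET_CUE_DISPLACEMENT, s, t))
                ramp = np.clip((t - t_on - params.feedback_latency) / 0.05, 0.0, 1.0)
                f_lat = f_lat + np.sign(cued) * params.feedback_gain * CURL_GAIN_B * v * ramp
            else:
                cued = st.target
            ff = FFCondition(B=CURL_GAIN_B,
                             k=k_center if (st.target == 0.0 or st.trial_type is TrialType.TWO_TARGET)
                             else -k_center,
                             clamp=st.clamp)
        else:
            k_trial = 0
            if st.ff_on:
                k_trial = k_center if st.target == 0.0 else -k_center
            ff = FFCondition(B=CURL_GAIN_B if st.ff_on else 0.0, k=k_trial)
            f_lat = k_trial * CURL_GAIN_B * v  # field actually experienced
            cued = st.target
        # --- learning ---
        history.append(state.copy())
        if st.clamp is ClampMode.NONE:
            ideal = 0.0
            if st.ff_on:
                ideal = 1.0 if ff.k == k_center else -1.0
            learner_update(state, theta_move, ideal, params)
        # --- assemble trial ---
        u = direction_unit(theta_move)
        if full_series or st.clamp is not ClampMode.NONE:
            pos, vel = np.outer(s, u), np.outer(v, u)
            tt, ffl = t, f_lat
        else:
            # single-sample placeholder carrying the peak velocity, so the
            # validity filters still see the true peak speed
            pos, vel = np.outer(s[:1], u), np.outer([v.max()], u)
            tt, ffl = t[:1], f_lat[:1]
        trials.append(Trial(
            participant=participant, trial=i, epoch=st.epoch,
            trial_type=st.trial_type,
            target_set=(30.0, -30.0) if st.trial_type is TrialType.TWO_TARGET else (st.target,),
            cued_final_target=float(cued), ff=ff, obstacle_side=ObstacleSide.NONE,
            sample_rate=DEFAULT_SAMPLE_RATE, t=tt, pos=pos, vel=vel,
            lateral_force=ffl, movement_time=duration,
            planned_direction=theta_move,
        ))
    return FFParticipantResult(trials=trials, history=history, k_center=k_center)
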