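"""Trial container and CSV interchange.

A :class:`Trial` is one outward reach: metadata (epoch, trial type, targets,
force-field / clamp / obstacle condition) plus uniformly sampled kinematic
and force time series.  Angles are in degrees with 0 = straight ahead and
positive = leftward; positions are in meters with the start at the origin
and straight-ahead along +y.

Trial tables are exchanged as long-format CSV, one row per sample, with
columns ``participant, trial, epoch, type, target, ff_k, ff_B, clamp,
obstacle, t, x, y, vx, vy, f_lat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .forcefield import ClampMode, FFCondition


class Epoch(str, Enum):
    BASELINE = "baseline"
    TRAINING = "training"
    TEST = "test"


class TrialType(str, Enum):
    ONE_TARGET = "one_target"
    TWO_TARGET = "two_target"


class ObstacleSide(str, Enum):
    NONE = "none"
    LEFT = "left"
    RIGHT = "right"


def direction_unit(angle_deg: float) -> np.ndarray:
    """Unit vector for a reach direction (0 deg = +y, positive = leftward = -x...).

    The workspace convention is: +y straight ahead, +x to the participant's
    right; a *positive* angle (leftward) therefore rotates the direction
    toward -x.
    """
    a = np.deg2rad(angle_deg)
    return np.array([-np.sin(a), np.cos(a)])


@dataclass
class Trial:
    participant: int
    trial: int
    epoch: Epoch
    trial_type: TrialType
    target_set: tuple[float, ...]
    cued_final_target: float
    ff: FFCondition
    obstacle_side: ObstacleSide
    sample_rate: float
    t: np.ndarray
    pos: np.ndarray  # (n, 2) m
    vel: np.ndarray  # (n, 2) m/s
    lateral_force: np.ndarray  # (n,) N, + along the stated lateral axis
    movement_time: float
    # direction the plan was aimed at (deg); generator metadata used by tests
    planned_direction: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        self.lateral_force = np.asarray(self.lateral_force, dtype=float)
        dt = np.diff(self.t)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("trial time base must be strictly increasing and uniform")
        if self.trial_type is TrialType.TWO_TARGET and len(self.target_set) != 2:
            raise ValueError("two_target trials must have exactly 2 potential targets")

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.vel, axis=1)

    @property
    def peak_speed(self) -> float:
        return float(self.speed.max()) if len(self.t) else 0.0

    def displacement(self) -> np.ndarray:
        """Distance of the hand from the start position at each sample (m)."""
        return np.linalg.norm(self.pos - self.pos[0], axis=1)


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    """Serialize trials to the long-format interchange table."""
    chunks = []
    for tr in trials:
        n = len(tr.t)
        chunks.append(
            pd.DataFrame(
                {
                    "participant": np.full(n, tr.participant, dtype=int),
                    "trial": np.full(n, tr.trial, dtype=int),
                    "epoch": tr.epoch.value,
                    "type": tr.trial_type.value,
                    "target": tr.cued_final_target,
                    "ff_k": tr.ff.k,
                    "ff_B": tr.ff.B,
                    "clamp": tr.ff.clamp.value,
                    "obstacle": tr.obstacle_side.value,
                    "t": tr.t,
                    "x": tr.pos[:, 0],
                    "y": tr.pos[:, 1],
                    "vx": tr.vel[:, 0],
                    "vy": tr.vel[:, 1],
                    "f_lat": tr.lateral_force,
                    "direction": np.nan if tr.planned_direction is None else tr.planned_direction,
                    "mt": tr.movement_time,
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["participant", "trial", "epoch", "type", "target", "ff_k",
                     "ff_B", "clamp", "obstacle", "t", "x", "y", "vx", "vy",
                     "f_lat", "direction", "mt"]
        )
    return pd.concat(chunks, ignore_index=True)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    """Reconstruct :class:`Trial` objects from the interchange table."""
    required = {"participant", "trial", "epoch", "type", "target", "ff_k", "ff_B",
                "clamp", "obstacle", "t", "x", "y", "vx", "vy", "f_lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    out: list[Trial] = []
    for (pid, tid), g in df.groupby(["participant", "trial"], sort=True):
        g = g.sort_values("t")
        t = g["t"].to_numpy()
        dt = np.diff(t)
        rate = 1.0 / float(np.median(dt)) if len(dt) else 200.0
        ttype = TrialType(g["type"].iloc[0])
        target = float(g["target"].iloc[0])
        target_set = (30.0, -30.0) if ttype is TrialType.TWO_TARGET else (target,)
        direction = None
        if "direction" in g.columns and np.isfinite(g["direction"].iloc[0]):
            direction = float(g["direction"].iloc[0])
        mt = float(g["mt"].iloc[0]) if "mt" in g.columns else float(t[-1] - t[0]) if len(t) else 0.0
        out.append(
            Trial(
                participant=int(pid),
                trial=int(tid),
                epoch=Epoch(g["epoch"].iloc[0]),
                trial_type=ttype,
                target_set=target_set,
                cued_final_target=target,
                ff=FFCondition(B=float(g["ff_B"].iloc[0]), k=int(g["ff_k"].iloc[0]),
                               clamp=ClampMode(g["clamp"].iloc[0])),
                obstacle_side=ObstacleSide(g["obstacle"].iloc[0]),
                sample_rate=rate,
                t=t,
                pos=g[["x", "y"]].to_numpy(),
                vel=g[["vx", "vy"]].to_numpy(),
                lateral_force=g["f_lat"].to_numpy(),
                movement_time=mt,
                planned_direction=direction,
            )
        )
    return out
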