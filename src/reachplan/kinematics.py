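"""Kinematic preprocessing: movement directions, validity filters, adaptive
movement-time thresholds, obstacle collision detection, trial-averaged
trajectories and the mirrored-and-pooled direction summaries.

Movement onset follows the online rule: the first sample at which hand speed
exceeds 5 cm/s or displacement exceeds 3 cm, whichever occurs first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

from .obstacle_models import ObstacleSummary, Variant
from .trial import ObstacleSide, Trial

ONSET_SPEED = 0.05  # m/s
ONSET_DISPLACEMENT = 0.03  # m

MT_BOUNDS = (0.225, 2.0)  # s
PEAK_SPEED_BOUNDS = (0.2, 1.0)  # m/s, applied to multi-FF-style data only

TRAJECTORY_GRID_STEP = 0.254e-3  # m, y-grid for trajectory averaging


class DirectionMode(str, Enum):
    AT_10CM = "at_10cm"  # heading 10 cm from the start (multi-FF experiment)
    AT_MIDPOINT = "at_midpoint"  # heading at the movement midpoint (obstacle experiments)


def _angle_deg(vec: np.ndarray) -> float:
    # workspace convention: 0 deg = +y, positive = leftward (-x)
    return float(np.degrees(np.arctan2(-vec[0], vec[1])))


def onset_index(trial: Trial) -> int:
    """First sample where speed > 5 cm/s or displacement > 3 cm."""
    disp = trial.displacement()
    speed = trial.speed
    hits = np.nonzero((speed > ONSET_SPEED) | (disp > ONSET_DISPLACEMENT))[0]
    return int(hits[0]) if len(hits) else 0


def movement_direction(trial: Trial, mode: DirectionMode | str = DirectionMode.AT_10CM,
                       reference: str = "onset") -> float:
    """Signed hand direction (deg) at a reference displacement, relative to
    the hand's direction at movement onset (``reference="onset"``, the
    deflection measure) or to straight ahead (``reference="ahead"``, the
    absolute direction used as the generalization-model argument).

    The reference point is 10 cm from the start (``at_10cm``) or half the
    final displacement (``at_midpoint``); positions are linearly
    interpolated to hit the reference displacement exactly.

    Raises
    ------
    ValueError
        If the trajectory never reaches the reference displacement; such
        trials are excluded from direction statistics.
    """
    mode = DirectionMode(mode)
    disp = trial.displacement()
    ref = 0.10 if mode is DirectionMode.AT_10CM else 0.5 * float(disp[-1])
    if disp[-1] < ref or len(disp) < 2:
        raise ValueError(f"trajectory never reaches reference displacement {ref:.3f} m")
    j = int(np.searchsorted(disp, ref))
    j = max(j, 1)
    frac = (ref - disp[j - 1]) / (disp[j] - disp[j - 1]) if disp[j] > disp[j - 1] else 0.0
    p_ref = trial.pos[j - 1] + frac * (trial.pos[j] - trial.pos[j - 1])
    start = trial.pos[0]
    if reference == "ahead":
        a = _angle_deg(p_ref - start)
    elif reference == "onset":
        i0 = onset_index(trial)
        d_onset = trial.pos[i0] - start
        if np.linalg.norm(d_onset) < 1e-9:
            d_onset = trial.vel[i0] if np.linalg.norm(trial.vel[i0]) > 1e-12 else (p_ref - start)
        a = _angle_deg(p_ref - start) - _angle_deg(d_onset)
    else:
        raise ValueError(f"unknown direction reference {reference!r}")
    return float((a + 180.0) % 360.0 - 180.0)


# ---------------------------------------------------------------------------
# trial validity filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept,
                "rejections": dict(self.rejections)}


def filter_trials(trials: Sequence[Trial], check_peak_speed: bool = False
                  ) -> tuple[list[Trial], FilterReport]:
    """Keep trials whose movement time is within 225-2000 ms and, for
    multi-FF-style data (``check_peak_speed=True``), whose peak speed is
    within 0.2-1 m/s."""
    report = FilterReport(n_input=len(trials))
    kept: list[Trial] = []
    for tr in trials:
        if not (MT_BOUNDS[0] <= tr.movement_time <= MT_BOUNDS[1]):
            report.rejections["movement_time"] = report.rejections.get("movement_time", 0) + 1
            continue
        if check_peak_speed and not (PEAK_SPEED_BOUNDS[0] <= tr.peak_speed <= PEAK_SPEED_BOUNDS[1]):
            report.rejections["peak_speed"] = report.rejections.get("peak_speed", 0) + 1
            continue
        kept.append(tr)
    report.n_kept = len(kept)
    return kept, report


def movement_time_threshold(history: Sequence[float], window: int = 18,
                            percentile: float = 70.0, initial: float = 2.0) -> float:
    """'Too-slow' threshold: the 70th percentile (linear-interpolation
    definition) of the most recent ``window`` movement times of the same
    trial type.  An empty history returns the configured initial threshold."""
    if len(history) == 0:
        return initial
    recent = np.asarray(history[-window:], dtype=float)
    return float(np.percentile(recent, percentile))  # type-7 linear interpolation


# ---------------------------------------------------------------------------
# obstacle geometry and collision detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObstacleGeometry:
    """Rectangular obstacle of the avoidance experiments.

    The rectangle's long axis is perpendicular to the start-to-obstructed-
    target vector and crosses it midway (10 cm along a 20 cm reach).  It is
    1 cm wide along the path and protrudes 2 cm toward the midline; away
    from the midline it extends 10 cm in the ``expt2a`` variant and 0 cm in
    the pared-down ``expt2b`` variant.  The inner (toward-midline) tip sits
    15 deg away from the straight-ahead direction.
    """

    variant: Variant
    obstructed_target: float  # deg; sign encodes the obstacle side
    reach_distance: float = 0.2
    width: float = 0.01
    toward_midline: float = 0.02

    ANGULAR_OFFSET_DEG = 15.0

    @property
    def away_from_midline(self) -> float:
        return 0.10 if Variant(self.variant) is Variant.EXPT2A else 0.0

    def corners(self) -> np.ndarray:
        from .trial import direction_unit

        u = direction_unit(self.obstructed_target)
        # perpendicular unit pointing toward the midline
        p = np.array([u[1], -u[0]]) if self.obstructed_target > 0 else np.array([-u[1], u[0]])
        c = 0.5 * self.reach_distance * u
        half_w = 0.5 * self.width
        lo, hi = -self.away_from_midline, self.toward_midline
        if hi <= lo or self.width <= 0:
            raise ValueError("degenerate obstacle rectangle")
        return np.array([
            c + (-half_w) * u + lo * p,
            c + (-half_w) * u + hi * p,
            c + half_w * u + hi * p,
            c + half_w * u + lo * p,
        ])

    def polygon(self) -> Polygon:
        return Polygon(self.corners())


def detect_collision(trial_or_path: Trial | np.ndarray, geom: ObstacleGeometry) -> bool:
    """True iff any interpolated trajectory segment intersects the closed
    obstacle rectangle (touching an edge counts as a hit)."""
    pos = trial_or_path.pos if isinstance(trial_or_path, Trial) else np.asarray(trial_or_path)
    if len(pos) < 2:
        return bool(geom.polygon().intersects(LineString([pos[0], pos[0]])))
    return bool(geom.polygon().intersects(LineString(pos)))


# ---------------------------------------------------------------------------
# trajectory averaging
# ---------------------------------------------------------------------------

def average_trajectory(trials: Sequence[Trial | np.ndarray],
                       step: float = TRAJECTORY_GRID_STEP
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean path: x-positions linearly interpolated onto a common
    y-grid (0.254 mm spacing) and averaged across trials.

    Trials whose y-progression is not monotone over the averaged span are
    dropped with a warning.  Returns ``(y_grid, mean_x)``.
    """
    paths = []
    for tr in trials:
        pos = tr.pos if isinstance(tr, Trial) else np.asarray(tr)
        y = pos[:, 1]
        if np.any(np.diff(y) <= 0):
            warnings.warn("dropping trial with non-monotone y progression from average")
            continue
        paths.append(pos)
    if not paths:
        raise ValueError("no trials with monotone y progression to average")
    y_lo = max(p[0, 1] for p in paths)
    y_hi = min(p[-1, 1] for p in paths)
    grid = np.arange(y_lo, y_hi + step / 2, step)
    xs = np.stack([np.interp(grid, p[:, 1], p[:, 0]) for p in paths])
    return grid, xs.mean(axis=0)


# ---------------------------------------------------------------------------
# mirroring and pooling of direction data
# ---------------------------------------------------------------------------

def mirror_directions(directions: Iterable[float], sides: Iterable[ObstacleSide | str]
                      ) -> np.ndarray:
    """Map per-trial deflections from the two counterbalanced obstacle-side
    conditions onto the canonical left-side convention, in which *positive =
    away from the obstacle side* (for the intermediate 2-target movement).

    Left-side trials are kept as-is and right-side trials (the mirror-image
    condition) are sign-flipped.  Trials labelled ``none`` (obstacle-free)
    must have been assigned a side beforehand (see
    :func:`assign_pseudo_sides`).
    """
    dirs = np.asarray(list(directions), dtype=float)
    signs = np.array([1.0 if ObstacleSide(s) is ObstacleSide.LEFT else -1.0
                      for s in sides])
    if any(ObstacleSide(s) is ObstacleSide.NONE for s in sides):
        raise ValueError("obstacle-free trials need an assigned pseudo-side before pooling")
    return dirs * signs


def assign_pseudo_sides(n: int, rng: np.random.Generator) -> list[ObstacleSide]:
    """Randomly label obstacle-free trials with left/right pseudo-conditions
    (balanced to within one trial) for side-matched pooling."""
    half = n // 2
    sides = [ObstacleSide.LEFT] * half + [ObstacleSide.RIGHT] * (n - half)
    rng.shuffle(sides)  # type: ignore[arg-type]
    return sides


def mirror_and_pool(participant: int,
                    variant: Variant | str,
                    conditions: Mapping[str, tuple[Sequence[float], Sequence[ObstacleSide | str]]],
                    ) -> ObstacleSummary:
    """Build a per-participant :class:`ObstacleSummary` from per-trial
    directions grouped by condition.

    ``conditions`` maps condition names (``one_target_obstructed``,
    ``one_target_unobstructed``, ``two_target_obstacle``, and optionally
    ``two_target_free``) to ``(directions, obstacle sides)``.  Each
    condition is mirrored to the away-from-obstacle-positive convention and
    pooled across sides; means and sample SDs form the summary.  A missing
    required condition yields a summary flagged incomplete.
    """
    required = ("one_target_obstructed", "one_target_unobstructed", "two_target_obstacle")
    pooled: dict[str, np.ndarray] = {}
    for name, (dirs, sides) in conditions.items():
        pooled[name] = mirror_directions(dirs, sides)
    complete = all(name in pooled and len(pooled[name]) >= 2 for name in required)

    def stat(name: str, f) -> float:
        return float(f(pooled[name])) if name in pooled and len(pooled[name]) else float("nan")

    n_trials = int(sum(len(v) for v in pooled.values()))
    return ObstacleSummary(
        participant=participant,
        variant=Variant(variant),
        mu1A=stat("one_target_obstructed", np.mean),
        mu1B=stat("one_target_unobstructed", np.mean),
        sigma1A=stat("one_target_obstructed", lambda x: np.std(x, ddof=1)),
        sigma2=stat("two_target_obstacle", lambda x: np.std(x, ddof=1)),
        mu2=stat("two_target_obstacle", np.mean),
        mu2_free=stat("two_target_free", np.mean),
        n_trials=n_trials,
        complete=complete,
    )
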