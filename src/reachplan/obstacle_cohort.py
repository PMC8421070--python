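"""Synthetic obstacle-avoidance cohorts.

Generates per-participant initial-movement-direction data for the obstacle
experiments under a selectable ground-truth planning model (motor averaging
or performance optimization), then summarizes it through the same
mirror-and-pool path the analysis uses.

Per participant, true means and variabilities are drawn from cohort-level
distributions; per-trial directions are drawn around them.  Trial
directions are stored in each side's own frame (right-side trials are the
mirror image of left-side ones), so that :func:`~reachplan.kinematics.
mirror_and_pool` recovers the away-from-obstacle-positive convention.

Defaults emulate the larger obstacle experiment (pared-down obstacle,
n = 26): obstructed 1-target movements deflect ~20 deg away from the
obstacle, which in the shared 2-target frame of that variant is a *negative*
``mu1A``; direction SDs of a few degrees are drawn lognormally so both
variability measures share one distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .kinematics import mirror_and_pool
from .obstacle_models import (OBSTACLE_OFFSET_DEG, ObstacleSummary, Variant,
                              margin_sign)
from .trial import ObstacleSide


class GroundTruth(str, Enum):
    MA = "ma"
    PO = "po"


@dataclass(frozen=True)
class ObstacleCohortSpec:
    """Cohort-level generative parameters for an obstacle experiment.

    ``mu1A_loc`` is in the shared 2-target frame (for ``expt2b`` a typical
    away-from-obstacle deflection of +20 deg corresponds to ``mu1A_loc``
    = -20).  ``sigma_med``/``sigma_logsd`` parameterize the lognormal from
    which both sigma1A and sigma2 are drawn independently.  ``noise_scale``
    scales the per-trial direction spread without changing the true
    variabilities that enter the ground-truth model.
    """

    n: int = 26
    ground_truth: GroundTruth = GroundTruth.PO
    variant: Variant = Variant.EXPT2B
    mu1A_loc: float = -20.0
    mu1A_scale: float = 6.0
    mu1B_loc: float = 0.0
    mu1B_scale: float = 2.0
    sigma_med: float = 4.5
    sigma_logsd: float = 0.25
    n_1a: int = 90
    n_1b: int = 44
    n_2: int = 120
    n_2free: int = 90
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one participant")
        if self.sigma_med <= 0 or self.sigma_logsd < 0:
            raise ValueError("direction SD distribution must be positive")
        if min(self.n_1a, self.n_1b, self.n_2, self.n_2free) < 2:
            raise ValueError("trial counts must be >= 2")
        if self.noise_scale <= 0:
            raise ValueError("noise scale must be positive")


@dataclass
class ObstacleCohort:
    spec: ObstacleCohortSpec
    summaries: list[ObstacleSummary]
    trials: pd.DataFrame = field(repr=False)
    true_params: pd.DataFrame = field(repr=False)


def ground_truth_mu2(gt: GroundTruth, variant: Variant, mu1A: float, mu1B: float,
                     sigma1A: float, sigma2: float) -> float:
    """True mean 2-target direction implied by the generating model."""
    if GroundTruth(gt) is GroundTruth.MA:
        return 0.5 * mu1A + 0.5 * mu1B
    margin = margin_sign(variant) * mu1A * (sigma2 / sigma1A) - OBSTACLE_OFFSET_DEG
    return 0.5 * margin if margin > 0 else 0.0


def _sided_draws(rng: np.random.Generator, mean: float, sd: float, n: int
                 ) -> tuple[np.ndarray, list[ObstacleSide]]:
    """Draw n trial directions around ``mean``, half per obstacle side;
    right-side trials are stored mirror-imaged (negated)."""
    d = rng.normal(mean, sd, size=n)
    half = n // 2
    sides = [ObstacleSide.LEFT] * half + [ObstacleSide.RIGHT] * (n - half)
    raw = d.copy()
    raw[half:] = -raw[half:]
    return raw, sides


def synthesize_model_cohort(model: str, weight: float, n: int,
                            rng: np.random.Generator,
                            variant: Variant = Variant.EXPT2B,
                            margin_range: tuple[float, float] = (10.0, 35.0),
                            mu1B_sd: float = 2.0,
                            ratio_logsd: float = 0.1,
                            sigma_med: float = 4.5,
                            noise_sd: float = 0.5) -> list[ObstacleSummary]:
    """Summary-level cohort whose 2-target directions follow a refined model.

    Away-from-obstacle margins are drawn uniformly over ``margin_range`` and
    per-participant variability ratios lognormally around 1; ``mu2`` is the
    refined MA (``model="ma"``) or refined PO (``model="po"``) prediction at
    the generating ``weight`` plus zero-mean direction noise of SD
    ``noise_sd``.  Used for parameter-recovery checks.
    """
    sgn = margin_sign(variant)
    out = []
    for i in range(n):
        margin = rng.uniform(*margin_range)
        mu1A = sgn * margin
        mu1B = rng.normal(0.0, mu1B_sd)
        sigma1A = sigma_med * np.exp(rng.normal(0.0, ratio_logsd))
        sigma2 = sigma1A * np.exp(rng.normal(0.0, ratio_logsd))
        if model == "ma":
            mu2 = weight * mu1A + (1.0 - weight) * mu1B
        elif model == "po":
            m = margin * (sigma2 / sigma1A) - OBSTACLE_OFFSET_DEG
            mu2 = (1.0 - weight) * m if m > 0 else 0.0
        else:
            raise ValueError(f"unknown model family {model!r}")
        out.append(ObstacleSummary(
            participant=i, variant=variant, mu1A=float(mu1A), mu1B=float(mu1B),
            sigma1A=float(sigma1A), sigma2=float(sigma2),
            mu2=float(mu2 + rng.normal(0.0, noise_sd)),
        ))
    return out


def simulate_obstacle_cohort(spec: ObstacleCohortSpec) -> ObstacleCohort:
    """Generate a cohort of per-trial directions and pooled summaries."""
    summaries: list[ObstacleSummary] = []
    trial_rows = []
    true_rows = []
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        mu1A = rng.normal(spec.mu1A_loc, spec.mu1A_scale)
        mu1B = rng.normal(spec.mu1B_loc, spec.mu1B_scale)
        sigma1A = spec.sigma_med * np.exp(rng.normal(0.0, spec.sigma_logsd))
        sigma2 = spec.sigma_med * np.exp(rng.normal(0.0, spec.sigma_logsd))
        mu2 = ground_truth_mu2(spec.ground_truth, spec.variant,
                               mu1A, mu1B, sigma1A, sigma2)
        ns = spec.noise_scale
        conditions = {
            "one_target_obstructed": _sided_draws(rng, mu1A, sigma1A * ns, spec.n_1a),
            "one_target_unobstructed": _sided_draws(rng, mu1B, sigma1A * ns, spec.n_1b),
            "two_target_obstacle": _sided_draws(rng, mu2, sigma2 * ns, spec.n_2),
            "two_target_free": _sided_draws(rng, 0.0, sigma2 * ns, spec.n_2free),
        }
        summaries.append(mirror_and_pool(i, spec.variant, conditions))
        for cond, (dirs, sides) in conditions.items():
            for d, s in zip(dirs, sides):
                trial_rows.append((i, cond, s.value, float(d)))
        true_rows.append((i, mu1A, mu1B, sigma1A, sigma2, mu2))
    trials = pd.DataFrame(trial_rows,
                          columns=["participant", "condition", "side", "direction"])
    true_params = pd.DataFrame(true_rows,
                               columns=["participant", "mu1A", "mu1B",
                                        "sigma1A", "sigma2", "mu2"])
    return ObstacleCohort(spec=spec, summaries=summaries, trials=trials,
                          true_params=true_params)
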