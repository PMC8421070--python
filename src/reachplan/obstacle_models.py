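"""Safety-margin models for obstacle avoidance under goal uncertainty.

Two model families predict the mean initial movement direction ``mu2`` on
obstacle-present 2-target trials from 1-target observations:

* motor averaging (MA): a weighted average of the motor plans for the
  obstacle-obstructed and unobstructed potential targets,
  ``mu2_hat = alpha*mu1A + (1-alpha)*mu1B`` (baseline: alpha = 1/2);
* performance optimization (PO): a weighted balance between movement timing
  (the 0 deg intermediate direction) and an obstacle-avoidance safety margin
  scaled by relative motor variability,
  ``mu2_hat = beta*0 + (1-beta)*(m1A*sigma2/sigma1A - 15 deg)`` (baseline:
  beta = 1/2), floored at 0 deg when the variability-scaled margin does not
  exceed the obstacle's 15 deg angular offset.

Angle convention: all deflections are stored in the shared 2-target frame
(positive = away from the obstacle side for the intermediate movement).
In the ``expt2a`` geometry the obstructed-target deflection is rightward
around the obstacle and is positive in this frame; in ``expt2b`` it is
leftward (toward the obstacle side of the intermediate movement) and
negative.  The PO safety margin is the *away-from-obstacle* deflection of
the obstructed 1-target movement, which is ``+mu1A`` in expt2a and
``-mu1A`` in expt2b (:attr:`ObstacleSummary.margin_1a`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Angular offset of the obstacle's inner edge from straight ahead (deg).
OBSTACLE_OFFSET_DEG = 15.0


class Variant(str, Enum):
    EXPT2A = "expt2a"
    EXPT2B = "expt2b"


def margin_sign(variant: Variant | str) -> float:
    """Sign mapping the shared-frame obstructed-target deflection onto the
    away-from-obstacle safety margin (+1 for expt2a, -1 for expt2b)."""
    return 1.0 if Variant(variant) is Variant.EXPT2A else -1.0


@dataclass
class ObstacleSummary:
    """Per-participant direction summary after left/right mirroring and pooling.

    All angles in degrees, shared 2-target frame (see module docstring);
    ``sigma1A``/``sigma2`` are sample SDs of the initial movement directions
    on obstacle-obstructed 1-target and obstacle-present 2-target trials.
    """

    participant: int
    variant: Variant
    mu1A: float
    mu1B: float
    sigma1A: float
    sigma2: float
    mu2: float
    mu2_free: float = float("nan")
    n_trials: int = 0
    complete: bool = True

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        if self.complete and (self.sigma1A < 0 or self.sigma2 < 0):
            raise ValueError("direction SDs cannot be negative")

    @property
    def margin_1a(self) -> float:
        """Away-from-obstacle deflection of obstructed 1-target movements."""
        return margin_sign(self.variant) * self.mu1A

    @property
    def ratio(self) -> float:
        """Per-participant variability ratio sigma2 / sigma1A."""
        if self.sigma1A <= 0:
            raise ValueError("variability ratio requires sigma1A > 0")
        return self.sigma2 / self.sigma1A


def summaries_to_frame(summaries: Sequence[ObstacleSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant": [s.participant for s in summaries],
            "variant": [s.variant.value for s in summaries],
            "mu1A": [s.mu1A for s in summaries],
            "mu1B": [s.mu1B for s in summaries],
            "sigma1A": [s.sigma1A for s in summaries],
            "sigma2": [s.sigma2 for s in summaries],
            "mu2": [s.mu2 for s in summaries],
            "mu2_free": [s.mu2_free for s in summaries],
            "n_trials": [s.n_trials for s in summaries],
        }
    )


def frame_to_summaries(df: pd.DataFrame) -> list[ObstacleSummary]:
    required = {"participant", "variant", "mu1A", "mu1B", "sigma1A", "sigma2", "mu2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary table is missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(ObstacleSummary(
            participant=int(row["participant"]), variant=Variant(row["variant"]),
            mu1A=float(row["mu1A"]), mu1B=float(row["mu1B"]),
            sigma1A=float(row["sigma1A"]), sigma2=float(row["sigma2"]),
            mu2=float(row["mu2"]),
            mu2_free=float(row.get("mu2_free", float("nan"))),
            n_trials=int(row.get("n_trials", 0)),
        ))
    return out


def pooled_ratio(cohort: Sequence[ObstacleSummary]) -> float:
    """Population-level variability ratio: mean sigma2 over mean sigma1A."""
    s2 = np.mean([s.sigma2 for s in cohort])
    s1 = np.mean([s.sigma1A for s in cohort])
    if s1 <= 0:
        raise ValueError("pooled sigma1A must be positive")
    return float(s2 / s1)


# ---------------------------------------------------------------------------
# model predictions
# ---------------------------------------------------------------------------

def ma_refined(s: ObstacleSummary, alpha: float) -> float:
    """Refined MA prediction ``alpha*mu1A + (1-alpha)*mu1B`` (deg)."""
    _check_weight(alpha, "alpha")
    return alpha * s.mu1A + (1.0 - alpha) * s.mu1B


def ma_baseline(s: ObstacleSummary) -> float:
    """Baseline MA prediction: equal weighting of the two potential plans."""
    return ma_refined(s, 0.5)


def po_refined(s: ObstacleSummary, beta: float, ratio: float | None = None) -> float:
    """Refined PO prediction ``beta*0 + (1-beta)*(m1A*ratio - 15 deg)``.

    ``ratio`` defaults to the participant's own sigma2/sigma1A; population-
    level calls pass the ratio of cohort means (:func:`pooled_ratio`).  The
    0 deg floor applies when the variability-scaled margin does not exceed
    the 15 deg obstacle offset.
    """
    _check_weight(beta, "beta")
    r = s.ratio if ratio is None else ratio
    if r <= 0:
        raise ValueError("variability ratio must be positive")
    margin = s.margin_1a * r - OBSTACLE_OFFSET_DEG
    if margin <= 0.0:
        return 0.0
    return beta * 0.0 + (1.0 - beta) * margin


def po_baseline(s: ObstacleSummary, ratio: float | None = None) -> float:
    """Baseline PO prediction: equal weighting of the timing and
    obstacle-avoidance objectives."""
    return po_refined(s, 0.5, ratio=ratio)


def _check_weight(w: float, name: str) -> None:
    if not (0.0 <= w <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {w}")


def population_prediction(cohort: Sequence[ObstacleSummary], model: str,
                          weight: float) -> float:
    """Population-averaged model prediction from cohort-mean inputs (deg)."""
    mu1A = float(np.mean([s.mu1A for s in cohort]))
    mu1B = float(np.mean([s.mu1B for s in cohort]))
    if model == "ma":
        return weight * mu1A + (1.0 - weight) * mu1B
    if model == "po":
        m = margin_sign(cohort[0].variant) * mu1A
        margin = m * pooled_ratio(cohort) - OBSTACLE_OFFSET_DEG
        return (1.0 - weight) * margin if margin > 0 else 0.0
    raise ValueError(f"unknown model family {model!r}")


# ---------------------------------------------------------------------------
# constrained fitting of the weighting parameters
# ---------------------------------------------------------------------------

def _clipped_slope(x: np.ndarray, y: np.ndarray) -> float:
    sxx = float(x @ x)
    if sxx <= 0:
        raise ValueError("zero variance in regressor")
    return float(np.clip((x @ y) / sxx, 0.0, 1.0))


def fit_alpha(cohort: Sequence[ObstacleSummary]) -> float:
    """Constrained least-squares estimate of the MA weighting parameter.

    Minimizes the refined-MA SSE over participants, equivalently the
    no-intercept regression of ``mu2 - mu1B`` on ``mu1A - mu1B``, with the
    slope clipped to [0, 1]."""
    _check_cohort(cohort)
    x = np.array([s.mu1A - s.mu1B for s in cohort])
    y = np.array([s.mu2 - s.mu1B for s in cohort])
    return _clipped_slope(x, y)


def fit_beta(cohort: Sequence[ObstacleSummary]) -> float:
    """Constrained least-squares estimate of the PO weighting parameter.

    Minimizes the refined-PO SSE over participants using per-participant
    variability ratios: a no-intercept regression of ``mu2`` on the
    variability-scaled margin ``m1A*sigma2/sigma1A - 15 deg``; the slope is
    ``1 - beta``, and beta is clipped to [0, 1]."""
    _check_cohort(cohort)
    x = np.array([s.margin_1a * s.ratio - OBSTACLE_OFFSET_DEG for s in cohort])
    y = np.array([s.mu2 for s in cohort])
    return float(1.0 - _clipped_slope(x, y))


def _check_cohort(cohort: Sequence[ObstacleSummary]) -> None:
    if len(cohort) < 3:
        raise ValueError("need at least 3 complete participant summaries")
    if any(not s.complete for s in cohort):
        raise ValueError("cohort contains incomplete summaries")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Fitted/evaluated obstacle model: population prediction and errors."""

    model_id: str  # e.g. MA_baseline, PO_refined
    weight: float
    prediction: float  # population-averaged predicted mu2 (deg)
    per_participant_sq_err: np.ndarray = field(repr=False, default=None)  # deg^2

    @property
    def mse(self) -> float:
        return float(np.mean(self.per_participant_sq_err))

    @property
    def sem(self) -> float:
        e = self.per_participant_sq_err
        return float(np.std(e, ddof=1) / np.sqrt(len(e)))


def evaluate_model(cohort: Sequence[ObstacleSummary], model: str, weight: float,
                   label: str | None = None) -> ModelFit:
    """Squared error of a model's population-averaged prediction against each
    participant's observed mean 2-target direction."""
    pred = population_prediction(cohort, model, weight)
    errs = np.array([(s.mu2 - pred) ** 2 for s in cohort])
    return ModelFit(model_id=label or f"{model.upper()}(w={weight:g})", weight=weight,
                    prediction=pred, per_participant_sq_err=errs)


def cross_validate(fit_cohort: Sequence[ObstacleSummary],
                   eval_cohort: Sequence[ObstacleSummary],
                   model: str) -> dict:
    """Fit a model's weighting parameter on one experiment and evaluate its
    population prediction on the other.

    Returns the held-out fit, the eval cohort's own (same-cohort) fit, and
    the percentage MSE increase of the cross-validated prediction relative
    to the same-cohort one."""
    fit_fun = {"ma": fit_alpha, "po": fit_beta}[model]
    w_cv = fit_fun(fit_cohort)
    w_self = fit_fun(eval_cohort)
    cv = evaluate_model(eval_cohort, model, w_cv, label=f"{model.upper()}_cv")
    own = evaluate_model(eval_cohort, model, w_self, label=f"{model.upper()}_self")
    increase = (cv.mse - own.mse) / own.mse * 100.0 if own.mse > 0 else 0.0
    return {"model": model, "weight_cv": w_cv, "weight_self": w_self,
            "mse_cv": cv.mse, "sem_cv": cv.sem, "mse_self": own.mse,
            "sem_self": own.sem, "pct_mse_increase": increase}


def prediction_index_value(observed: float, mu_po: float, mu_ma: float) -> float:
    """Prediction index: +1 at the PO prediction, -1 at the MA prediction,
    0 midway (``(mu2 - muC)/muD`` with common/differential modes)."""
    mu_c = 0.5 * (mu_po + mu_ma)
    mu_d = 0.5 * (mu_po - mu_ma)
    if mu_d == 0:
        raise ValueError("prediction index undefined when the PO and MA predictions coincide")
    return (observed - mu_c) / mu_d


def direction_prediction_index(cohort: Sequence[ObstacleSummary],
                               mu_po: float, mu_ma: float) -> tuple[float, np.ndarray]:
    """Per-participant prediction indices against population-level MA/PO
    direction predictions; returns (mean PI, per-participant PIs)."""
    pis = np.array([prediction_index_value(s.mu2, mu_po, mu_ma) for s in cohort])
    return float(pis.mean()), pis


def weight_sweep(cohort: Sequence[ObstacleSummary], model: str,
                 weights: Iterable[float] = (1 / 3, 0.5, 2 / 3)) -> pd.DataFrame:
    """Sensitivity sweep of prediction and MSE over a grid of weights
    (the 1:2 / 2:1 weighting check uses weights 1/3 and 2/3)."""
    rows = []
    for w in weights:
        f = evaluate_model(cohort, model, float(w))
        rows.append({"model": model, "weight": float(w),
                     "prediction": f.prediction, "mse": f.mse, "sem": f.sem})
    return pd.DataFrame(rows)
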