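"""Force-profile analysis of the multi-FF experiment.

Builds time-aligned, normalized lateral-force profiles from error-clamp
trials, forms the motor-averaging (MA) and performance-optimization (PO)
predictions for 2-target trials, quantifies their match to the data with a
prediction index, and refines the predictions with a sum-of-Gaussians
direction-generalization model.

Conventions
-----------
* Profiles are aligned to target-cue onset ``T_ON`` (the 3 cm displacement
  event); aligned time is negative before the cue.
* Values are normalized so +1 equals the amplitude of the peak ideal
  adaptive response to the center-target field; this maps the
  counterbalanced field-sign subgroups onto one canonical participant.
* The adaptation coefficient is the no-intercept regression slope of the
  baseline-subtracted clamp-trial force onto the ideal center-target
  compensation, so +1 = full compensation of the center-target field and
  -1 = full compensation of the (opposite) lateral-target field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .forcefield import ClampMode
from .trial import Epoch, Trial, TrialType

#: Common aligned time base (s relative to T_ON).
PROFILE_GRID = np.arange(-0.20, 0.40 + 1e-9, 0.005)

TARGET_CUE_DISPLACEMENT = 0.03  # m


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class ForceProfile:
    """Normalized lateral-force profile aligned to target-cue onset."""

    t: np.ndarray  # s relative to T_ON
    values: np.ndarray  # dimensionless, +1 = peak ideal center-target compensation
    onset: float  # movement onset in aligned time (s, negative)
    label: str = ""
    participant: int | None = None
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("profile time base and values must match")

    def interval_mean(self, end: float, start: float | None = None) -> float:
        """Mean value from movement onset (or ``start``) to ``end`` s after T_ON."""
        lo = self.onset if start is None else start
        mask = (self.t >= lo) & (self.t <= end) & np.isfinite(self.values)
        if not mask.any():
            raise ValueError("empty profile interval")
        return float(self.values[mask].mean())


def center_field_sign(trial: Trial) -> int:
    """Sign of the field trained at the center target for this participant,
    recovered from the trial's own field metadata."""
    if trial.trial_type is TrialType.TWO_TARGET or trial.cued_final_target == 0.0:
        return trial.ff.k
    return -trial.ff.k


def cue_onset_time(trial: Trial) -> float:
    """Time of target-cue onset: the 3 cm displacement event (s)."""
    disp = trial.displacement()
    if disp[-1] < TARGET_CUE_DISPLACEMENT:
        raise ValueError("trial never reaches the 3 cm cue displacement")
    return float(np.interp(TARGET_CUE_DISPLACEMENT, disp, trial.t))


def ideal_compensation(trial: Trial) -> np.ndarray:
    """Force profile that exactly cancels the trial's field:
    ``-k * B * speed(t)`` along the lateral axis (N)."""
    return -trial.ff.k * trial.ff.B * trial.speed


def adaptation_coefficient(measured: np.ndarray, ideal: np.ndarray,
                           baseline: np.ndarray | None = None) -> float:
    """No-intercept regression slope of (measured - baseline) on ideal."""
    measured = np.asarray(measured, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    if measured.shape != ideal.shape:
        raise ValueError("measured and ideal profiles must have equal length")
    if baseline is not None:
        measured = measured - np.asarray(baseline, dtype=float)
    denom = float(ideal @ ideal)
    if denom == 0.0:
        raise ValueError("adaptation coefficient undefined for identically zero ideal")
    return float(measured @ ideal) / denom


def trial_adaptation_coefficient(trial: Trial,
                                 baseline: "ForceProfile | None" = None) -> float:
    """Adaptation coefficient of one clamp trial against the ideal
    *center-target* compensation (canonical sign convention)."""
    if trial.ff.clamp is ClampMode.NONE:
        raise ValueError("adaptation is measured on clamp trials only")
    k_c = center_field_sign(trial)
    ideal_center = -k_c * trial.ff.B * trial.speed
    base = None
    if baseline is not None:
        # baseline profiles are stored normalized and canonical; map back to
        # this trial's raw force units before subtracting
        t_on = cue_onset_time(trial)
        scale = trial.ff.B * trial.peak_speed
        base_norm = np.interp(trial.t - t_on, baseline.t,
                              np.where(np.isfinite(baseline.values), baseline.values, 0.0),
                              left=0.0, right=0.0)
        base = base_norm * (-k_c) * scale
    return adaptation_coefficient(trial.lateral_force, ideal_center, baseline=base)


def align_and_normalize(trials: list[Trial], label: str = "",
                        grid: np.ndarray = PROFILE_GRID,
                        canonical: bool = True) -> ForceProfile:
    """Average clamp-trial profile: per trial, lateral force aligned to T_ON
    and divided by the peak of that trial's ideal center-target compensation
    (sign included, mapping both counterbalanced subgroups onto the
    canonical +1 = center-compensation convention), then averaged.

    ``canonical=False`` normalizes by magnitude only (no field-sign
    mapping); the feedback-onset detection uses this, since the kinematic
    correction toward the cued target does not flip with the
    counterbalanced field sign."""
    clamp_trials = [tr for tr in trials if tr.ff.clamp is not ClampMode.NONE]
    if not clamp_trials:
        raise ValueError("no clamp trials to build a force profile from")
    vals = np.full((len(clamp_trials), len(grid)), np.nan)
    onsets = []
    for i, tr in enumerate(clamp_trials):
        t_on = cue_onset_time(tr)
        divisor = tr.ff.B * tr.peak_speed
        if divisor <= 0:
            raise ValueError("normalization divisor must be positive")
        k_c = center_field_sign(tr)
        norm = tr.lateral_force * ((-k_c) if canonical else 1.0) / divisor
        ta = tr.t - t_on
        inside = (grid >= ta[0]) & (grid <= ta[-1])
        vals[i, inside] = np.interp(grid[inside], ta, norm)
        onsets.append(-t_on)
    pid = clamp_trials[0].participant
    finite = np.isfinite(vals)
    counts = finite.sum(axis=0)
    sums = np.where(finite, vals, 0.0).sum(axis=0)
    mean_vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ForceProfile(t=grid, values=mean_vals, onset=float(np.mean(onsets)),
                        label=label, participant=pid, n_trials=len(clamp_trials))


def subtract_baseline(profile: ForceProfile, baseline: ForceProfile) -> ForceProfile:
    if profile.t.shape != baseline.t.shape or not np.allclose(profile.t, baseline.t):
        raise ValueError("profiles must share a time base")
    base = np.where(np.isfinite(baseline.values), baseline.values, 0.0)
    return replace(profile, values=profile.values - base,
                   label=profile.label + "-baseline_subtracted")


# ---------------------------------------------------------------------------
# predictions and the prediction index
# ---------------------------------------------------------------------------

def ma_force_prediction(left: ForceProfile, right: ForceProfile) -> ForceProfile:
    """Raw MA prediction: pointwise mean of the left- and right-target
    adaptive responses."""
    if left.t.shape != right.t.shape or not np.allclose(left.t, right.t):
        raise ValueError("profiles must share a time base")
    return ForceProfile(t=left.t, values=0.5 * (left.values + right.values),
                        onset=0.5 * (left.onset + right.onset), label="MA_raw",
                        participant=left.participant,
                        n_trials=left.n_trials + right.n_trials)


def po_force_prediction(center: ForceProfile) -> ForceProfile:
    """Raw PO prediction: the center-target adaptive response."""
    return replace(center, label="PO_raw")


@dataclass
class PredictionResult:
    mu_po: float
    mu_ma: float
    mu2: float
    pi: float
    interval: str  # "to_T_ON" or "to_T_RESP"

    @property
    def mu_c(self) -> float:
        return 0.5 * (self.mu_po + self.mu_ma)

    @property
    def mu_d(self) -> float:
        return 0.5 * (self.mu_po - self.mu_ma)


def prediction_index(observed: ForceProfile, po: ForceProfile, ma: ForceProfile,
                     interval_end: float, interval: str = "",
                     start: float | None = None) -> PredictionResult:
    """Prediction index over [movement onset, interval_end]:
    ``PI = (mu2 - muC) / muD`` with ``muC = (muPO+muMA)/2`` and
    ``muD = (muPO-muMA)/2``; +1 at the PO prediction, -1 at MA."""
    s = observed.onset if start is None else start
    mu2 = observed.interval_mean(interval_end, start=s)
    mu_po = po.interval_mean(interval_end, start=s)
    mu_ma = ma.interval_mean(interval_end, start=s)
    mu_d = 0.5 * (mu_po - mu_ma)
    if mu_d == 0.0:
        raise ValueError("prediction index undefined when PO and MA interval means coincide")
    pi = (mu2 - 0.5 * (mu_po + mu_ma)) / mu_d
    return PredictionResult(mu_po=mu_po, mu_ma=mu_ma, mu2=mu2, pi=pi,
                            interval=interval or f"to_{interval_end:g}s")


def detect_t_resp(profiles_by_side: list[tuple[ForceProfile, ForceProfile]],
                  alpha: float = 0.01, sustain: int = 3) -> float | None:
    """Feedback-response onset: earliest aligned time (>= T_ON) at which the
    across-participant paired t-test of (left-cued - right-cued) force
    rejects zero at ``alpha`` for ``sustain`` consecutive samples.

    Returns seconds after T_ON, or None if never detected."""
    if len(profiles_by_side) < 3:
        raise ValueError("need at least 3 participants to detect the feedback response")
    grid = profiles_by_side[0][0].t
    diffs = np.stack([lp.values - rp.values for lp, rp in profiles_by_side])
    post = grid >= 0.0
    idx = np.nonzero(post)[0]
    sig = np.zeros(len(idx), dtype=bool)
    for j, i in enumerate(idx):
        col = diffs[:, i]
        col = col[np.isfinite(col)]
        if len(col) < 3 or np.allclose(col, col[0]):
            continue
        _, p = stats.ttest_1samp(col, 0.0)
        sig[j] = p < alpha
    run = 0
    for j in range(len(idx)):
        run = run + 1 if sig[j] else 0
        if run >= sustain:
            return float(grid[idx[j - sustain + 1]])
    return None


# ---------------------------------------------------------------------------
# generalization model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneralizationParams:
    """Sum-of-Gaussians direction generalization ``g(theta)``:
    negative-lobed Gaussians of height A1 at the lateral trained directions
    (+/-30 deg), a positive Gaussian of height A2 at the center, and an
    offset A0, all sharing width sigma (deg)."""

    A1: float
    A2: float
    A0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("generalization width sigma must be positive")


def evaluate_generalization(theta, p: GeneralizationParams):
    """``g(theta) = -A1 G(theta-30) + A2 G(theta) - A1 G(theta+30) + A0``
    with ``G`` a unit Gaussian of width sigma; even in theta."""
    th = np.asarray(theta, dtype=float)
    two_s2 = 2.0 * p.sigma**2
    g = (-p.A1 * np.exp(-((th - 30.0) ** 2) / two_s2)
         + p.A2 * np.exp(-(th**2) / two_s2)
         - p.A1 * np.exp(-((th + 30.0) ** 2) / two_s2)
         + p.A0)
    return g if g.ndim else float(g)


def fit_generalization(directions: np.ndarray, coefficients: np.ndarray,
                       sigma_grid: np.ndarray | None = None
                       ) -> tuple[GeneralizationParams, float]:
    """Least-squares fit of the sum-of-Gaussians model to population-averaged
    adaptation coefficients at probed directions.

    The amplitudes (A1, A2, A0) are linear given sigma, so the fit profiles
    them over a sigma grid and polishes the best width with a bounded local
    search (a cheap, restart-robust global strategy).  Returns the
    parameters and R^2 (defined as 1 for an exact zero-residual fit).
    """
    th = np.asarray(directions, dtype=float)
    y = np.asarray(coefficients, dtype=float)
    if len(np.unique(th)) < 5:
        raise ValueError("need at least 5 distinct probe directions for a 4-parameter fit")
    if sigma_grid is None:
        sigma_grid = np.linspace(3.0, 60.0, 58)

    def design(sig: float) -> np.ndarray:
        two_s2 = 2.0 * sig**2
        return np.column_stack([
            -(np.exp(-((th - 30.0) ** 2) / two_s2) + np.exp(-((th + 30.0) ** 2) / two_s2)),
            np.exp(-(th**2) / two_s2),
            np.ones_like(th),
        ])

    def sse_of(sig: float) -> tuple[float, np.ndarray]:
        X = design(sig)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), coef

    best = min(((*sse_of(s), s) for s in sigma_grid), key=lambda z: z[0])
    sig0 = best[2]
    res = optimize.minimize_scalar(lambda s: sse_of(s)[0],
                                   bounds=(max(1.0, sig0 - 1.0), sig0 + 1.0),
                                   method="bounded", options={"xatol": 1e-8})
    sig = float(res.x) if sse_of(float(res.x))[0] < best[0] else sig0
    sse, coef = sse_of(sig)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if math.isclose(sse, 0.0, abs_tol=1e-20) or sst == 0.0 else 1.0 - sse / sst
    params = GeneralizationParams(A1=float(coef[0]), A2=float(coef[1]),
                                  A0=float(coef[2]), sigma=sig)
    return params, r2


def refine_prediction(raw: ForceProfile, direction_sample: np.ndarray,
                      p: GeneralizationParams, nominal: float) -> ForceProfile:
    """Scale a raw prediction by the expected generalization over a
    participant's movement-direction distribution relative to the nominal
    direction: ``scale = E[g(theta)] / g(nominal)``."""
    dirs = np.asarray(direction_sample, dtype=float)
    if len(dirs) == 0:
        raise ValueError("empty movement-direction sample")
    g_nom = evaluate_generalization(nominal, p)
    if g_nom == 0.0:
        raise ValueError("refinement undefined: g(nominal) = 0")
    scale = float(np.mean(evaluate_generalization(dirs, p))) / g_nom
    return replace(raw, values=raw.values * scale, label=raw.label + "_refined")
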