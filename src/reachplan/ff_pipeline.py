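"""End-to-end multi-FF analysis: from trial records to prediction indices.

Orchestrates the force-profile operations over a cohort: per-participant
baseline-subtracted adaptive responses, the MA/PO predictions, feedback-
response-onset detection, raw and generalization-refined prediction
indices, and the generalization-probe analysis of the dense-direction
variant of the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ffanalysis import (ForceProfile, GeneralizationParams, align_and_normalize,
                         detect_t_resp, evaluate_generalization,
                         fit_generalization, ma_force_prediction,
                         po_force_prediction, prediction_index,
                         subtract_baseline, trial_adaptation_coefficient)
from .forcefield import ClampMode
from .kinematics import filter_trials, movement_direction
from .trial import Epoch, Trial, TrialType


@dataclass
class FFParticipantProfiles:
    """Analysis-ready per-participant profiles of the multi-FF experiment."""

    participant: int
    left: ForceProfile
    center: ForceProfile
    right: ForceProfile
    two: ForceProfile
    two_left: ForceProfile
    two_right: ForceProfile
    lateral_directions: np.ndarray  # 1-target FF movement directions, test epoch (deg)
    two_directions: np.ndarray  # null 2-target movement directions, baseline epoch (deg)


def _direction(tr: Trial) -> float:
    if len(tr.t) > 2:
        return movement_direction(tr, "at_10cm", reference="ahead")
    if tr.planned_direction is None:
        raise ValueError("trial carries neither kinematics nor a planned direction")
    return tr.planned_direction


def participant_ff_profiles(trials: list[Trial]) -> FFParticipantProfiles:
    """Build baseline-subtracted, normalized profiles for one participant."""
    kept, _ = filter_trials(trials, check_peak_speed=True)

    def pick(epoch, ttype, clamp=None, target=None, cue=None):
        out = []
        for tr in kept:
            if tr.epoch is not epoch or tr.trial_type is not ttype:
                continue
            if clamp is not None and tr.ff.clamp is not clamp:
                continue
            if target is not None and tr.cued_final_target != target:
                continue
            if cue is not None and np.sign(tr.cued_final_target) != np.sign(cue):
                continue
            out.append(tr)
        return out

    base = {
        tgt: align_and_normalize(pick(Epoch.BASELINE, TrialType.ONE_TARGET,
                                      ClampMode.FULL, tgt), f"baseline_{tgt:g}")
        for tgt in (30.0, 0.0, -30.0)
    }
    base2 = align_and_normalize(pick(Epoch.BASELINE, TrialType.TWO_TARGET,
                                     ClampMode.PARTIAL), "baseline_2t")
    prof = {
        tgt: subtract_baseline(
            align_and_normalize(pick(Epoch.TEST, TrialType.ONE_TARGET,
                                     ClampMode.FULL, tgt), f"test_{tgt:g}"),
            base[tgt])
        for tgt in (30.0, 0.0, -30.0)
    }
    two_all = pick(Epoch.TEST, TrialType.TWO_TARGET, ClampMode.PARTIAL)
    two = subtract_baseline(align_and_normalize(two_all, "test_2t"), base2)
    # cue-side profiles feed T_RESP detection: magnitude normalization only,
    # no baseline subtraction (the kinematic feedback correction is
    # cue-locked and does not flip with the counterbalanced field sign)
    def side_profile(side_trials, label):
        if not side_trials:  # cue side unsampled in a very small cohort
            return ForceProfile(t=base2.t, values=np.full_like(base2.t, np.nan),
                                onset=base2.onset, label=label, n_trials=0)
        return align_and_normalize(side_trials, label, canonical=False)

    two_l = side_profile([t for t in two_all if t.cued_final_target > 0], "test_2t_left")
    two_r = side_profile([t for t in two_all if t.cued_final_target < 0], "test_2t_right")
    lat_dirs = np.array([
        _direction(tr) for tr in pick(Epoch.TEST, TrialType.ONE_TARGET)
        if tr.ff.clamp is ClampMode.NONE and abs(tr.cued_final_target) == 30.0
    ])
    two_dirs = np.array([
        _direction(tr) for tr in pick(Epoch.BASELINE, TrialType.TWO_TARGET)
        if tr.ff.clamp is ClampMode.NONE
    ])
    pid = trials[0].participant
    return FFParticipantProfiles(pid, prof[30.0], prof[0.0], prof[-30.0],
                                 two, two_l, two_r, lat_dirs, two_dirs)


def _ci95(x: np.ndarray) -> float:
    if len(x) < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, len(x) - 1) * np.std(x, ddof=1) / np.sqrt(len(x)))


def analyze_ff_cohort(cohort_trials: list[list[Trial]],
                      gen: GeneralizationParams | None = None,
                      alpha: float = 0.01,
                      detect_feedback: bool = True) -> dict:
    """Cohort-level multi-FF analysis.

    Returns raw (and, given generalization parameters, refined) prediction
    indices over the movement-onset-to-T_ON and movement-onset-to-T_RESP
    intervals, with across-participant means, 95% CIs and one-sample
    t-tests, plus the detected feedback-response onset.
    """
    parts = [participant_ff_profiles(tr) for tr in cohort_trials]
    t_resp = (detect_t_resp([(p.two_left, p.two_right) for p in parts], alpha=alpha)
              if detect_feedback else None)
    intervals = {"to_T_ON": 0.0}
    if t_resp is not None:
        intervals["to_T_RESP"] = t_resp

    def pis(refined: bool) -> dict:
        out = {}
        for name, end in intervals.items():
            vals = []
            for p in parts:
                ma = ma_force_prediction(p.left, p.right)
                po = po_force_prediction(p.center)
                if refined:
                    assert gen is not None
                    s_ma = float(np.mean(evaluate_generalization(p.lateral_directions, gen))
                                 / evaluate_generalization(30.0, gen))
                    s_po = float(np.mean(evaluate_generalization(p.two_directions, gen))
                                 / evaluate_generalization(0.0, gen))
                    ma = ForceProfile(ma.t, ma.values * s_ma, ma.onset, "MA_refined",
                                      p.participant, ma.n_trials)
                    po = ForceProfile(po.t, po.values * s_po, po.onset, "PO_refined",
                                      p.participant, po.n_trials)
                vals.append(prediction_index(p.two, po, ma, end, interval=name).pi)
            arr = np.array(vals)
            t, pval = stats.ttest_1samp(arr, 0.0)
            out[name] = {"mean": float(arr.mean()), "ci95": _ci95(arr),
                         "t": float(t), "p": float(pval), "per_participant": vals}
        return out

    report = {"n": len(parts), "t_resp": t_resp, "raw": pis(False)}
    if gen is not None:
        report["refined"] = pis(True)
    return report


def training_adaptation_curve(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adaptation coefficients of training/test error-clamp trials for one
    participant: (trial indices, targets, coefficients)."""
    idx, tgts, acs = [], [], []
    for tr in trials:
        if tr.ff.clamp is ClampMode.FULL and tr.epoch in (Epoch.TRAINING, Epoch.TEST):
            idx.append(tr.trial)
            tgts.append(tr.cued_final_target)
            acs.append(trial_adaptation_coefficient(tr))
    return np.array(idx), np.array(tgts), np.array(acs)


def final_adaptation_levels(trials: list[Trial], frac: float = 0.1) -> dict[float, float]:
    """Mean adaptation coefficient over the last ``frac`` of training-epoch
    error-clamp trials, per target direction."""
    out: dict[float, float] = {}
    for tgt in (30.0, 0.0, -30.0):
        acs = [trial_adaptation_coefficient(tr) for tr in trials
               if tr.ff.clamp is ClampMode.FULL and tr.epoch is Epoch.TRAINING
               and tr.cued_final_target == tgt]
        n_tail = max(1, int(round(len(acs) * frac)))
        out[tgt] = float(np.mean(acs[-n_tail:])) if acs else float("nan")
    return out


def generalization_curve(cohort_trials: list[list[Trial]]
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Population-averaged test-epoch adaptation coefficient per probed
    direction (the generalization-variant measurement)."""
    per_dir: dict[float, list[float]] = {}
    for trials in cohort_trials:
        acc: dict[float, list[float]] = {}
        for tr in trials:
            if tr.ff.clamp is not ClampMode.FULL:
                continue
            if tr.epoch is Epoch.TEST:
                acc.setdefault(tr.cued_final_target, []).append(
                    trial_adaptation_coefficient(tr))
        for tgt, vals in acc.items():
            per_dir.setdefault(tgt, []).append(float(np.mean(vals)))
    dirs = np.array(sorted(per_dir))
    means = np.array([np.mean(per_dir[d]) for d in dirs])
    return dirs, means


def fit_generalization_from_cohort(cohort_trials: list[list[Trial]]
                                   ) -> tuple[GeneralizationParams, float]:
    """Fit the sum-of-Gaussians model to a generalization-variant cohort."""
    dirs, means = generalization_curve(cohort_trials)
    return fit_generalization(dirs, means)
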