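import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachplan.ffanalysis import (ForceProfile, GeneralizationParams,
                                  adaptation_coefficient, align_and_normalize,
                                  detect_t_resp, evaluate_generalization,
                                  fit_generalization, ideal_compensation,
                                  ma_force_prediction, po_force_prediction,
                                  prediction_index, refine_prediction)
from reachplan.forcefield import CURL_GAIN_B, ClampMode, FFCondition
from reachplan.trial import Trial, TrialType, Epoch, ObstacleSide

from conftest import make_reach_trial


def const_speed_trial(speed: float, k: int = 1, B: float = CURL_GAIN_B) -> Trial:
    n = 100
    t = np.arange(n) / 200.0
    vel = np.column_stack([np.zeros(n), np.full(n, speed)])
    pos = np.column_stack([np.zeros(n), speed * t])
    return Trial(participant=0, trial=0, epoch=Epoch.TEST,
                 trial_type=TrialType.ONE_TARGET, target_set=(0.0,),
                 cued_final_target=0.0, ff=FFCondition(B=B, k=k, clamp=ClampMode.FULL),
                 obstacle_side=ObstacleSide.NONE, sample_rate=200.0, t=t, pos=pos,
                 vel=vel, lateral_force=np.zeros(n), movement_time=t[-1])


class TestIdealCompensation:
    def test_constant_speed_magnitude(self):
        f = ideal_compensation(const_speed_trial(0.4))
        assert np.allclose(np.abs(f), 6.0)

    def test_zero_velocity(self):
        assert np.allclose(ideal_compensation(const_speed_trial(0.0)), 0.0)

    def test_sign_flips_with_field_sign(self):
        f_pos = ideal_compensation(const_speed_trial(0.4, k=1))
        f_neg = ideal_compensation(const_speed_trial(0.4, k=-1))
        assert np.allclose(f_pos, -f_neg)


class TestAdaptationCoefficient:
    def test_full_compensation_is_plus_one(self):
        tr = make_reach_trial(adaptation=1.0)
        ideal = ideal_compensation(tr)
        assert adaptation_coefficient(tr.lateral_force, ideal) == pytest.approx(1.0)

    def test_zero_force_is_zero(self):
        ideal = ideal_compensation(make_reach_trial(adaptation=1.0))
        assert adaptation_coefficient(np.zeros_like(ideal), ideal) == 0.0

    def test_linearity(self):
        ideal = ideal_compensation(make_reach_trial(adaptation=1.0))
        assert adaptation_coefficient(-0.5 * ideal, ideal) == pytest.approx(-0.5)

    @settings(derandomize=True, max_examples=30)
    @given(c=st.floats(-3, 3))
    def test_scale_equivariance(self, c):
        ideal = ideal_compensation(make_reach_trial(adaptation=1.0))
        assert adaptation_coefficient(c * ideal, ideal) == pytest.approx(c, abs=1e-9)

    def test_baseline_subtraction(self):
        ideal = ideal_compensation(make_reach_trial(adaptation=1.0))
        baseline = 0.3 * ideal
        measured = 0.7 * ideal + baseline
        assert adaptation_coefficient(measured, ideal, baseline) == pytest.approx(0.7)

    def test_zero_ideal_rejected(self):
        with pytest.raises(ValueError):
            adaptation_coefficient(np.ones(5), np.zeros(5))


class TestAlignAndNormalize:
    def test_identical_trials_equal_single_trial_profile(self):
        tr = make_reach_trial(adaptation=0.8)
        one = align_and_normalize([tr])
        many = align_and_normalize([tr, tr, tr])
        assert np.allclose(one.values, many.values, equal_nan=True)

    def test_speed_rescaling_leaves_normalized_peak_unchanged(self):
        slow = make_reach_trial(adaptation=0.8, duration=0.66)
        fast = make_reach_trial(adaptation=0.8, duration=0.44)
        p_slow = align_and_normalize([slow])
        p_fast = align_and_normalize([fast])
        assert np.nanmax(p_slow.values) == pytest.approx(np.nanmax(p_fast.values),
                                                         rel=1e-3)

    @pytest.mark.parametrize("a", [0.25, -0.6, 1.0])
    def test_known_adaptation_recovered_at_peak(self, a):
        prof = align_and_normalize([make_reach_trial(adaptation=a)])
        peak = np.nanmax(prof.values) if a > 0 else np.nanmin(prof.values)
        assert peak == pytest.approx(a, rel=1e-3)

    def test_counterbalanced_subgroups_map_to_canonical_sign(self):
        # same adaptation level, opposite field signs: canonical profiles match
        p1 = align_and_normalize([make_reach_trial(adaptation=0.5, k_center=1)])
        p2 = align_and_normalize([make_reach_trial(
            adaptation=0.5, k_center=-1,
            ff=FFCondition(B=CURL_GAIN_B, k=-1, clamp=ClampMode.FULL))])
        assert np.allclose(p1.values, p2.values, equal_nan=True)

    def test_requires_clamp_trials(self):
        tr = make_reach_trial(ff=FFCondition(B=CURL_GAIN_B, k=1))
        with pytest.raises(ValueError):
            align_and_normalize([tr])


def profile(values, onset=-0.15, t=None):
    t = np.arange(-0.2, 0.4, 0.005) if t is None else t
    return ForceProfile(t=t, values=np.broadcast_to(values, t.shape).astype(float),
                        onset=onset)


class TestPredictions:
    def test_ma_is_pointwise_mean(self):
        assert np.allclose(ma_force_prediction(profile(0.4), profile(0.8)).values, 0.6)

    def test_ma_of_mirror_pair_is_zero(self):
        assert np.allclose(ma_force_prediction(profile(0.7), profile(-0.7)).values, 0.0)

    def test_ma_of_identical_inputs(self):
        p = profile(0.3)
        assert np.allclose(ma_force_prediction(p, p).values, p.values)

    @pytest.mark.parametrize("v", [0.1, -0.5, 0.9])
    def test_po_is_identity_with_relabel(self, v):
        p = profile(v)
        out = po_force_prediction(p)
        assert np.allclose(out.values, p.values) and out.label == "PO_raw"

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            ma_force_prediction(profile(0.1), profile(0.1, t=np.arange(-0.1, 0.4, 0.005)))


class TestPredictionIndex:
    def test_definitional_anchors(self):
        po, ma = profile(0.8), profile(-0.6)
        assert prediction_index(po, po, ma, 0.0).pi == pytest.approx(1.0)
        assert prediction_index(ma, po, ma, 0.0).pi == pytest.approx(-1.0)
        mid = profile(0.1)  # (0.8 + -0.6)/2
        assert prediction_index(mid, po, ma, 0.0).pi == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(0.1, 5), shift=st.floats(-2, 2), obs=st.floats(-2, 2))
    def test_invariant_under_common_affine_transform(self, scale, shift, obs):
        po, ma, o = profile(0.8), profile(-0.6), profile(obs)
        base = prediction_index(o, po, ma, 0.0).pi
        po2, ma2, o2 = (profile(scale * v + shift) for v in (0.8, -0.6, obs))
        assert prediction_index(o2, po2, ma2, 0.0).pi == pytest.approx(base, abs=1e-9)

    def test_equal_predictions_rejected(self):
        with pytest.raises(ValueError):
            prediction_index(profile(0.1), profile(0.5), profile(0.5), 0.0)


class TestDetectTResp:
    def make_cohort(self, offset_s, n=8, effect=1.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-0.2, 0.4, 0.005)
        cohort = []
        for _ in range(n):
            ramp = np.clip((t - offset_s) / 0.05, 0, 1) if offset_s is not None else 0.0
            noise = rng.normal(0, 0.01, size=(2, len(t)))
            left = ForceProfile(t, effect * ramp + noise[0], onset=-0.15)
            right = ForceProfile(t, -effect * ramp + noise[1], onset=-0.15)
            cohort.append((left, right))
        return cohort

    def test_identical_sides_never_detect(self):
        assert detect_t_resp(self.make_cohort(None)) is None

    def test_large_divergence_at_150ms_detected_within_one_sample(self):
        got = detect_t_resp(self.make_cohort(0.150))
        assert got == pytest.approx(0.150, abs=0.0051)

    def test_requires_three_participants(self):
        with pytest.raises(ValueError):
            detect_t_resp(self.make_cohort(0.15, n=2))


class TestGeneralization:
    def test_center_gaussian_anchor(self):
        p = GeneralizationParams(A1=0, A2=1, A0=0, sigma=15)
        assert evaluate_generalization(0.0, p) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=40)
    @given(theta=st.floats(-45, 45), a1=st.floats(-2, 2), a2=st.floats(-2, 2),
           a0=st.floats(-1, 1))
    def test_even_symmetry(self, theta, a1, a2, a0):
        p = GeneralizationParams(A1=a1, A2=a2, A0=a0, sigma=12.0)
        assert evaluate_generalization(theta, p) == pytest.approx(
            evaluate_generalization(-theta, p), abs=1e-12)

    def test_lateral_lobe_value(self):
        p = GeneralizationParams(A1=1, A2=0, A0=0, sigma=15)
        assert evaluate_generalization(30.0, p) == pytest.approx(-1 - np.exp(-3600 / 450))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            GeneralizationParams(A1=0, A2=1, A0=0, sigma=0.0)

    def test_noiseless_refit_recovers_parameters_exactly(self):
        truth = GeneralizationParams(A1=0.9, A2=0.8, A0=0.15, sigma=14.0)
        th = np.arange(-30, 30.1, 7.5)
        y = evaluate_generalization(th, truth)
        fit, r2 = fit_generalization(th, y)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        for name in ("A1", "A2", "A0", "sigma"):
            assert getattr(fit, name) == pytest.approx(getattr(truth, name), abs=1e-6)

    def test_constant_data_degenerates_to_offset(self):
        th = np.arange(-30, 30.1, 7.5)
        fit, r2 = fit_generalization(th, np.full_like(th, 0.4))
        assert r2 == pytest.approx(1.0)
        assert fit.A0 == pytest.approx(0.4, abs=1e-8)
        assert abs(fit.A1) < 1e-6 and abs(fit.A2) < 1e-6

    def test_too_few_directions_rejected(self):
        with pytest.raises(ValueError):
            fit_generalization(np.array([0, 7.5, 15, 22.5]), np.zeros(4))


class TestRefinePrediction:
    P = GeneralizationParams(A1=0.9, A2=0.8, A0=0.1, sigma=14.0)

    def test_point_mass_at_nominal_is_identity(self):
        raw = profile(0.8)
        out = refine_prediction(raw, np.zeros(50), self.P, nominal=0.0)
        assert np.allclose(out.values, raw.values)

    def test_symmetric_spread_around_local_max_shrinks(self, rng):
        # numeric-integration oracle for a Gaussian direction spread at 0 deg
        dirs = rng.normal(0.0, 8.0, size=20000)
        raw = profile(1.0)
        out = refine_prediction(raw, dirs, self.P, nominal=0.0)
        scale = out.values[0] / raw.values[0]
        grid = np.linspace(-60, 60, 20001)
        w = np.exp(-grid**2 / (2 * 8.0**2))
        oracle = float(np.trapezoid(w * evaluate_generalization(grid, self.P), grid)
                       / np.trapezoid(w, grid)) / evaluate_generalization(0.0, self.P)
        assert scale < 1.0
        assert scale == pytest.approx(oracle, abs=0.02)

    def test_zero_nominal_generalization_rejected(self):
        p = GeneralizationParams(A1=0, A2=1, A0=-1, sigma=15)  # g(0) = 0
        with pytest.raises(ValueError):
            refine_prediction(profile(1.0), np.zeros(5), p, nominal=0.0)

    def test_empty_direction_sample_rejected(self):
        with pytest.raises(ValueError):
            refine_prediction(profile(1.0), np.array([]), self.P, nominal=0.0)
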