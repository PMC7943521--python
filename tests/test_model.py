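"""Forward model: lognormal speed profiles, arcs, trajectories, VTPs, SNR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import slmspeech as slm
from slmspeech.model import SampledSignal

valid_strokes = st.builds(
    slm.LognormalStroke,
    D=st.floats(0.5, 50),
    t0=st.floats(-0.5, 0.5),
    mu=st.floats(-2.5, -0.5),
    sigma=st.floats(0.05, 0.8),
    theta_s=st.floats(-3.0, 3.0),
    theta_e=st.floats(-3.0, 3.0),
)


class TestLognormalSpeed:
    def test_zero_at_and_before_onset(self, stroke):
        t = np.array([stroke.t0 - 0.1, stroke.t0])
        assert np.all(slm.lognormal_speed(t, stroke) == 0.0)

    def test_argmax_matches_closed_form(self):
        """Numeric maximization on a fine grid agrees with t0 + exp(mu-s^2)."""
        s = slm.LognormalStroke(D=1, t0=0.0, mu=-1.6, sigma=0.15)
        t = np.linspace(1e-4, 1.0, 200001)
        v = slm.lognormal_speed(t, s)
        t_num = t[np.argmax(v)]
        assert math.isclose(s.peak_time, math.exp(-1.6 - 0.15**2), rel_tol=1e-12)
        assert abs(t_num - s.peak_time) < 1e-5
        assert abs(s.peak_time - 0.1974) < 1e-4

    def test_integrates_to_amplitude(self):
        """The speed profile integrates to D over its support (quadrature)."""
        s = slm.LognormalStroke(D=2.0, t0=0.0, mu=-1.6, sigma=0.15)
        area, _ = quad(lambda u: float(slm.lognormal_speed(np.array([u]), s)[0]),
                       0.0, 10.0, limit=200)
        assert abs(area - 2.0) < 1e-6

    def test_peak_speed_closed_form(self, stroke):
        t = np.linspace(stroke.t0 + 1e-5, stroke.t0 + 2.0, 400001)
        v = slm.lognormal_speed(t, stroke)
        assert abs(v.max() - stroke.peak_speed) < 1e-6 * stroke.peak_speed

    @pytest.mark.parametrize("bad", [dict(D=-1.0), dict(sigma=0.0), dict(sigma=-0.2)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(D=1.0, t0=0.0, mu=-1.6, sigma=0.15)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            slm.LognormalStroke(**kwargs)


class TestAngularProgress:
    def test_midpoint_at_exp_mu(self, stroke):
        t = stroke.t0 + math.exp(stroke.mu)
        phi = slm.angular_progress(np.array([t]), stroke)[0]
        assert abs(phi - 0.5 * (stroke.theta_s + stroke.theta_e)) < 1e-12

    def test_limits(self, stroke):
        assert slm.angular_progress(np.array([stroke.t0 - 1.0]), stroke)[0] == stroke.theta_s
        assert abs(slm.angular_progress(np.array([stroke.t0 + 1e4]), stroke)[0]
                   - stroke.theta_e) < 1e-9

    @settings(max_examples=50, derandomize=True)
    @given(valid_strokes)
    def test_monotone_between_endpoints(self, s):
        t = s.t0 + np.linspace(1e-4, 3.0, 500)
        phi = slm.angular_progress(t, s)
        dphi = np.diff(phi)
        if s.theta_e >= s.theta_s:
            assert np.all(dphi >= -1e-12)
        else:
            assert np.all(dphi <= 1e-12)
        lo, hi = sorted((s.theta_s, s.theta_e))
        assert np.all(phi >= lo - 1e-9) and np.all(phi <= hi + 1e-9)


class TestSynthesis:
    def test_empty_plan_is_zero(self):
        tb = SampledSignal(0.0, 0.01, np.zeros(100))
        v = slm.synthesize_velocity(slm.ActionPlan([]), tb)
        assert np.all(v.samples == 0)

    def test_straight_stroke_has_no_y_velocity(self):
        s = slm.LognormalStroke(D=2, t0=0.0, mu=-1.6, sigma=0.2)
        tb = SampledSignal(0.0, 0.005, np.zeros(400))
        v = slm.synthesize_velocity(slm.ActionPlan([s]), tb)
        assert np.all(v.samples[:, 1] == 0)

    def test_superposition_of_separated_strokes(self):
        s1 = slm.LognormalStroke(D=2, t0=0.0, mu=-1.6, sigma=0.1)
        s2 = slm.LognormalStroke(D=3, t0=10.0, mu=-1.6, sigma=0.1)
        tb = SampledSignal(0.0, 0.01, np.zeros(1100))
        both = slm.synthesize_velocity(slm.ActionPlan([s1, s2]), tb)
        v1 = slm.synthesize_velocity(slm.ActionPlan([s1]), tb)
        s2b = slm.ActionPlan([s2])
        v2 = slm.synthesize_velocity(s2b, tb)
        np.testing.assert_allclose(
            both.speed(), v1.speed() + v2.speed(), atol=1e-9
        )

    def test_arc_endpoint_quarter_turn(self):
        """A quarter-circle arc of length pi/2 displaces to (1, 1)."""
        s = slm.LognormalStroke(D=math.pi / 2, t0=0.0, mu=-1.6, sigma=0.15,
                                theta_s=0.0, theta_e=math.pi / 2)
        plan = slm.ActionPlan([s])
        tb = slm.plan_timebase(plan, dt=0.001, coverage=8)
        traj = slm.synthesize_trajectory(plan, tb)
        np.testing.assert_allclose(traj.samples[-1], [1.0, 1.0], atol=1e-6)

    def test_straight_stroke_limit_matches_small_arc(self):
        """The chord limit equals the arc formula as theta_e -> theta_s."""
        tb = SampledSignal(0.0, 0.01, np.zeros(300))
        straight = slm.LognormalStroke(D=10, t0=0.0, mu=-1.6, sigma=0.15)
        tiny_arc = slm.LognormalStroke(D=10, t0=0.0, mu=-1.6, sigma=0.15,
                                       theta_s=0.0, theta_e=1e-6)
        a = slm.synthesize_trajectory(slm.ActionPlan([straight]), tb)
        b = slm.synthesize_trajectory(slm.ActionPlan([tiny_arc]), tb)
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-5)
        np.testing.assert_allclose(a.samples[-1], [10.0, 0.0], atol=1e-6)

    def test_completed_trajectory_ends_at_final_vtp(self, two_stroke_plan):
        tb = slm.plan_timebase(two_stroke_plan, dt=0.002, coverage=10)
        traj = slm.synthesize_trajectory(two_stroke_plan, tb)
        vtps = slm.virtual_targets(two_stroke_plan)
        np.testing.assert_allclose(traj.samples[-1], vtps[-1], atol=1e-6)

    def test_trajectory_is_integral_of_velocity(self, two_stroke_plan):
        """With overlap, position equals the time-integral of velocity O(dt^2)."""
        dt = 0.001
        tb = slm.plan_timebase(two_stroke_plan, dt=dt, coverage=8)
        v = slm.synthesize_velocity(two_stroke_plan, tb)
        traj = slm.synthesize_trajectory(two_stroke_plan, tb)
        integ = np.cumsum(0.5 * (v.samples[1:] + v.samples[:-1]), axis=0) * dt
        np.testing.assert_allclose(traj.samples[1:] - traj.samples[0],
                                   integ, atol=5e-4)


class TestVirtualTargets:
    def test_quarter_turn_target(self):
        s = slm.LognormalStroke(D=math.pi / 2, t0=0.0, mu=-1.6, sigma=0.15,
                                theta_s=0.0, theta_e=math.pi / 2)
        vtps = slm.virtual_targets(slm.ActionPlan([s]))
        np.testing.assert_allclose(vtps[1], [1.0, 1.0], atol=1e-12)

    def test_straight_stroke_chord(self):
        s = slm.LognormalStroke(D=3.0, t0=0.0, mu=-1.6, sigma=0.15,
                                theta_s=0.7, theta_e=0.7)
        vtps = slm.virtual_targets(slm.ActionPlan([s]))
        np.testing.assert_allclose(
            vtps[1], [3 * math.cos(0.7), 3 * math.sin(0.7)], atol=1e-12
        )

    def test_chain_is_cumulative_sum_of_chords(self):
        strokes = [
            slm.LognormalStroke(D=2, t0=0.0, mu=-1.6, sigma=0.1, theta_s=0.0, theta_e=1.0),
            slm.LognormalStroke(D=3, t0=0.2, mu=-1.5, sigma=0.2, theta_s=1.0, theta_e=0.5),
            slm.LognormalStroke(D=1, t0=0.4, mu=-1.4, sigma=0.15, theta_s=0.5, theta_e=0.5),
        ]
        plan = slm.ActionPlan(strokes, vtp0=(1.0, -2.0))
        vtps = slm.virtual_targets(plan)
        expected = np.array([1.0, -2.0])
        for j, s in enumerate(strokes, start=1):
            expected = expected + s.chord()
            np.testing.assert_allclose(vtps[j], expected, atol=1e-12)


class TestSnr:
    def _sig(self, x):
        return SampledSignal(0.0, 0.01, np.asarray(x, dtype=float))

    def test_perfect_reconstruction_is_infinite(self):
        v = self._sig(np.sin(np.linspace(0, 3, 200)) ** 2)
        assert slm.snr(v, v) == math.inf
        assert slm.snr(v, v, cap=100.0) == 100.0

    def test_zero_reconstruction_is_zero_db(self):
        v = self._sig(np.random.default_rng(0).random(100) + 0.5)
        z = self._sig(np.zeros(100))
        assert abs(slm.snr(v, z)) < 1e-12

    def test_half_amplitude_is_12_db(self):
        v = self._sig(np.random.default_rng(1).random(100) + 0.5)
        half = self._sig(0.5 * v.samples)
        assert abs(slm.snr(v, half) - 20 * math.log10(4)) < 1e-12
        assert abs(slm.snr(v, half) - 12.04) < 0.01

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.random((50, 2))
        b = a + 0.1 * rng.random((50, 2))
        s1 = slm.snr(SampledSignal(0, 0.01, a), SampledSignal(0, 0.01, b))
        s2 = slm.snr(SampledSignal(0, 0.01, 7.3 * a), SampledSignal(0, 0.01, 7.3 * b))
        assert abs(s1 - s2) < 1e-9

    def test_mismatched_grids_rejected(self):
        a = SampledSignal(0.0, 0.01, np.ones(10))
        b = SampledSignal(0.0, 0.02, np.ones(10))
        with pytest.raises(ValueError):
            slm.snr(a, b)


class TestSupport:
    def test_bounds_sit_at_level_times_peak(self, stroke):
        lo, hi = slm.lognormal_support(stroke, 0.05)
        target = 0.05 * stroke.peak_speed
        for b in (lo, hi):
            v = slm.lognormal_speed(np.array([b]), stroke)[0]
            assert abs(v - target) < 1e-9 * target
        assert stroke.t0 < lo < stroke.peak_time < hi

    @settings(max_examples=30, derandomize=True)
    @given(valid_strokes, st.floats(-0.3, 0.3))
    def test_shift_equivariance_and_amplitude_invariance(self, s, delta):
        lo, hi = slm.lognormal_support(s)
        shifted = slm.LognormalStroke(D=s.D, t0=s.t0 + delta, mu=s.mu,
                                      sigma=s.sigma)
        lo2, hi2 = slm.lognormal_support(shifted)
        assert abs(lo2 - lo - delta) < 1e-8 and abs(hi2 - hi - delta) < 1e-8
        scaled = slm.LognormalStroke(D=5 * s.D, t0=s.t0, mu=s.mu, sigma=s.sigma)
        lo3, hi3 = slm.lognormal_support(scaled)
        assert abs(lo3 - lo) < 1e-8 and abs(hi3 - hi) < 1e-8


class TestActionPlanSerialization:
    def test_json_round_trip(self, two_stroke_plan):
        text = two_stroke_plan.to_json()
        back = slm.ActionPlan.from_json(text)
        assert back.vtp0 == two_stroke_plan.vtp0
        for a, b in zip(back.strokes, two_stroke_plan.strokes):
            assert a.as_dict() == b.as_dict()

    def test_out_of_order_strokes_rejected(self):
        with pytest.raises(ValueError):
            slm.ActionPlan([
                slm.LognormalStroke(D=1, t0=0.5, mu=-1.6, sigma=0.1),
                slm.LognormalStroke(D=1, t0=0.1, mu=-1.6, sigma=0.1),
            ])
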