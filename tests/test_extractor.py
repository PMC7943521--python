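"""Inverse problem: greedy lognormal decomposition of velocity signals."""

import math

import numpy as np
import pytest

import slmspeech as slm
from slmspeech.extract import (
    ExtractionConfig,
    SigmaLognormalExtractor,
    SkipCandidate,
    estimate_stroke_from_peak,
    extract,
    find_stroke_candidates,
    refine,
)
from slmspeech.model import SampledSignal


def _velocity(plan, dt=0.01):
    return slm.synthesize_velocity(plan, slm.plan_timebase(plan, dt=dt))


class TestCandidates:
    def test_all_zero_signal_yields_no_candidates(self):
        sig = SampledSignal(0.0, 0.01, np.zeros(100))
        assert find_stroke_candidates(sig) == []

    def test_single_stroke_single_candidate_at_mode(self, stroke):
        v = _velocity(slm.ActionPlan([stroke]))
        cands = find_stroke_candidates(v)
        assert len(cands) == 1
        assert abs(cands[0][0] - stroke.peak_time) <= v.dt

    def test_two_separated_strokes_two_candidates(self):
        plan = slm.ActionPlan([
            slm.LognormalStroke(D=2, t0=0.0, mu=-1.6, sigma=0.1),
            slm.LognormalStroke(D=3, t0=1.0, mu=-1.6, sigma=0.1),
        ])
        assert len(find_stroke_candidates(_velocity(plan))) == 2

    def test_candidates_sorted_by_time(self):
        plan = slm.ActionPlan([
            slm.LognormalStroke(D=3, t0=0.0, mu=-1.6, sigma=0.1),
            slm.LognormalStroke(D=2, t0=0.8, mu=-1.6, sigma=0.1),
        ])
        cands = find_stroke_candidates(_velocity(plan))
        times = [c[0] for c in cands]
        assert times == sorted(times)


class TestInitializer:
    def test_noiseless_single_stroke_close_to_truth(self):
        truth = slm.LognormalStroke(D=5, t0=0.05, mu=-1.6, sigma=0.15)
        v = _velocity(slm.ActionPlan([truth]))
        peak = find_stroke_candidates(v)[0]
        est = estimate_stroke_from_peak(v, peak, velocity=v)
        assert abs(est.D - truth.D) / truth.D < 0.10
        assert abs(est.mu - truth.mu) / abs(truth.mu) < 0.10
        assert abs(est.sigma - truth.sigma) / truth.sigma < 0.10
        assert abs(est.t0 - truth.t0) < 0.005

    def test_narrow_stroke_recovers_small_sigma(self):
        truth = slm.LognormalStroke(D=5, t0=0.05, mu=-1.6, sigma=0.05)
        v = _velocity(slm.ActionPlan([truth]), dt=0.002)
        est = estimate_stroke_from_peak(v, find_stroke_candidates(v)[0], velocity=v)
        assert 0 < est.sigma < 0.12

    def test_straight_stroke_yields_equal_angles(self):
        truth = slm.LognormalStroke(D=5, t0=0.05, mu=-1.6, sigma=0.15,
                                    theta_s=0.8, theta_e=0.8)
        v = _velocity(slm.ActionPlan([truth]))
        est = estimate_stroke_from_peak(v, find_stroke_candidates(v)[0], velocity=v)
        assert abs(est.theta_e - est.theta_s) < 1e-9
        assert abs(est.theta_s - 0.8) < 0.05

    def test_edge_peak_raises_skip(self):
        # a profile cut right at its maximum has no left crossing
        truth = slm.LognormalStroke(D=5, t0=0.0, mu=-1.6, sigma=0.15)
        t = truth.peak_time + 0.01 * np.arange(50)
        v = slm.lognormal_speed(t, truth)
        sig = SampledSignal(float(t[0]), 0.01, v)
        with pytest.raises(SkipCandidate):
            estimate_stroke_from_peak(sig, (float(t[0]), float(v[0])))


class TestExtract:
    def test_zero_observation(self):
        sig = SampledSignal(0.0, 0.01, np.zeros((100, 2)))
        res = extract(sig)
        assert res.nblog == 0 and res.converged and math.isinf(res.snr)

    def test_nonfinite_input_rejected(self):
        bad = np.zeros((50, 2))
        bad[10, 0] = np.nan
        with pytest.raises(ValueError):
            extract(SampledSignal(0.0, 0.01, bad))

    def test_single_stroke_recovered_within_two_percent(self, stroke):
        v = _velocity(slm.ActionPlan([stroke]))
        res = extract(v)
        assert res.nblog == 1
        assert res.snr >= 40
        est = res.strokes[0]
        for field in ("D", "mu", "sigma", "theta_s", "theta_e"):
            a, b = getattr(stroke, field), getattr(est, field)
            assert abs(b - a) <= 0.02 * max(abs(a), 0.1), field
        assert abs(est.t0 - stroke.t0) < 0.002

    def test_five_stroke_plan_fully_recovered(self, sound_map):
        plan, _ = slm.sample_action_plan(sound_map, slm.SynthConfig(n_strokes=5, seed=1))
        res = extract(_velocity(plan), ExtractionConfig(snr_target=40))
        assert res.nblog == 5
        assert res.snr >= 25

    def test_snr_consistent_with_reconstruction(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        res = extract(v)
        recomputed = slm.snr(v, res.reconstruction)
        assert math.isclose(res.snr, recomputed, rel_tol=1e-12)

    def test_deterministic(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        r1, r2 = extract(v), extract(v)
        assert r1.snr == r2.snr
        assert [s.as_dict() for s in r1.strokes] == [s.as_dict() for s in r2.strokes]

    def test_idempotent_on_own_reconstruction(self, two_stroke_plan):
        """Re-extracting a reconstruction explains it at least as well
        (up to numerical precision once both fits are essentially exact)."""
        v = _velocity(two_stroke_plan)
        first = extract(v)
        second = extract(first.reconstruction)
        assert second.snr >= first.snr or min(first.snr, second.snr) >= 100.0

    def test_speed_only_extraction(self, stroke):
        v = _velocity(slm.ActionPlan([stroke]))
        speed = SampledSignal(v.t_start, v.dt, v.speed())
        res = extract(speed)
        assert res.nblog == 1
        assert res.snr >= 40
        assert res.strokes[0].theta_s == res.strokes[0].theta_e == 0.0


class TestRefine:
    def test_fixed_point_on_optimal_strokes(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        out = refine(list(two_stroke_plan.strokes), v)
        for a, b in zip(two_stroke_plan.strokes, out):
            for f in ("D", "t0", "mu", "sigma", "theta_s", "theta_e"):
                assert abs(getattr(a, f) - getattr(b, f)) < 1e-4

    def test_returns_to_truth_from_perturbation(self, two_stroke_plan):
        from dataclasses import replace

        v = _velocity(two_stroke_plan)
        pert = [replace(s, D=s.D * 1.1, mu=s.mu * 0.9, sigma=s.sigma * 1.1)
                for s in two_stroke_plan.strokes]
        out = refine(pert, v, ExtractionConfig(refine_tolerance=1e-13))
        for a, b in zip(two_stroke_plan.strokes, out):
            for f in ("D", "t0", "mu", "sigma", "theta_s", "theta_e"):
                ref = max(abs(getattr(a, f)), 0.1)
                assert abs(getattr(a, f) - getattr(b, f)) <= 0.01 * ref, f

    def test_never_decreases_snr_on_noisy_signal(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        rng = np.random.default_rng(7)
        power = float(np.mean(v.speed() ** 2))
        noisy = SampledSignal(
            v.t_start, v.dt,
            v.samples + rng.normal(0, math.sqrt(power / 10 ** 2) / math.sqrt(2),
                                   v.samples.shape),
        )
        before = slm.snr(noisy, slm.synthesize_velocity(two_stroke_plan, noisy))
        out = refine(list(two_stroke_plan.strokes), noisy)
        after = slm.snr(noisy, slm.synthesize_velocity(slm.ActionPlan(sorted(out, key=lambda s: s.t0)), noisy))
        assert after >= before - 1e-9


class TestMonotoneImprovement:
    def test_snr_nondecreasing_across_greedy_iterations(self, sound_map):
        """Each accepted greedy addition must not lower the reported SNR."""
        plan, _ = slm.sample_action_plan(sound_map, slm.SynthConfig(n_strokes=4, seed=5))
        v = _velocity(plan)
        snrs = []
        for budget in (1, 2, 3, 4):
            res = extract(v, ExtractionConfig(snr_target=200, max_strokes=budget,
                                              prune=False))
            snrs.append(min(res.snr, 1e6))
        assert all(b >= a - 1e-6 for a, b in zip(snrs, snrs[1:]))


class TestEstimatorFacade:
    def test_fit_sets_fitted_attributes(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        est = SigmaLognormalExtractor().fit(v)
        assert est.n_strokes_ == len(est.strokes_)
        assert est.converged_
        assert est.reconstruction_.same_grid(v)
        assert est.residual_.same_grid(v)

    def test_get_set_params_round_trip(self):
        est = SigmaLognormalExtractor(snr_target=30.0)
        params = est.get_params()
        assert params["snr_target"] == 30.0
        est.set_params(peak_floor=0.02)
        assert est._config().peak_floor == 0.02

    def test_predict_resynthesizes_velocity(self, two_stroke_plan):
        v = _velocity(two_stroke_plan)
        est = SigmaLognormalExtractor().fit(v)
        out = est.predict(v)
        np.testing.assert_allclose(out.samples, est.reconstruction_.samples,
                                   atol=1e-9)

    def test_result_table_has_one_row_per_stroke(self, two_stroke_plan):
        est = SigmaLognormalExtractor().fit(_velocity(two_stroke_plan))
        df = est.result_.to_table()
        assert len(df) == est.n_strokes_
        assert {"D", "t0", "mu", "sigma", "peak_time", "support_begin"} <= set(df.columns)
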