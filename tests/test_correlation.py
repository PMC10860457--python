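"""Respiratory correlation model: fitting, prediction, gating."""

import numpy as np
import pytest

from mdtt.correlation import (BEAM_HOLD, BEAM_ON, fit_model, model_residuals,
                              predict, surrogate_states, verification_summary,
                              verify_tracking)
from mdtt.phantom import patient_like_trace
from mdtt.reconstruction import MotionTrace3D


def _states_and_trace(times, signal, positions):
    return surrogate_states(times, signal), MotionTrace3D(times, positions)


def _sine_signal(n=120, dt=0.2, period=8.0, amp=3.0):
    t = np.arange(n) * dt
    return t, amp * np.sin(2 * np.pi * t / period)


class TestFitModel:
    def test_exact_linear_case(self):
        t, s = _sine_signal()
        pos = np.stack([np.zeros_like(s), 2.0 * s, np.zeros_like(s)], axis=1)
        states, trace = _states_and_trace(t, s, pos)
        model = fit_model(states, trace)
        assert np.allclose(model.coeffs[1], [0.0, 2.0, 0.0, 0.0], atol=1e-9)
        assert np.allclose(model.residual_mean, 0.0, atol=1e-9)

    def test_constant_signal_rank_deficient(self):
        t = np.arange(30.0)
        states, trace = _states_and_trace(t, np.ones_like(t), np.zeros((30, 3)))
        with pytest.raises(ValueError):
            fit_model(states, trace)

    def test_too_few_samples_rejected(self):
        t = np.arange(10.0)
        states, trace = _states_and_trace(t, np.sin(t), np.zeros((10, 3)))
        with pytest.raises(ValueError):
            fit_model(states, trace)

    def test_velocity_term_captures_hysteresis(self):
        # A phase-lagged (loop-shaped) internal-vs-external relation needs
        # the velocity term: it must come out nonzero and cut residuals
        # versus the velocity-free quadratic.
        tr = patient_like_trace(seed=4, amplitude_jitter=0.0, period_jitter=0.0,
                                drift_mm_per_min=0.0, external_noise_sd=0.0,
                                duration_s=40.0)
        t = tr.times[::5]
        states = surrogate_states(t, tr.external_at(t))
        trace = MotionTrace3D(t, tr.displacement_at(t))
        model = fit_model(states, trace)
        assert abs(model.coeffs[1, 3]) > 0.05  # SI velocity coefficient
        s = np.array([x.signal_mm for x in states])
        X0 = np.column_stack([np.ones_like(s), s, s * s])
        beta, *_ = np.linalg.lstsq(X0, trace.positions, rcond=None)
        res0 = np.abs(trace.positions - X0 @ beta).mean(axis=0)
        assert model.residual_mean[1] < res0[1]

    def test_residuals_invariant_to_time_shift(self):
        t, s = _sine_signal()
        rng = np.random.default_rng(0)
        pos = np.stack([0.1 * s, 2.0 * s + 0.05 * s**2, -0.4 * s], axis=1)
        pos += 0.1 * rng.standard_normal(pos.shape)
        m1 = fit_model(*_states_and_trace(t, s, pos))
        m2 = fit_model(*_states_and_trace(t + 137.0, s, pos))
        assert np.allclose(m1.residual_mean, m2.residual_mean, atol=1e-12)
        assert np.allclose(m1.coeffs, m2.coeffs, atol=1e-12)

    def test_fitted_beats_constant_prediction_across_seeds(self):
        # Least-squares optimality: the fitted model's residuals never
        # exceed those of the best constant predictor, over many draws.
        t, s = _sine_signal()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = np.stack([0.2 * s, 1.8 * s, 0.5 * s**2], axis=1)
            pos += 0.3 * rng.standard_normal(pos.shape)
            states, trace = _states_and_trace(t, s, pos)
            model = fit_model(states, trace)
            const_res = np.abs(pos - pos.mean(axis=0)).mean(axis=0)
            assert np.all(model.residual_mean <= const_res + 1e-12)


class TestPredict:
    def test_exact_at_fit_sample(self):
        t, s = _sine_signal()
        pos = np.stack([np.zeros_like(s), 2.0 * s, np.zeros_like(s)], axis=1)
        states, trace = _states_and_trace(t, s, pos)
        model = fit_model(states, trace)
        p, extrap = predict(model, states[10])
        assert np.allclose(p, pos[10], atol=1e-9)
        assert not extrap

    def test_zero_state_returns_intercept(self):
        t, s = _sine_signal()
        pos = np.stack([1.0 + 0.0 * s, 5.0 + 2.0 * s, -2.0 + 0.0 * s], axis=1)
        states, trace = _states_and_trace(t, s, pos)
        model = fit_model(states, trace)
        from mdtt.correlation import SurrogateState

        p, _ = predict(model, SurrogateState(0.0, 0.0, 0.0))
        assert np.allclose(p, [1.0, 5.0, -2.0], atol=1e-9)

    def test_extrapolation_flagged(self):
        t, s = _sine_signal(amp=2.0)
        pos = np.stack([s, s, s], axis=1)
        states, trace = _states_and_trace(t, s, pos)
        model = fit_model(states, trace)
        from mdtt.correlation import SurrogateState

        _, extrap = predict(model, SurrogateState(0.0, 10.0, 0.0))
        assert extrap

    def test_held_out_error_comparable_to_fit_residual(self):
        # Train/test split on a stationary stochastic session: held-out RMS
        # within 25% of the in-sample residual RMS.
        rng = np.random.default_rng(12)
        t = np.arange(400) * 0.2
        s = 3.0 * np.sin(2 * np.pi * t / 8.0)
        v = np.gradient(s, t)
        y = np.stack([0.3 * s, 1.9 * s + 0.07 * s**2 + 0.4 * v, -0.6 * s], axis=1)
        y += 0.3 * rng.standard_normal(y.shape)
        states, trace = _states_and_trace(t, s, y)
        fit_states, fit_trace = _states_and_trace(t[:300], s[:300], y[:300])
        model = fit_model(fit_states, fit_trace)
        pred = np.stack([predict(model, st)[0] for st in states[300:]])
        rms_out = np.sqrt(((y[300:] - pred) ** 2).mean())
        X = np.column_stack([np.ones(300), s[:300], s[:300]**2, v[:300]])
        beta, *_ = np.linalg.lstsq(X, y[:300], rcond=None)
        rms_in = np.sqrt(((y[:300] - X @ beta) ** 2).mean())
        assert rms_out == pytest.approx(rms_in, rel=0.25)


class TestParameterRecovery:
    def test_coefficients_within_three_se(self):
        # Data generated from a known quadratic+velocity model with 0.3 mm
        # noise (n = 200): each coefficient within 3 SE in >= 95% of 100
        # seeded replicates.
        true = np.array([[0.5, 0.3, 0.02, 0.1],
                         [11.0, 2.4, 0.05, -0.7],
                         [-1.8, 0.9, -0.03, 0.2]])
        t = np.arange(200) * 0.2
        s = 3.0 * np.sin(2 * np.pi * t / 8.0) + 0.3 * np.sin(2 * np.pi * t / 23.0)
        v = np.gradient(s, t)
        X = np.column_stack([np.ones_like(s), s, s * s, v])
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            y = X @ true.T + 0.3 * rng.standard_normal((len(t), 3))
            states, trace = _states_and_trace(t, s, y)
            model = fit_model(states, trace)
            within = np.abs(model.coeffs - true) <= 3.0 * model.coeff_se
            ok += bool(np.all(within))
        assert ok >= 95


class TestVerification:
    def _records(self, diffs, tol=3.0):
        t = np.arange(len(diffs), dtype=float)
        det = np.zeros((len(diffs), 3))
        det[:, 1] = diffs
        trace = MotionTrace3D(t, det)
        states = surrogate_states(t, np.sin(t))
        # A model predicting exactly zero everywhere.
        zero = np.zeros((len(t), 3))
        model = fit_model(surrogate_states(np.arange(30.0),
                                           np.sin(np.arange(30.0))),
                          MotionTrace3D(np.arange(30.0), np.zeros((30, 3))))
        return verify_tracking(model, trace, states, tolerance_mm=tol)

    def test_perfect_prediction_all_beam_on(self):
        recs = self._records(np.zeros(10))
        assert all(r.beam_status == BEAM_ON for r in recs)
        assert all(r.vector_diff_mm == 0.0 for r in recs)

    def test_boundary_equal_tolerance_keeps_beam_on(self):
        recs = self._records(np.array([3.0]), tol=3.0)
        assert recs[0].beam_status == BEAM_ON

    def test_single_excursion_single_hold(self):
        diffs = np.array([0.5, 0.8, 3.5, 0.6, 0.4])
        recs = self._records(diffs, tol=3.0)
        holds = [r.beam_status for r in recs]
        assert holds.count(BEAM_HOLD) == 1
        assert recs[2].beam_status == BEAM_HOLD

    def test_truth_table_depends_only_on_diff_and_tolerance(self):
        for tol in (0.0, 1.0, 3.0):
            for d in (0.0, 0.5, 1.0, 2.9999, 3.0, 3.0001, 10.0):
                recs = self._records(np.array([d]), tol=tol)
                expected = BEAM_HOLD if d > tol else BEAM_ON
                assert recs[0].beam_status == expected

    def test_summary_statistics(self):
        recs = self._records(np.array([1.0, 2.0, 4.0]))
        s = verification_summary(recs)
        assert s["mean_3d_mm"] == pytest.approx(7.0 / 3.0)
        assert s["hold_fraction"] == pytest.approx(1.0 / 3.0)
        assert s["n"] == 3


class TestModelResiduals:
    def test_perfect_fit_zero_residuals(self):
        t, s = _sine_signal()
        pos = np.stack([s, 2 * s, 3 * s], axis=1)
        states, trace = _states_and_trace(t, s, pos)
        model = fit_model(states, trace)
        mean, sd = model_residuals(model, states, trace)
        assert np.allclose(mean, 0.0, atol=1e-9)
        assert np.allclose(sd, 0.0, atol=1e-9)
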