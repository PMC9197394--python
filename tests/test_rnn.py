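"""Network dynamics, input law, gradients, and training behavior."""

import numpy as np
import pytest

from tanglekit.rnn import (
    InputProtocol,
    RNNParams,
    TrainConfig,
    _loss_and_grads,
    _nmse,
    extract_steady_cycle,
    make_input,
    make_target,
    readout,
    simulate,
    step,
)
from tanglekit.netanalysis import fundamental_period


def zero_params(n=4, k=1, p=2, tau=10.0):
    return RNNParams(A=np.zeros((n, n)), B=np.zeros((n, k)), b=np.zeros(n),
                     C=np.zeros((p, n)), d_out=np.zeros(p), tau=tau)


class TestStep:
    def test_pure_leak_decays_by_one_over_tau(self):
        params = zero_params(tau=10.0)
        r = np.array([1.0, -2.0, 0.5, 3.0])
        np.testing.assert_allclose(step(params, r, np.zeros(1)), 0.9 * r)

    def test_bias_fixed_point_reached_geometrically(self):
        params = zero_params()
        params.b = np.array([0.3, -0.7, 1.1, 0.0])
        r = np.zeros(4)
        residuals = []
        for _ in range(50):
            r = step(params, r, np.zeros(1))
            residuals.append(np.linalg.norm(r - params.b))
        ratios = np.array(residuals[1:20]) / np.array(residuals[:19])
        np.testing.assert_allclose(ratios, 0.9, atol=1e-12)
        # residual halves every log(0.5)/log(0.9) ~ 6.6 steps
        halving = np.log(0.5) / np.log(ratios.mean())
        assert halving == pytest.approx(6.58, abs=0.01)

    def test_non_finite_state_rejected(self):
        params = zero_params()
        with pytest.raises(ValueError):
            step(params, np.array([np.nan, 0, 0, 0]), np.zeros(1))


class TestReadout:
    def test_zero_weights_give_bias(self):
        params = zero_params()
        params.d_out = np.array([0.5, -1.0])
        out = readout(params, np.zeros((4, 10)))
        np.testing.assert_allclose(out, np.tile(params.d_out[:, None], (1, 10)))

    def test_single_unit_identity_readout_is_tanh(self):
        params = RNNParams(A=np.zeros((1, 1)), B=np.zeros((1, 1)), b=np.zeros(1),
                           C=np.ones((1, 1)), d_out=np.zeros(1), tau=10)
        r = np.linspace(-2, 2, 20)[None, :]
        np.testing.assert_allclose(readout(params, np.tanh(r)), np.tanh(r))

    def test_matches_matrix_multiply_oracle(self, rng):
        params = zero_params()
        params.C = rng.standard_normal((2, 4))
        params.d_out = rng.standard_normal(2)
        f = rng.standard_normal((4, 30))
        np.testing.assert_allclose(
            readout(params, f), params.C @ f + params.d_out[:, None]
        )


class TestInputLaw:
    def test_slowest_condition_amplitude(self):
        assert InputProtocol().amplitude(1) == 0.5

    def test_fastest_condition_amplitude(self):
        assert InputProtocol().amplitude(8) == 0.9375

    def test_zero_before_onset(self):
        proto = InputProtocol()
        for c in range(1, 9):
            u, on, off = make_input(proto, c, 2000, seed=0)
            assert on == 800
            np.testing.assert_array_equal(u[:, :800], 0)
            assert np.all(u[0, 800:off] == proto.amplitude(c))

    def test_off_step_drawn_from_stated_range(self):
        proto = InputProtocol()
        offs = [make_input(proto, 1, 2000, seed=s)[2] for s in range(50)]
        assert all(1500 <= o <= 1900 for o in offs)
        assert len(set(offs)) > 10

    def test_one_hot_is_indicator(self):
        proto = InputProtocol(mode="one_hot")
        u, on, off = make_input(proto, 3, 2000, seed=1)
        assert u.shape[0] == 8
        np.testing.assert_array_equal(u[:, on:off].sum(axis=0), 1)
        assert np.all(u[2, on:off] == 1)

    def test_timing_scales_with_total_steps(self):
        on, lo, hi = InputProtocol().timing(1000)
        assert (on, lo, hi) == (400, 750, 950)

    def test_condition_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            InputProtocol().amplitude(9)

    def test_target_zero_when_input_off(self, factor_spec):
        y = make_target(factor_spec, 1, 2000, 4.0, 800, 1700)
        np.testing.assert_array_equal(y[:, :800], 0)
        np.testing.assert_array_equal(y[:, 1700:], 0)
        assert np.abs(y[:, 800:1700]).max() > 0


class TestGradients:
    def test_bptt_matches_finite_differences(self, rng):
        """BPTT gradients agree with central finite differences on a tiny
        network — the fundamental correctness check for training."""
        n, k, p, T, C = 5, 2, 3, 25, 2
        params = RNNParams(
            A=rng.standard_normal((n, n)) * 0.3,
            B=rng.standard_normal((n, k)) * 0.3,
            b=rng.standard_normal(n) * 0.1,
            C=rng.standard_normal((p, n)) * 0.3,
            d_out=rng.standard_normal(p) * 0.1,
            tau=10,
        )
        u = rng.standard_normal((k, T, C))
        y = rng.standard_normal((p, T, C))
        _, _, grads = _loss_and_grads(params, u, y)
        eps = 1e-6
        for name in ("A", "B", "b", "C", "d_out"):
            w = getattr(params, name)
            flat_idx = [tuple(i) for i in np.ndindex(w.shape)][:: max(w.size // 6, 1)]
            for idx in flat_idx:
                orig = w[idx]
                w[idx] = orig + eps
                lp, _, _ = _loss_and_grads(params, u, y)
                w[idx] = orig - eps
                lm, _, _ = _loss_and_grads(params, u, y)
                w[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[name][idx] == pytest.approx(num, rel=1e-5, abs=1e-10)


class TestNMSE:
    def test_invariant_to_target_scale(self, rng):
        y = rng.standard_normal((3, 100, 2))
        t = rng.standard_normal((3, 100, 2))
        assert _nmse(5 * y, 5 * t) == pytest.approx(_nmse(y, t))

    def test_success_threshold_equals_r2(self, rng):
        t = rng.standard_normal((2, 500, 1))
        noise = rng.standard_normal(t.shape)
        noise *= np.sqrt(0.009 * np.var(t) / np.var(noise))
        assert _nmse(t + noise, t) < 0.01  # i.e. R^2 > 0.99


class TestSimulate:
    def test_zero_network_stays_silent(self):
        params = zero_params()
        rec = simulate(params, InputProtocol(), 1, total_steps=500)
        np.testing.assert_array_equal(rec.firing, 0)
        np.testing.assert_array_equal(rec.outputs, 0)

    def test_deterministic_given_seed(self, mini_network):
        params, proto, spec = mini_network
        a = simulate(params, proto, 1, total_steps=1200, seed=3)
        b = simulate(params, proto, 1, total_steps=1200, seed=3)
        np.testing.assert_array_equal(a.firing, b.firing)

    def test_outputs_track_readout_invariant(self, mini_network):
        params, proto, spec = mini_network
        rec = simulate(params, proto, 1, total_steps=1500)
        np.testing.assert_allclose(
            rec.outputs, readout(params, rec.firing), atol=1e-12
        )


class TestTrainedNetwork:
    """Behavioral checks on the small trained fixture network."""

    def test_converged_to_oscillation(self, mini_network):
        params, proto, spec = mini_network
        assert mini_network.history["final_nmse"] < 0.05

    def test_output_period_matches_target(self, mini_network):
        """Fundamental period of the output matches the commanded speed
        within 2% (autocorrelation check)."""
        params, proto, spec = mini_network
        for c in range(1, spec.n_speeds + 1):
            rec = simulate(params, proto, c, total_steps=2000, off_step=2000)
            tail = rec.outputs[:, 1000:]
            period = fundamental_period(tail, dt=params.dt)
            assert period == pytest.approx(spec.period_ms(c - 1), rel=0.02)

    def test_outputs_decay_after_input_off(self, mini_network):
        params, proto, spec = mini_network
        rec = simulate(params, proto, 1, total_steps=2000, off_step=1200)
        on_norm = np.linalg.norm(rec.outputs[:, 900:1200]) / np.sqrt(300)
        tail_norm = np.linalg.norm(rec.outputs[:, -100:]) / np.sqrt(100)
        assert tail_norm < 0.2 * on_norm

    def test_steady_cycle_extraction_is_periodic(self, mini_network):
        params, proto, spec = mini_network
        rec = simulate(params, proto, 1, total_steps=2000)
        cyc = extract_steady_cycle(rec, spec.period_ms(0))
        assert cyc.shape[1] == pytest.approx(spec.period_ms(0) / params.dt, abs=1)
        # start and end of one steady cycle nearly coincide
        gap = np.linalg.norm(cyc[:, 0] - cyc[:, -1])
        scale = np.linalg.norm(cyc - cyc.mean(axis=1, keepdims=True), axis=0).mean()
        assert gap < 0.35 * scale

    def test_training_divergence_raises(self, muscle_factors):
        cfg = TrainConfig(max_iterations=10, learning_rate=1e200, clip_norm=1e300,
                          total_steps=600)
        with pytest.raises(FloatingPointError):
            from tanglekit.rnn import train
            train(muscle_factors, InputProtocol(), cfg, seed=0, n_units=20)
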