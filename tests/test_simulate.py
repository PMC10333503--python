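"""Integrate-and-fire dynamics: closed forms, sum semantics, noise statistics."""

import numpy as np
import pytest

from spikerls import _kernels
from spikerls.network import (NetworkConfig, NoiseSpec, build_network,
                              build_plastic_graph, build_static_graph)
from spikerls.simulate import (LIFCell, Simulator, synaptic_current_decomposition)


def make_sim(n=32, sigma=0.0, k=0, x_bal=0.5, stim=False, **kw):
    cfg = NetworkConfig(n_neurons=n, k_static=k, n_plastic=min(8, n - 1),
                        sigma=sigma, x_bal_e=x_bal, x_bal_i=x_bal,
                        plastic_init_scale=0.0, **kw)
    static, plastic, stimulus, noise = build_network(cfg)
    return Simulator(cfg, static, plastic, stimulus if stim else None, noise)


class TestSubthreshold:
    def test_below_threshold_drive_relaxes_exponentially_no_spikes(self):
        mu = 0.6
        sim = make_sim(x_bal=mu)
        state = sim.init_state()
        state.v[:] = 0.0
        v_hist = []
        for _ in range(3000):
            spiked = sim.step(state)
            assert spiked.size == 0
            v_hist.append(state.v[0])
        # exact propagator: V(t) = mu (1 - e^{-t/tau_m}) from V=0
        t = np.arange(1, 3001) * sim.dt
        expected = mu * (1.0 - np.exp(-t / sim.config.tau_m))
        assert np.allclose(v_hist, expected, atol=1e-10)

    def test_zero_input_decays_monotonically_to_rest(self):
        sim = make_sim(x_bal=0.0)
        state = sim.init_state()
        state.v[:] = 0.9
        prev = state.v.copy()
        for _ in range(500):
            sim.step(state)
            assert np.all(state.v <= prev + 1e-15)
            prev = state.v.copy()
        assert np.all(np.abs(state.v) < 1e-2)


class TestSpiking:
    def test_noiseless_isi_matches_closed_form(self):
        mu = 2.0
        sim = make_sim(n=2, x_bal=mu)
        res = sim.run_trial(500.0)
        isis = np.diff(res.raster.times[res.raster.neurons == 0])
        expected = sim.config.tau_ref + sim.config.tau_m * np.log(
            (mu - sim.config.v_reset) / (mu - sim.config.v_threshold))
        assert isis.size > 10
        assert np.all(np.abs(isis - expected) <= sim.dt + 1e-9)

    def test_voltage_never_exceeds_threshold_after_step(self):
        sim = make_sim(n=64, sigma=0.2, x_bal=1.0)
        state = sim.init_state(7)
        for _ in range(2000):
            sim.step(state)
            assert np.all(state.v <= sim.config.v_threshold)

    def test_refractory_clamps_voltage_at_reset(self):
        mu = 3.0
        sim = make_sim(n=2, x_bal=mu)
        state = sim.init_state()
        spike_step = None
        for k in range(5000):
            spiked = sim.step(state)
            if spike_step is None and 0 in spiked:
                spike_step = k
            elif spike_step is not None and k <= spike_step + int(sim.config.tau_ref / sim.dt) - 1:
                assert state.v[0] == sim.config.v_reset
            elif spike_step is not None:
                break


class TestSumSemantics:
    def test_common_target_receives_exact_sum_of_weights(self):
        # two presynaptic neurons spike into one target in the same step
        out_ptr = np.array([0, 1, 2, 2], dtype=np.int64)
        out_tgt = np.array([2, 2], dtype=np.int64)
        out_w = np.array([0.3, -0.45])
        x = np.zeros(3)
        _kernels.propagate_spikes_static(np.array([0, 1]), out_ptr, out_tgt, out_w, x)
        assert x[2] == 0.3 + (-0.45)

    def test_processing_order_does_not_change_result(self, rng):
        n = 200
        cfg = NetworkConfig(n_neurons=n, k_static=50, n_plastic=4, seed_graph=3)
        g = build_static_graph(cfg)
        spiked = rng.choice(n, size=40, replace=False).astype(np.int64)
        x1, x2 = np.zeros(n), np.zeros(n)
        _kernels.propagate_spikes_static(spiked, g.out_ptr, g.out_tgt, g.out_w, x1)
        _kernels.propagate_spikes_static(spiked[::-1].copy(), g.out_ptr, g.out_tgt,
                                         g.out_w, x2)
        assert np.allclose(x1, x2, atol=1e-12)


class TestSynapticCurrent:
    def test_decomposition_matches_running_current(self):
        cfg = NetworkConfig(n_neurons=64, k_static=0, n_plastic=16, sigma=0.2,
                            x_bal_e=1.0, x_bal_i=1.0)
        static, plastic, stim, noise = build_network(cfg)
        sim = Simulator(cfg, static, plastic, stim, noise)
        res = sim.run_trial(200.0, noise_seed=5)
        u, R = synaptic_current_decomposition(res.state, plastic)
        assert np.allclose(u, res.state.u_plastic, rtol=1e-5, atol=1e-12)
        assert R.shape == (64, 16)

    def test_zero_traces_give_zero_current(self):
        cfg = NetworkConfig(n_neurons=8, n_plastic=3)
        plastic = build_plastic_graph(8, 3, seed=1)
        sim = make_sim(n=8)
        state = sim.init_state()
        u, _ = synaptic_current_decomposition(state, plastic)
        assert np.all(u == 0)

    def test_single_nonzero_trace_isolates_one_weight(self):
        plastic = build_plastic_graph(8, 3, seed=1)
        sim = make_sim(n=8)
        state = sim.init_state()
        j = plastic.pre_idx[0, 1]
        state.r_trace[j] = 2.5
        u, _ = synaptic_current_decomposition(state, plastic)
        contributions = np.where(plastic.pre_idx == j, plastic.weights, 0.0).sum(axis=1)
        assert np.allclose(u, 2.5 * contributions)

    def test_doubling_weights_doubles_current(self):
        cfg = NetworkConfig(n_neurons=64, k_static=0, n_plastic=16, sigma=0.2,
                            x_bal_e=1.0, x_bal_i=1.0, plastic_init_scale=1.0)
        static, plastic, stim, noise = build_network(cfg)
        sim = Simulator(cfg, static, plastic, stim, noise)
        res = sim.run_trial(100.0, noise_seed=3)
        u1, _ = synaptic_current_decomposition(res.state, plastic)
        plastic.weights *= 2.0
        u2, _ = synaptic_current_decomposition(res.state, plastic)
        assert np.allclose(u2, 2.0 * u1)

    def test_spike_trace_integral_is_one_per_spike(self):
        # one forced spike; the unit-area filter trace integrates to 1
        sim = make_sim(n=2, x_bal=0.0)
        state = sim.init_state()
        state.x_trace[0] = 1.0          # as left by a spike
        integral = 0.0
        for _ in range(20000):
            sim.step(state)
            integral += state.r_trace[0] * sim.dt
        assert np.isclose(integral, 1.0, rtol=1e-3)


class TestNoise:
    def test_stationary_variance_matches_ou_formula(self):
        sigma = 0.05
        sim = make_sim(n=256, sigma=sigma, x_bal=0.0)
        state = sim.init_state(11)
        for _ in range(2000):            # discard transient (~20 tau_m)
            sim.step(state)
        acc, acc2, count = 0.0, 0.0, 0
        for _ in range(20_000):
            sim.step(state)
            acc += state.v.sum()
            acc2 += (state.v ** 2).sum()
            count += state.v.size
        var = acc2 / count - (acc / count) ** 2
        expected = sigma ** 2 * sim.config.tau_m / 2.0
        assert abs(var - expected) / expected < 0.05

    def test_sigma_zero_is_bit_reproducible(self):
        r1 = make_sim(n=16, x_bal=1.5).run_trial(200.0)
        r2 = make_sim(n=16, x_bal=1.5).run_trial(200.0)
        assert np.array_equal(r1.raster.times, r2.raster.times)
        assert np.array_equal(r1.raster.neurons, r2.raster.neurons)

    def test_same_noise_seed_identical_rasters(self):
        r1 = make_sim(n=32, sigma=0.2, x_bal=1.0).run_trial(300.0, noise_seed=9)
        r2 = make_sim(n=32, sigma=0.2, x_bal=1.0).run_trial(300.0, noise_seed=9)
        assert np.array_equal(r1.raster.times, r2.raster.times)
        assert np.array_equal(r1.raster.neurons, r2.raster.neurons)


class TestTrialMechanics:
    def test_zero_window_raster_is_empty(self):
        sim = make_sim(n=4, x_bal=2.0)
        res = sim.run_trial(300.0)
        assert len(res.raster.in_window(100.0, 100.0)) == 0

    def test_trial_shorter_than_stimulus_rejected(self):
        sim = make_sim(n=4, stim=True)
        with pytest.raises(ValueError):
            sim.run_trial(40.0)

    def test_dense_recording_budget_enforced(self):
        sim = make_sim(n=16, x_bal=1.5)
        sim.DENSE_RECORD_BUDGET = 100
        with pytest.raises(MemoryError, match="downsampl"):
            sim.run_trial(500.0, record_u=True, record_every=1)

    def test_non_finite_state_error_names_variable(self):
        sim = make_sim(n=4)
        state = sim.init_state()
        state.v[2] = np.nan
        with pytest.raises(FloatingPointError, match="'v'.*neuron 2"):
            sim._assert_finite(state)

    def test_raster_times_non_decreasing_ids_in_range(self):
        sim = make_sim(n=32, sigma=0.3, x_bal=1.0)
        res = sim.run_trial(300.0, noise_seed=2)
        assert np.all(np.diff(res.raster.times) >= 0)
        assert res.raster.neurons.min() >= 0
        assert res.raster.neurons.max() < 32


class TestCellModelPlugin:
    def test_custom_cell_model_is_honoured(self):
        class FastLIF(LIFCell):
            pass

        cell = FastLIF(tau_m=5.0, v_threshold=0.8)
        cfg = NetworkConfig(n_neurons=4, n_plastic=2, sigma=0.0,
                            x_bal_e=2.0, x_bal_i=2.0, plastic_init_scale=0.0)
        static, plastic, stim, noise = build_network(cfg)
        sim = Simulator(cfg, static, plastic, None, noise, cell_model=cell)
        res = sim.run_trial(200.0)
        isis = np.diff(res.raster.times[res.raster.neurons == 0])
        expected = cell.tau_ref + 5.0 * np.log(2.0 / (2.0 - 0.8))
        assert np.all(np.abs(isis - expected) <= sim.dt + 1e-9)
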