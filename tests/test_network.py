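import numpy as np
import pytest

import critsig as cs
from critsig.network import (BrunelParams, NoiseDriveSpec, StimulusProtocol,
                             build_network, firing_rate, run_trials, simulate)
from critsig.types import DegenerateNetworkError, Raster
from critsig.walks import CoinFlipParams, simulate_coin_flip_walk


class TestTopology:
    def test_exact_in_degrees(self, small_network):
        params, conn = small_network
        n_e = params.in_degree_exc
        n_i = params.in_degree_inh
        assert np.all(conn.exc.sum(axis=1) == n_e)
        assert np.all(conn.inh.sum(axis=1) == n_i)

    def test_thousand_neuron_default_has_1e5_connections(self):
        params = BrunelParams(n_neurons=1000)
        conn = build_network(params, seed=0)
        assert conn.n_connections == 100_000

    def test_no_self_connections(self, small_network):
        _, conn = small_network
        assert conn.exc.diagonal().sum() == 0
        assert conn.inh.diagonal().sum() == 0

    def test_inhibitory_weights_scale_with_g(self, small_network):
        params, conn = small_network
        w = conn.weight_matrix(params.j_eff, 4.0)
        inh_cols = w[:, params.n_excitatory:]
        assert inh_cols.min() == pytest.approx(-4.0 * params.j_eff)
        exc_cols = w[:, :params.n_excitatory]
        assert exc_cols.max() == pytest.approx(params.j_eff)

    def test_zero_density_is_empty(self):
        conn = build_network(BrunelParams(n_neurons=50,
                                          connection_density=0.0), 0)
        assert conn.n_connections == 0

    def test_degenerate_density_rejected(self):
        with pytest.raises(DegenerateNetworkError):
            build_network(BrunelParams(n_neurons=5,
                                       connection_density=0.01), 0)

    def test_same_seed_same_topology(self):
        p = BrunelParams(n_neurons=100)
        a = build_network(p, seed=3)
        b = build_network(p, seed=3)
        assert np.array_equal(a.exc, b.exc) and np.array_equal(a.inh, b.inh)


class TestDynamics:
    def test_silent_network_stays_silent(self, small_network):
        params, conn = small_network
        raster = simulate(conn, params, 40, seed=3)
        assert raster.spikes.sum() == 0

    def test_low_g_pulse_ignites_sustained_activity(self, small_network):
        params, conn = small_network
        p = params.with_g(1.5)
        act = run_trials(conn, p, 40, stim_magnitudes=[128] * 5, t_stim=1,
                         seed=4)
        late = act[:, -10:].mean()
        assert late > 0.2 * p.n_neurons

    def test_high_g_pulse_is_extinguished(self, small_network):
        params, conn = small_network
        p = params.with_g(6.0)
        act = run_trials(conn, p, 40, stim_magnitudes=[128] * 5, t_stim=1,
                         seed=4)
        assert act[:, 10:].sum() == 0

    def test_stimulus_larger_than_network_rejected(self, small_network):
        params, conn = small_network
        with pytest.raises(ValueError):
            run_trials(conn, params, 20, stim_magnitudes=[params.n_neurons + 1])

    def test_firing_rate_examples(self):
        assert firing_rate(Raster(spikes=np.zeros((4, 6)))) == 0.0
        assert firing_rate(Raster(spikes=np.ones((4, 6)))) == 1.0

    def test_rate_transition_from_active_to_inactive(self, small_network):
        params, conn = small_network
        rates = []
        for g in (1.5, 3.0, 5.0):
            p = params.with_g(g)
            act = run_trials(conn, p, 50,
                             stim_magnitudes=[int(0.32 * p.n_neurons)] * 10,
                             t_stim=1, seed=11)
            rates.append(act[:, 1:].mean() / p.n_neurons)
        assert rates[0] > 10 * rates[2]
        assert rates[0] > rates[1] > rates[2]

    def test_determinism_given_seed(self, small_network):
        params, conn = small_network
        a = run_trials(conn, params, 30, stim_magnitudes=[64], seed=9)
        b = run_trials(conn, params, 30, stim_magnitudes=[64], seed=9)
        assert np.array_equal(a, b)


class TestNoiseDrive:
    def test_disconnected_correlated_drive_reproduces_counts(self):
        trace = simulate_coin_flip_walk(CoinFlipParams(n_flips=60), seed=2)
        noise = NoiseDriveSpec(mode="correlated", n_driven=64, gain=1.0,
                               drive_trace=trace)
        params = BrunelParams(n_neurons=64, connection_density=0.0)
        act = run_trials(None, params, 60, noise=noise, seed=5)
        k = np.minimum(trace.values[:60], 64)
        assert np.array_equal(act[0], k)

    def test_uncorrelated_noise_rate_matches_p_spont(self):
        params = BrunelParams(n_neurons=200, connection_density=0.0)
        noise = NoiseDriveSpec(mode="uncorrelated", p_spont=0.05)
        act = run_trials(None, params, 400, noise=noise, seed=6)
        rate = act.mean() / params.n_neurons
        assert rate == pytest.approx(0.05, rel=0.1)

    def test_protocol_levels_are_eighths_of_n(self):
        levels = StimulusProtocol().magnitudes(1000)
        assert levels.tolist() == [0, 125, 250, 375, 500, 625, 750, 875]

    def test_raster_and_counts_agree(self, small_network):
        params, conn = small_network
        act, rasters = run_trials(conn, params.with_g(2.0), 30,
                                  stim_magnitudes=[100, 50], t_stim=1,
                                  seed=13, record="raster")
        assert np.array_equal(rasters.sum(axis=1), act)
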