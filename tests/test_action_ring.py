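import numpy as np
import pytest

from snplast.action_ring import (
    ActionLayerParams,
    ActionLayerState,
    build_lateral_weights,
    epsp_kernel,
    escape_rate,
    estimate_rates,
    membrane_potentials,
    preferred_directions,
    rate_kernel,
    sample_action_spikes,
    update_membrane,
)

P = ActionLayerParams()


class TestDirections:
    def test_ring_geometry(self):
        d = preferred_directions(P)
        assert d.shape == (40, 2)
        assert np.allclose(np.linalg.norm(d, axis=1), P.a0)
        assert np.allclose(d.sum(axis=0), 0.0, atol=1e-14)
        # theta_N = 2*pi -> a_N = a0*(0, 1)
        assert np.allclose(d[-1], (0.0, P.a0), atol=1e-15)

    def test_antipodal_pairs_cancel(self):
        d = preferred_directions(P)
        assert np.allclose(d, -np.roll(d, 20, axis=0), atol=1e-15)


class TestLateralWeights:
    def test_symmetric_with_inhibitory_diagonal(self):
        w = build_lateral_weights(P)
        assert np.allclose(w, w.T)
        assert np.allclose(np.diag(w), P.w_minus / P.n_actions)  # -7.5

    def test_similar_excite_dissimilar_inhibit(self):
        w = build_lateral_weights(P)
        near = w[0, 1]
        far = w[0, 20]
        assert near > far
        assert near > 0 > far

    def test_raw_profile_available(self):
        w = build_lateral_weights(P, normalised=False)
        # the literal constants put the raw near-neighbour weight at
        # w_+/N * exp(psi*cos(2pi/N)) ~ 1e9
        assert w[0, 1] > 1e8


class TestMembrane:
    def test_silent_network_at_rest(self):
        s = ActionLayerState(P)
        u = update_membrane(
            s, np.zeros(121, bool), np.zeros(40, bool), np.full((121, 40), 2.0),
            build_lateral_weights(P), 1.0,
        )
        assert np.allclose(u, 0.0)

    def test_epsp_peak_amplitude(self):
        """A single spike through weight 2 peaks at ~1.26 mV at the kernel's
        analytic maximum t* = tau_m*tau_s*ln(tau_m/tau_s)/(tau_m-tau_s)."""
        tstar = P.tau_m * P.tau_s * np.log(P.tau_m / P.tau_s) / (P.tau_m - P.tau_s)
        peak = 2.0 * epsp_kernel(tstar, P)
        assert peak == pytest.approx(1.2599, abs=1e-3)
        # dense scan confirms t* is the maximum
        tt = np.linspace(0, 100, 100_001)
        assert np.max(2.0 * epsp_kernel(tt, P)) <= peak + 1e-9

    def test_online_accumulator_matches_kernel(self):
        """Stepping the accumulators reproduces eps(k*dt) exactly."""
        s = ActionLayerState(P)
        w = np.zeros((1, 40))
        w[0, 0] = 2.0
        lat = build_lateral_weights(P)
        pre = np.array([True])
        u = update_membrane(s, pre, np.zeros(40, bool), w, lat, 1.0)
        assert u[0] == pytest.approx(0.0)  # eps(0) = 0
        vals = [u[0]]
        for _ in range(20):
            u = update_membrane(s, np.array([False]), np.zeros(40, bool), w, lat, 1.0)
            vals.append(u[0])
        expect = 2.0 * epsp_kernel(np.arange(21.0), P)
        assert np.allclose(vals, expect, rtol=1e-12)

    def test_refractory_equals_chi_at_own_spike(self):
        s = ActionLayerState(P)
        s.last_spike[:] = s.t  # just spiked, no input
        assert np.allclose(membrane_potentials(s), P.chi)


class TestEscapeRate:
    @pytest.mark.parametrize(
        "u, expected",
        [
            (16.0, 60.0),
            (0.0, 60.0 * np.exp(-8.0)),
            (18.0, 60.0 * np.e),
        ],
    )
    def test_exponential_escape(self, u, expected):
        assert escape_rate(u, P) == pytest.approx(expected)

    def test_spike_resets_accumulators_and_clock(self):
        s = ActionLayerState(P)
        s.ff_m[:] = 5.0
        s.ff_s[:] = 1.0
        s.t = 10.0
        spikes = sample_action_spikes(s, np.full(40, 100.0), 1.0, np.random.default_rng(0))
        assert spikes.all()  # p clipped at 1 for huge u
        assert np.all(s.ff_m == 0.0) and np.all(s.last_spike == 10.0)


class TestRateEstimate:
    def test_no_spikes_zero_rate(self):
        s = ActionLayerState(P)
        rho = estimate_rates(s, np.zeros(40), 1.0)
        assert np.allclose(rho, 0.0)

    def test_single_spike_integrates_to_one(self):
        s = ActionLayerState(P)
        spikes = np.zeros(40)
        spikes[0] = 1.0
        total = estimate_rates(s, spikes, 1.0)[0]
        for _ in range(5000):
            total += estimate_rates(s, np.zeros(40), 1.0)[0]
        assert total * 1.0 == pytest.approx(1.0, rel=1e-3)  # integral of gamma

    def test_periodic_train_converges_to_rate(self):
        s = ActionLayerState(P)
        period = 10  # one spike per 10 ms -> 0.1 spikes/ms
        vals = []
        for step in range(4000):
            spk = np.zeros(40)
            if step % period == 0:
                spk[0] = 1.0
            vals.append(estimate_rates(s, spk, 1.0)[0])
        assert np.mean(vals[1000:]) == pytest.approx(0.1, rel=2e-2)

    def test_online_filter_matches_direct_convolution(self, rng):
        """1 s random raster: online accumulators equal the explicit sum of
        gamma over the full spike history to high precision."""
        s = ActionLayerState(P)
        spikes = rng.random((1000, 40)) < 0.05
        hist = []
        online = np.empty((1000, 40))
        for t, spk in enumerate(spikes):
            online[t] = estimate_rates(s, spk.astype(float), 1.0)
            hist.append(spk)
        times = np.arange(1000.0)
        direct = np.zeros(40)
        t_now = 999.0
        for t, spk in zip(times, hist):
            direct += spk * rate_kernel(t_now - t, P)
        assert np.allclose(online[-1], direct, rtol=1e-9, atol=1e-15)


def test_lateral_connectivity_sharpens_direction_tuning(network):
    """Winner-take-all: with lateral weights installed, sustained uniform
    drive concentrates spiking on fewer directions (lower circular variance
    of the population vector of spike counts) than without them."""
    from snplast.place_cells import place_rates, sample_place_spikes

    def run(lateral_on, seed):
        rng = np.random.default_rng(seed)
        s = ActionLayerState(P)
        lat = network.lateral if lateral_on else np.zeros((40, 40))
        w = np.full((121, 40), 2.0)
        prev = np.zeros(40, bool)
        counts = np.zeros(40)
        x = np.array([0.5, 0.5])
        for _ in range(500):
            pre = sample_place_spikes(place_rates(x, network.cells), 1.0, rng)
            u = update_membrane(s, pre, prev, w, lat, 1.0)
            prev = sample_action_spikes(s, u, 1.0, rng)
            counts += prev
        th = 2 * np.pi * np.arange(1, 41) / 40
        R = np.abs(np.sum(counts * np.exp(1j * th))) / counts.sum()
        return 1.0 - R  # circular variance

    on = np.mean([run(True, s) for s in range(3)])
    off = np.mean([run(False, s) for s in range(3)])
    assert on < off
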