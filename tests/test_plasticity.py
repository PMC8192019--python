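import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snplast.plasticity import (
    PlasticityParams,
    PlasticityState,
    deliver_dopamine,
    init_weights,
    step_plasticity,
    stdp_window,
)


class TestWindow:
    def test_unit_at_coincidence(self):
        assert stdp_window(0.0) == 1.0

    def test_one_tau_decay(self):
        assert stdp_window(10.0, tau=10.0) == pytest.approx(np.exp(-1))
        assert stdp_window(-10.0, tau=10.0) == pytest.approx(np.exp(-1))

    @given(st.floats(-100, 100))
    def test_symmetric_positive_bounded(self, dt):
        w = stdp_window(dt)
        assert 0.0 < w <= 1.0
        assert w == stdp_window(-dt)


def _double_sum_oracle(pre_times, post_times, tau=10.0):
    """Explicit all-pairs sum of W(t_post - t_pre) for one synapse."""
    total = 0.0
    for tp in pre_times:
        for tq in post_times:
            total += np.exp(-abs(tq - tp) / tau)
    return total


class TestCoincidenceOracle:
    def test_trace_mass_equals_double_sum_on_random_rasters(self):
        """500 ms of random spikes on a 5x3 synapse block: the online
        trace-based coincidence mass accumulated over the trial equals the
        explicit pairwise sum to 1e-9 relative error."""
        rng = np.random.default_rng(21)
        n_pre, n_post, steps = 5, 3, 500
        pre = rng.random((steps, n_pre)) < 0.06
        post = rng.random((steps, n_post)) < 0.04
        pp = PlasticityParams(eta_ach=0.0, eta_da=1.0, tau_e=np.inf)
        state = PlasticityState(n_pre, n_post)
        w = np.full((n_pre, n_post), 2.0)
        for t in range(steps):
            step_plasticity(state, pre[t], post[t], w, pp, 1.0)
        # with tau_e -> inf the eligibility is the undecayed total mass
        for i in range(n_pre):
            for j in range(n_post):
                expect = _double_sum_oracle(
                    np.nonzero(pre[:, i])[0], np.nonzero(post[:, j])[0]
                )
                assert state.eligibility[i, j] == pytest.approx(expect, rel=1e-9)

    def test_single_pair_depression(self):
        """Pre at t, post at t+5 ms, eta_ACh = 1e-3: dw = -1e-3*e^{-0.5}."""
        pp = PlasticityParams(eta_ach=1e-3, eta_da=0.0)
        state = PlasticityState(1, 1)
        w = np.full((1, 1), 2.0)
        step_plasticity(state, np.array([True]), np.array([False]), w, pp, 1.0)
        for _ in range(4):
            step_plasticity(state, np.array([False]), np.array([False]), w, pp, 1.0)
        step_plasticity(state, np.array([False]), np.array([True]), w, pp, 1.0)
        assert w[0, 0] - 2.0 == pytest.approx(-1e-3 * np.exp(-0.5), rel=1e-12)


class TestNeuromodulatorGating:
    def test_no_spikes_no_change(self):
        pp = PlasticityParams()
        state = PlasticityState(2, 2)
        state.pre_trace[:] = 1.0
        w = np.full((2, 2), 2.0)
        step_plasticity(state, np.zeros(2, bool), np.zeros(2, bool), w, pp, 1.0)
        assert np.all(w == 2.0)
        assert np.all(state.pre_trace == np.exp(-0.1))  # decayed only

    def test_zero_ach_accumulates_eligibility_without_depression(self):
        """Full cholinergic silencing: weights frozen during exploration but
        the eligibility trace still builds for a later dopamine update."""
        pp = PlasticityParams(eta_ach=0.0)
        state = PlasticityState(2, 2)
        w = np.full((2, 2), 2.0)
        rng = np.random.default_rng(2)
        for _ in range(100):
            step_plasticity(state, rng.random(2) < 0.3, rng.random(2) < 0.3, w, pp, 1.0)
        assert np.all(w == 2.0)
        assert state.eligibility.sum() > 0.0

    def test_ach_updates_depress_da_updates_potentiate(self):
        rng = np.random.default_rng(3)
        pp = PlasticityParams(eta_ach=1e-3, eta_da=1e-3)
        state = PlasticityState(3, 3)
        w = np.full((3, 3), 2.0)
        for _ in range(200):
            step_plasticity(state, rng.random(3) < 0.3, rng.random(3) < 0.3, w, pp, 1.0)
        assert np.all(w <= 2.0) and np.any(w < 2.0)
        before = w.copy()
        deliver_dopamine(state, w, pp)
        assert np.all(w >= before) and np.any(w > before)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            PlasticityParams(eta_ach=-1.0)


class TestDopamine:
    def test_empty_eligibility_changes_nothing(self):
        pp = PlasticityParams()
        state = PlasticityState(2, 2)
        w = np.full((2, 2), 2.0)
        deliver_dopamine(state, w, pp)
        assert np.all(w == 2.0)

    def test_retroactive_discount_at_one_tau_e(self):
        """A unit coincidence exactly tau_e = 2 s before the reward is read
        out as eta_DA * e^{-1}."""
        pp = PlasticityParams(eta_ach=0.0, eta_da=1e-3)
        state = PlasticityState(1, 1)
        w = np.full((1, 1), 2.0)
        state.eligibility[0, 0] = 1.0  # unit coincidence now
        for _ in range(2000):  # 2 s of decay
            step_plasticity(state, np.zeros(1, bool), np.zeros(1, bool), w, pp, 1.0)
        deliver_dopamine(state, w, pp)
        assert w[0, 0] - 2.0 == pytest.approx(1e-3 * np.exp(-1), rel=1e-9)
        assert np.all(state.eligibility == 0.0)

    def test_depression_converted_to_potentiation(self):
        """The sequence ACh-depression then prompt dopamine yields a net
        potentiation when eta_DA > eta_ACh (the rule's signature effect)."""
        pp = PlasticityParams(eta_ach=1e-4, eta_da=1e-3)
        state = PlasticityState(1, 1)
        w = np.full((1, 1), 2.0)
        step_plasticity(state, np.array([True]), np.array([True]), w, pp, 1.0)
        assert w[0, 0] < 2.0
        deliver_dopamine(state, w, pp)
        assert w[0, 0] > 2.0

    def test_double_delivery_rejected(self):
        pp = PlasticityParams()
        state = PlasticityState(1, 1)
        w = np.full((1, 1), 2.0)
        deliver_dopamine(state, w, pp)
        with pytest.raises(RuntimeError):
            deliver_dopamine(state, w, pp)


class TestBounds:
    def test_weights_stay_in_bounds_under_heavy_updates(self):
        rng = np.random.default_rng(4)
        pp = PlasticityParams(eta_ach=0.05, eta_da=0.5)
        state = PlasticityState(4, 4)
        w = init_weights(4, 4, None, pp)
        for k in range(300):
            step_plasticity(state, rng.random(4) < 0.5, rng.random(4) < 0.5, w, pp, 1.0)
            if k % 100 == 99:
                deliver_dopamine(state, w, pp)
                state.da_delivered = False
            assert np.all(w >= pp.w_min) and np.all(w <= pp.w_max)

    def test_init_weights(self):
        pp = PlasticityParams()
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        w = init_weights(2, 2, mask, pp)
        assert w[0, 0] == 0.0 and np.all(w[~mask] == 2.0)
        assert np.all(init_weights(2, 2, np.ones((2, 2), bool), pp) == 0.0)
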