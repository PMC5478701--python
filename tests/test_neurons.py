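"""Unit tests for the neuron dynamics primitives."""

import numpy as np
import pytest
from scipy.special import erf

from erbp.neurons import (
    ActivationParams,
    EncoderParams,
    LayerState,
    NeuronParams,
    activation_rate,
    encode_input,
    step_error_layer,
    step_two_compartment_layer,
)

DT = 0.1


def run_clamped(params, clamp, duration, seed=0):
    """Drive one neuron with a clamped mean synaptic current; return rate."""
    rng = np.random.default_rng(seed)
    st = LayerState.zeros(1)
    st.I[:] = clamp
    ff = DT * clamp / params.tau_syn
    n = int(duration / DT)
    count = 0
    for k in range(n):
        st, sp = step_two_compartment_layer(st, ff, 0.0, params, k * DT, DT, rng)
        count += int(sp[0])
    return count / (duration / 1000.0)


class TestTwoCompartmentLayer:
    def test_zero_input_is_fixed_point(self):
        params = NeuronParams(sigma_w=0.0)
        st = LayerState.zeros(4)
        for k in range(100):
            st, sp = step_two_compartment_layer(st, 0.0, 0.0, params, k * DT, DT)
            assert not sp.any()
        assert np.all(st.V == 0.0) and np.all(st.U == 0.0) and np.all(st.I == 0.0)

    def test_subthreshold_clamp_converges_to_I_over_gV(self):
        # V_ss = I / g_V: 0.05 nA over 1 nS is 50 mV, below the 100 mV
        # threshold, so the membrane settles without spiking
        params = NeuronParams(sigma_w=0.0)
        st = LayerState.zeros(1)
        st.I[:] = 0.05
        ff = DT * 0.05 / params.tau_syn
        for k in range(200):  # 20 ms >> tau_m = 1 ms
            st, sp = step_two_compartment_layer(st, ff, 0.0, params, k * DT, DT)
            assert not sp.any()
        assert st.V[0] == pytest.approx(50.0, rel=1e-3)

    def test_suprathreshold_rate_matches_deterministic_period(self):
        # noiseless ISI = tau_refr + tau_m ln(Vss/(Vss - V_T)); at twice
        # threshold the logarithm is ln 2
        params = NeuronParams(sigma_w=0.0)
        rate = run_clamped(params, 0.2, duration=10000.0)
        isi = params.tau_refr + params.tau_m * np.log(2.0)
        assert rate == pytest.approx(1000.0 / isi, rel=0.02)
        # the analytic activation is the refractory-bounded ceiling
        ceiling = activation_rate(100.0, ActivationParams(5.0, params.tau_refr))
        assert rate <= ceiling

    def test_refractory_holds_membrane_at_reset(self):
        params = NeuronParams(sigma_w=0.0)
        st = LayerState.zeros(1)
        st.I[:] = 0.3
        ff = DT * 0.3 / params.tau_syn
        spike_steps = []
        V_during_refr = []
        for k in range(2000):
            t = k * DT
            refractory = st.refr_until[0] > t
            st, sp = step_two_compartment_layer(st, ff, 0.0, params, t, DT)
            if refractory:
                V_during_refr.append(st.V[0])
            if sp[0]:
                spike_steps.append(t + DT)
        assert np.all(np.asarray(V_during_refr) == 0.0)
        isis = np.diff(spike_steps)
        assert isis.min() >= params.tau_refr

    def test_dendrite_never_couples_to_soma(self):
        # zeroing U at any time must not change V, I or spiking
        params = NeuronParams(sigma_w=0.0)
        rng = np.random.default_rng(5)
        ff_seq = rng.normal(0.003, 0.003, size=(300, 8))
        err_seq = rng.normal(0.0, 40.0, size=(300, 8))
        a, b = LayerState.zeros(8), LayerState.zeros(8)
        for k in range(300):
            a, sa = step_two_compartment_layer(a, ff_seq[k], err_seq[k], params, k * DT, DT)
            b, sb = step_two_compartment_layer(b, ff_seq[k], 0.0, params, k * DT, DT)
            if k == 150:
                a.U[:] = 0.0
            np.testing.assert_array_equal(sa, sb)
        np.testing.assert_allclose(a.V, b.V)
        np.testing.assert_allclose(a.I, b.I)

    def test_rejects_bad_arguments(self):
        params = NeuronParams()
        st = LayerState.zeros(3)
        with pytest.raises(ValueError):
            step_two_compartment_layer(st, np.zeros(4), 0.0, params, 0.0, DT)
        with pytest.raises(ValueError):
            step_two_compartment_layer(st, 0.0, 0.0, params, 0.0, -1.0)

    def test_fast_membrane_invariant_enforced(self):
        with pytest.raises(ValueError):
            NeuronParams(C=10.0)  # tau_m = 10 ms > tau_syn/2


class TestErrorLayer:
    def drive(self, pred, label, n_steps, w_L=0.09, n=1):
        params = NeuronParams()
        st = LayerState.zeros(n)
        pos_total = np.zeros(n, int)
        neg_total = np.zeros(n, int)
        for k in range(n_steps):
            st, pos, neg = step_error_layer(
                st, pred[k], label[k], w_L, params, DT
            )
            pos_total += pos
            neg_total += neg
        return st, pos_total, neg_total

    def test_identical_trains_keep_error_neurons_silent(self):
        # 10 s of identical prediction and label trains
        rng = np.random.default_rng(0)
        n_steps = 100000
        train = rng.random((n_steps, 3)) < 0.02
        _, pos, neg = self.drive(train, train, n_steps, n=3)
        assert pos.sum() == 0 and neg.sum() == 0

    def test_label_only_drives_negative_neuron(self):
        n_steps = 39000  # ~ 1000 label spikes at one per 39 steps
        pred = np.zeros((n_steps, 1), dtype=bool)
        label = np.zeros((n_steps, 1), dtype=bool)
        label[::39, 0] = True
        _, pos, neg = self.drive(pred, label, n_steps)
        assert pos.sum() == 0
        assert neg.sum() > 0

    def test_unmatched_spike_arithmetic(self):
        # each unmatched label spike moves the negative membrane by
        # w_L * q / C = 90 mV against a 100 mV threshold with subtractive
        # reset, so n spikes produce floor(0.9 n) error spikes
        for n_spikes in (2, 5, 11):
            n_steps = 39 * n_spikes
            pred = np.zeros((n_steps, 1), dtype=bool)
            label = np.zeros((n_steps, 1), dtype=bool)
            label[::39, 0] = True
            _, pos, neg = self.drive(pred, label, n_steps)
            assert neg.sum() == int(np.floor(0.9 * n_spikes))

    def test_membrane_floor_is_symmetric(self):
        params = NeuronParams()
        st = LayerState.zeros(1)
        pred = np.ones(1, dtype=bool)
        label = np.zeros(1, dtype=bool)
        for _ in range(10):  # drive the negative membrane hard downward
            st, _, _ = step_error_layer(st, pred, label, 0.09, params, DT)
        assert st.U[0] == -params.V_T_E

    def test_length_mismatch_rejected(self):
        st = LayerState.zeros(2)
        with pytest.raises(ValueError):
            step_error_layer(st, np.zeros(3, bool), np.zeros(2, bool),
                             0.09, NeuronParams(), DT)


class TestEncoder:
    def test_hazard_at_zero_intensity(self):
        # tau_refr^-1 exp(gamma) with the published input scale/offset
        params = EncoderParams(beta=0.5, gamma=-0.215, tau_refr=4.0)
        rng = np.random.default_rng(0)
        n, dur = 1, 10000.0
        last = np.full(n, -np.inf)
        count = 0
        for k in range(int(dur / DT)):
            sp = encode_input(np.zeros(n), last, params, k * DT, DT, rng)
            count += int(sp[0])
        hazard = np.exp(-0.215) / 4.0
        expected = 1000.0 / (4.0 + 1.0 / hazard)  # refractory-bounded rate
        assert count / (dur / 1000.0) == pytest.approx(expected, rel=0.05)

    def test_refractory_blocks_spiking(self):
        params = EncoderParams(beta=10.0, gamma=5.0, tau_refr=4.0)
        rng = np.random.default_rng(0)
        last = np.array([0.0])  # just spiked at t = 0
        for k in range(int(4.0 / DT) - 1):
            sp = encode_input(np.ones(1), last, params, (k + 1) * DT, DT, rng)
            assert not sp[0]

    def test_rate_monotone_in_intensity(self):
        params = EncoderParams()
        rng = np.random.default_rng(1)
        counts = np.zeros(2)
        last = np.full(2, -np.inf)
        for k in range(int(10000.0 / DT)):
            sp = encode_input(np.array([0.0, 1.0]), last, params, k * DT, DT, rng)
            counts += sp
        assert counts[1] > counts[0]

    def test_rejects_out_of_range_intensity(self):
        with pytest.raises(ValueError):
            encode_input(np.array([1.2]), np.zeros(1), EncoderParams(), 0.0,
                         DT, np.random.default_rng(0))


class TestActivationRate:
    def test_half_maximum_at_zero_mean(self):
        p = ActivationParams(sigma_OU=10.0, tau_refr=3.9)
        assert activation_rate(0.0, p) == pytest.approx(1000.0 / (2 * 3.9))

    def test_limits(self):
        p = ActivationParams(sigma_OU=10.0, tau_refr=3.9)
        assert activation_rate(1e4, p) == pytest.approx(1000.0 / 3.9, rel=1e-9)
        assert activation_rate(-1e4, p) == pytest.approx(0.0, abs=1e-9)

    def test_one_sigma_point_matches_erf(self):
        sigma = 7.0
        p = ActivationParams(sigma_OU=sigma, tau_refr=3.9)
        expected = (1000.0 / 3.9) * 0.5 * (1 + erf(1.0))
        assert activation_rate(sigma * np.sqrt(2.0), p) == pytest.approx(expected)
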