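"""Unit tests for the Izhikevich neuron: reset rule, fixed points,
tonic-spiking regime and step-size convergence."""
import numpy as np
import pytest

from emgspike.core_dynamics import (
    NeuronParams,
    NeuronState,
    REGULAR_SPIKING,
    resting_state,
    simulate_neuron,
    step_neuron,
)


def rhs(state, params, I=0.0):
    dV = 0.04 * state.V**2 + 5.0 * state.V + 140.0 - state.u + I
    du = params.a * (params.b * state.V - state.u)
    return dV, du


class TestStepNeuron:
    def test_subthreshold_start_does_not_spike(self):
        state = NeuronState(-65.0, -13.0)
        for dt in (0.1, 0.5, 1.0):
            _, spiked = step_neuron(state, REGULAR_SPIKING, I=0.0, dt=dt)
            assert not spiked

    def test_reset_rule_at_threshold(self):
        # entering the step at the 30 mV cut-off must reset to c and bump u by d
        state = NeuronState(30.0, -13.0)
        dt = 0.5
        new, spiked = step_neuron(state, REGULAR_SPIKING, I=0.0, dt=dt)
        assert spiked
        assert new.V == REGULAR_SPIKING.c
        # u gets its Euler increment plus the after-spike d
        drift = dt * REGULAR_SPIKING.a * (REGULAR_SPIKING.b * 30.0 - state.u)
        assert new.u == pytest.approx(state.u + drift + REGULAR_SPIKING.d)
        assert new.u == pytest.approx(state.u + 8.0, abs=0.25)

    def test_membrane_never_exceeds_peak_after_step(self, rng):
        state = NeuronState(-70.0, -14.0)
        for _ in range(2000):
            state, _ = step_neuron(state, REGULAR_SPIKING, I=rng.uniform(0, 30), dt=0.5)
            assert state.V <= REGULAR_SPIKING.v_peak

    @pytest.mark.parametrize("dt", [0.0, -0.5, 1.5])
    def test_invalid_dt_rejected(self, dt):
        with pytest.raises(ValueError, match="dt"):
            step_neuron(NeuronState(-70.0, -14.0), REGULAR_SPIKING, 0.0, dt)

    @pytest.mark.parametrize(
        "state,I",
        [
            (NeuronState(np.nan, -14.0), 0.0),
            (NeuronState(-70.0, np.inf), 0.0),
            (NeuronState(-70.0, -14.0), np.nan),
        ],
    )
    def test_nonfinite_inputs_rejected_with_name(self, state, I):
        with pytest.raises(ValueError, match="non-finite [Vu I]"):
            step_neuron(state, REGULAR_SPIKING, I, 0.5)


class TestRestingState:
    def test_rs_preset_matches_quadratic_oracle(self):
        # independent oracle: numpy root-finding on 0.04 V^2 + (5-b) V + 140
        roots = np.roots([0.04, 5.0 - 0.2, 140.0])
        assert sorted(np.round(roots, 6)) == [-70.0, -50.0]
        rest = resting_state(REGULAR_SPIKING)
        assert rest.V == pytest.approx(-70.0, abs=1e-9)
        assert rest.u == pytest.approx(-14.0, abs=1e-9)

    def test_b_zero_variant_closed_form(self):
        params = NeuronParams(b=0.0)
        rest = resting_state(params)
        expected = min(np.roots([0.04, 5.0, 140.0]))  # stable branch
        assert rest.V == pytest.approx(expected, abs=1e-9)
        assert rest.u == 0.0

    def test_fixed_point_residual(self):
        rest = resting_state(REGULAR_SPIKING)
        dV, du = rhs(rest, REGULAR_SPIKING)
        assert abs(dV) < 1e-9 and abs(du) < 1e-9

    def test_one_step_barely_moves(self):
        rest = resting_state(REGULAR_SPIKING)
        new, spiked = step_neuron(rest, REGULAR_SPIKING, I=0.0, dt=0.5)
        assert not spiked
        assert abs(new.V - rest.V) < 1e-9

    def test_no_real_root_raises(self):
        # b near 5 pushes the quadratic discriminant negative -> no intersection
        with pytest.raises(ValueError, match="no resting state"):
            resting_state(NeuronParams(b=2.0))

    def test_zero_input_convergence_from_nearby_state(self):
        state = NeuronState(-60.0, -12.0)
        for _ in range(4000):
            state, _ = step_neuron(state, REGULAR_SPIKING, I=0.0, dt=0.5)
        assert state.V == pytest.approx(-70.0, abs=1e-6)
        assert state.u == pytest.approx(-14.0, abs=1e-6)


class TestSimulateNeuron:
    def test_quiescent_at_zero_current(self):
        V, spikes = simulate_neuron(np.zeros(2000), REGULAR_SPIKING, dt=0.5)
        assert len(spikes) == 0
        assert np.all(V < 0)

    def test_empty_trace_gives_empty_outputs(self):
        V, spikes = simulate_neuron(np.empty(0), REGULAR_SPIKING)
        assert len(V) == 0 and len(spikes) == 0

    def test_tonic_spiking_with_adaptation(self):
        V, spikes = simulate_neuron(np.full(2000, 10.0), REGULAR_SPIKING, dt=0.5)
        assert len(spikes) >= 2
        isi = np.diff(spikes)
        # spike-frequency adaptation: ISIs non-decreasing (one-step slack)
        assert np.all(np.diff(isi) >= -0.5)
        assert np.all(np.diff(spikes) > 0)

    def test_dense_reference_agrees_on_regime(self):
        # dense-dt oracle: same spike count and matching adaptation plateau
        _, s_coarse = simulate_neuron(np.full(2000, 10.0), dt=0.5)
        _, s_dense = simulate_neuron(np.full(2000, 10.0), dt=0.01, sample_dt=0.5)
        assert abs(len(s_coarse) - len(s_dense)) <= 1
        plateau_c = np.diff(s_coarse)[-3:].mean()
        plateau_d = np.diff(s_dense)[-3:].mean()
        assert plateau_c == pytest.approx(plateau_d, rel=0.05)

    def test_spike_time_first_order_convergence(self):
        # halving dt roughly halves the spike-time shift (explicit Euler)
        def shift(dt):
            _, s1 = simulate_neuron(np.full(1000, 10.0), dt=dt, sample_dt=0.5)
            _, s2 = simulate_neuron(np.full(1000, 10.0), dt=dt / 2, sample_dt=0.5)
            n = min(len(s1), len(s2))
            return np.max(np.abs(s1[:n] - s2[:n]))

        s_coarse, s_fine = shift(0.25), shift(0.05)
        assert s_fine < s_coarse
        assert shift(0.02) < 1.0  # sub-ms stability at fine steps

    def test_trace_clipped_at_peak(self):
        V, spikes = simulate_neuron(np.full(2000, 10.0), dt=0.5)
        assert len(spikes) > 0
        assert V.max() == REGULAR_SPIKING.v_peak

    def test_noninteger_sample_ratio_rejected(self):
        with pytest.raises(ValueError, match="integer multiple"):
            simulate_neuron(np.zeros(10), dt=0.4, sample_dt=0.5)
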