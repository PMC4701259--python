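"""Sensory spiking layer: drive current, decoupling identity, lateral
inhibition and feature sampling."""
import numpy as np
import pytest

from emgspike.core_dynamics import REGULAR_SPIKING, resting_state, step_neuron
from emgspike.data import EMGRecording
from emgspike.sensory_network import (
    LateralCouplingParams,
    SensoryLayerState,
    drive_current,
    extract_spiking_features,
    run_layer,
    step_layer,
)
from emgspike.synapse_tm import FEATURE_PRESET, SynapseState, step_synapse

from conftest import make_noise_recording


class TestDriveCurrent:
    def test_zero_everything(self):
        assert drive_current(0.0, np.zeros(7), LateralCouplingParams()) == 0.0

    def test_feedforward_gain(self):
        # 50 uV at k = 2e6 -> dimensionless drive of 100
        I = drive_current(5e-5, np.empty(0), LateralCouplingParams())
        assert I == pytest.approx(100.0)

    def test_rectification(self):
        p = LateralCouplingParams()
        y = np.array([0.1, 0.2])
        assert drive_current(-3e-5, y, p) == drive_current(3e-5, y, p)

    def test_inhibitory_sign(self):
        p = LateralCouplingParams(w=0.5, g=60.0, inhibitory=True)
        assert drive_current(0.0, np.array([0.1]), p) == pytest.approx(-3.0)
        p_exc = LateralCouplingParams(w=0.5, g=60.0, inhibitory=False)
        assert drive_current(0.0, np.array([0.1]), p_exc) == pytest.approx(3.0)


class TestStepLayer:
    def test_channel_count_mismatch_rejected(self):
        state = SensoryLayerState.at_rest(8)
        with pytest.raises(ValueError, match="samples"):
            step_layer(state, np.zeros(5))

    def test_zero_input_stays_quiescent(self):
        state = SensoryLayerState.at_rest(4)
        for _ in range(500):
            state, spiked = step_layer(state, np.zeros(4))
            assert not spiked.any()
        assert np.all(state.y == 0.0)
        assert np.allclose(state.V, resting_state(REGULAR_SPIKING).V, atol=1e-6)

    def test_decoupled_layer_matches_scalar_chain_bitwise(self, rng):
        # w=0 layer must be bit-identical to per-channel scalar simulation
        rec = make_noise_recording(rng, n_channels=3, duration_s=0.4)
        coupling = LateralCouplingParams(w=0.0)
        state = SensoryLayerState.at_rest(3, coupling=coupling)
        dt = 0.5
        m = round(1000.0 / rec.sample_rate / dt)

        scalar_neurons = [resting_state(REGULAR_SPIKING) for _ in range(3)]
        scalar_syn = [SynapseState() for _ in range(3)]
        for j in range(rec.n_samples):
            for _ in range(m):
                emg = rec.data[:, j]
                state, _ = step_layer(state, emg, dt=dt)
                for c in range(3):
                    I = drive_current(emg[c], np.empty(0), coupling)
                    scalar_neurons[c], spk = step_neuron(
                        scalar_neurons[c], REGULAR_SPIKING, I, dt
                    )
                    scalar_syn[c] = step_synapse(
                        scalar_syn[c], FEATURE_PRESET, dt, spike=spk
                    )
        for c in range(3):
            assert state.V[c] == scalar_neurons[c].V
            assert state.u[c] == scalar_neurons[c].u
            assert state.y[c] == scalar_syn[c].y
            assert state.x[c] == scalar_syn[c].x

    def test_common_input_suppressed_by_inhibition(self, rng):
        # identical strong common signal on all channels: every neuron fires
        # less in inhibitory mode than isolated
        n = round(2.0 * 400)
        common = rng.standard_normal(n) * 2e-5
        rec = EMGRecording(400.0, np.tile(common, (8, 1)))
        _, counts_iso, _ = run_layer(
            rec, SensoryLayerState.at_rest(8, coupling=LateralCouplingParams(w=0.0))
        )
        _, counts_inh, _ = run_layer(
            rec, SensoryLayerState.at_rest(8, coupling=LateralCouplingParams())
        )
        assert counts_iso.min() > 0
        assert np.all(counts_inh < counts_iso)


class TestExtractSpikingFeatures:
    def test_row_count_one_second(self, rng):
        rec = make_noise_recording(rng, n_channels=2, duration_s=1.0)
        feats = extract_spiking_features(rec)
        assert len(feats) == 20  # floor(1000 ms / 50 ms)
        assert np.all(np.diff(feats.times_ms) == 50.0)

    def test_all_zero_recording_gives_zero_features(self):
        rec = EMGRecording(400.0, np.zeros((8, 400)))
        feats = extract_spiking_features(rec)
        assert np.all(feats.X == 0.0)

    def test_too_short_recording_warns_and_is_empty(self):
        rec = EMGRecording(400.0, np.zeros((2, 10)))
        with pytest.warns(UserWarning, match="shorter"):
            feats = extract_spiking_features(rec)
        assert len(feats) == 0

    def test_selective_channel_activity(self, rng):
        # drive only channel 3: its mean feature dominates all others
        n = 800
        data = np.zeros((8, n))
        data[3] = rng.standard_normal(n) * 6e-5
        rec = EMGRecording(400.0, data)
        feats = extract_spiking_features(rec, mode="inhibitory")
        means = feats.X.mean(axis=0)
        assert np.all(means[3] > np.delete(means, 3))

    def test_rectification_symmetry(self, rng):
        rec = make_noise_recording(rng, n_channels=2, duration_s=0.5)
        flipped = EMGRecording(rec.sample_rate, -rec.data, rec.labels)
        f1 = extract_spiking_features(rec)
        f2 = extract_spiking_features(flipped)
        assert np.array_equal(f1.X, f2.X)

    def test_determinism(self, rng):
        rec = make_noise_recording(rng, n_channels=2, duration_s=0.5)
        f1 = extract_spiking_features(rec)
        f2 = extract_spiking_features(rec)
        assert np.array_equal(f1.X, f2.X)
        assert np.array_equal(f1.labels, f2.labels)

    def test_w_zero_inhibitory_equals_isolated(self, rng):
        rec = make_noise_recording(rng, n_channels=4, duration_s=0.5)
        coupling = LateralCouplingParams(w=0.0)
        f_inh = extract_spiking_features(rec, mode="inhibitory", coupling=coupling)
        f_iso = extract_spiking_features(rec, mode="isolated")
        assert np.array_equal(f_inh.X, f_iso.X)

    def test_in_phase_component_suppressed_in_features(self, rng):
        # adding a common-mode signal inflates isolated features more than
        # inhibitory ones
        base = make_noise_recording(rng, n_channels=8, duration_s=2.0, amplitude=2e-5)
        common = rng.standard_normal(base.n_samples) * 2e-5
        with_cm = EMGRecording(400.0, base.data + common, base.labels)

        def total(rec, mode):
            return extract_spiking_features(rec, mode=mode).X.sum()

        gain_iso = total(with_cm, "isolated") - total(base, "isolated")
        gain_inh = total(with_cm, "inhibitory") - total(base, "inhibitory")
        assert gain_iso > gain_inh

    def test_labels_follow_sampling_instants(self):
        n = 400  # 1 s at 400 Hz
        labels = np.zeros(n, dtype=int)
        labels[200:] = 3  # switch at 500 ms
        rec = EMGRecording(400.0, np.zeros((2, n)), labels)
        feats = extract_spiking_features(rec)
        assert feats.labels[:10].tolist() == [0] * 10
        assert feats.labels[10:].tolist() == [3] * 10
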