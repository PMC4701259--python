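"""Spiking sensory layer: the sEMG feature extractor.

One Izhikevich neuron per sEMG channel acts as a virtual sensory neuron.
Its drive current is the sum of a virtual-stimulator term — the rectified
sEMG sample scaled by a gain k — and a synaptic term collecting the weighted
outputs of all the other sensory neurons:

    I = sum_i w * (-g) * y_i(t) + k * |EMG(t)|

With the lateral connections inhibitory (the default), mutual inhibition
suppresses background firing and the in-phase (common-mode) component shared
by closely spaced electrodes, which carries no pattern information.  Each
neuron's spikes drive its own Tsodyks-Markram synapse, whose active-resource
fraction y(t) is both the inhibitory signal broadcast to the other channels
and the classification feature, sampled every 50 ms.

The layer update is synchronous: every channel's drive uses the previous
step's y values, so the result is independent of channel ordering, and a
layer with w = 0 is bit-identical to independent single-neuron simulations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_dynamics import DEFAULT_DT, NeuronParams, REGULAR_SPIKING, resting_state
from .data import EMGRecording, FeatureMatrix
from .synapse_tm import FEATURE_PRESET, SynapseParams, decay_coefficients

__all__ = [
    "LateralCouplingParams",
    "SensoryLayerState",
    "drive_current",
    "step_layer",
    "extract_spiking_features",
]

#: Classifier sampling period (ms): features are read out every 50 ms.
FEATURE_PERIOD_MS = 50.0


@dataclass(frozen=True)
class LateralCouplingParams:
    """Coupling and input-gain parameters of the sensory layer.

    `w` is the lateral connection weight and `g` the output-current scaling
    magnitude; with `inhibitory` set (the default) the applied coefficient
    is -g.  `k` maps volts of rectified sEMG to model current units; the
    default 2e6 puts physiological-scale signals (tens of microvolts RMS)
    into the neurons' spiking range.
    """

    w: float = 0.5
    g: float = 60.0
    inhibitory: bool = True
    k: float = 2e6

    def __post_init__(self) -> None:
        if self.w < 0 or self.g < 0:
            raise ValueError("w and g must be non-negative")
        if not self.k > 0:
            raise ValueError("k must be positive")

    @property
    def signed_g(self) -> float:
        return -self.g if self.inhibitory else self.g


@dataclass
class SensoryLayerState:
    """Per-channel neuron and synapse state of the sensory layer."""

    V: np.ndarray
    u: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    u_f: np.ndarray
    neuron: NeuronParams = REGULAR_SPIKING
    synapse: SynapseParams = FEATURE_PRESET
    coupling: LateralCouplingParams = field(default_factory=LateralCouplingParams)

    @property
    def n_channels(self) -> int:
        return len(self.V)

    @classmethod
    def at_rest(
        cls,
        n_channels: int,
        neuron: NeuronParams = REGULAR_SPIKING,
        synapse: SynapseParams = FEATURE_PRESET,
        coupling: LateralCouplingParams | None = None,
    ) -> "SensoryLayerState":
        """All neurons at their resting fixed point, synapses fully recovered."""
        if n_channels < 1:
            raise ValueError("need at least one channel")
        rest = resting_state(neuron)
        return cls(
            V=np.full(n_channels, rest.V),
            u=np.full(n_channels, rest.u),
            x=np.ones(n_channels),
            y=np.zeros(n_channels),
            z=np.zeros(n_channels),
            u_f=np.zeros(n_channels),
            neuron=neuron,
            synapse=synapse,
            coupling=coupling if coupling is not None else LateralCouplingParams(),
        )


def drive_current(
    emg_sample: float, y_others: np.ndarray, params: LateralCouplingParams
) -> float:
    """Total drive onto one sensory neuron: lateral synaptic current plus
    the rectified, k-scaled sEMG stimulator current."""
    return params.w * params.signed_g * float(np.sum(y_others)) + params.k * abs(
        emg_sample
    )


def step_layer(
    state: SensoryLayerState, emg_samples: np.ndarray, dt: float = DEFAULT_DT
) -> tuple[SensoryLayerState, np.ndarray]:
    """Advance the whole layer by one integration step.

    Drives are computed from the previous step's y values (synchronous
    update), excluding each neuron's own synapse; each spiking neuron then
    delivers a spike event to its own synapse.

    Returns the new layer state and the boolean spike mask.
    """
    emg_samples = np.asarray(emg_samples, dtype=np.float64)
    if emg_samples.shape != (state.n_channels,):
        raise ValueError(
            f"expected {state.n_channels} sEMG samples, got {emg_samples.shape}"
        )
    cp, npar, sp = state.coupling, state.neuron, state.synapse
    y_prev = state.y
    I = cp.w * cp.signed_g * (y_prev.sum() - y_prev) + cp.k * np.abs(emg_samples)

    V, u = state.V, state.u
    V_new = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + I)
    u_new = u + dt * (npar.a * (npar.b * V - u))
    spiked = V_new >= npar.v_peak
    V_new = np.where(spiked, npar.c, V_new)
    u_new = np.where(spiked, u_new + npar.d, u_new)

    x, y, z, u_f = state.x, state.y, state.z, state.u_f
    u_f = np.where(spiked, u_f + sp.U * (1.0 - u_f), u_f)
    delta = np.where(spiked, u_f * x, 0.0)
    x = x - delta
    y = y + delta
    Ey, Er, C, Ef = decay_coefficients(sp, dt)
    y_new = y * Ey
    z_new = z * Er + y * C
    new = SensoryLayerState(
        V=V_new,
        u=u_new,
        x=x + (y - y_new) + (z - z_new),
        y=y_new,
        z=z_new,
        u_f=u_f * Ef,
        neuron=npar,
        synapse=sp,
        coupling=cp,
    )
    return new, spiked


def _steps_per_sample(sample_rate: float, dt: float) -> int:
    interval_ms = 1000.0 / sample_rate
    m = round(interval_ms / dt)
    if m < 1 or abs(interval_ms / dt - m) > 1e-6:
        raise ValueError(
            f"sampling interval {interval_ms} ms is not an integer multiple of dt={dt} ms"
        )
    return m


def run_layer(
    recording: EMGRecording,
    state: SensoryLayerState,
    dt: float = DEFAULT_DT,
    record_every: int | None = None,
) -> tuple[np.ndarray, np.ndarray, SensoryLayerState]:
    """Integrate the layer over a recording (zero-order hold between sEMG
    samples).

    Returns (y_samples, spike_counts, final_state); `y_samples` holds the
    instantaneous per-channel y at every `record_every`-th step (empty if
    None).  This is the shared engine behind feature extraction and the
    isolated-vs-inhibitory comparisons.
    """
    if recording.n_channels != state.n_channels:
        raise ValueError("recording and layer disagree on channel count")
    m = _steps_per_sample(recording.sample_rate, dt)
    n_steps = recording.n_samples * m
    cp, npar, sp = state.coupling, state.neuron, state.synapse
    lateral = cp.w * cp.signed_g
    drive_ff = cp.k * np.abs(recording.data)  # (channels, samples)

    V = state.V.copy()
    u = state.u.copy()
    x = state.x.copy()
    y = state.y.copy()
    z = state.z.copy()
    u_f = state.u_f.copy()
    a, b, c, d, v_peak = npar.a, npar.b, npar.c, npar.d, npar.v_peak
    U_ = sp.U
    Ey, Er, C, Ef = decay_coefficients(sp, dt)

    spike_counts = np.zeros(state.n_channels, dtype=np.int64)
    out = []
    for step in range(n_steps):
        I = lateral * (y.sum() - y) + drive_ff[:, step // m]
        V_new = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + I)
        u = u + dt * (a * (b * V - u))
        spiked = V_new >= v_peak
        V = np.where(spiked, c, V_new)
        u = np.where(spiked, u + d, u)
        spike_counts += spiked

        u_f = np.where(spiked, u_f + U_ * (1.0 - u_f), u_f)
        delta = np.where(spiked, u_f * x, 0.0)
        x = x - delta
        y = y + delta
        y_new = y * Ey
        z_new = z * Er + y * C
        x = x + (y - y_new) + (z - z_new)
        y = y_new
        z = z_new
        u_f = u_f * Ef
        if record_every is not None and (step + 1) % record_every == 0:
            out.append(y.copy())

    final = SensoryLayerState(V, u, x, y, z, u_f, npar, sp, cp)
    y_samples = np.array(out) if out else np.empty((0, state.n_channels))
    return y_samples, spike_counts, final


def extract_spiking_features(
    recording: EMGRecording,
    feature_period: float = FEATURE_PERIOD_MS,
    mode: str = "inhibitory",
    neuron: NeuronParams = REGULAR_SPIKING,
    synapse: SynapseParams = FEATURE_PRESET,
    coupling: LateralCouplingParams | None = None,
    dt: float = DEFAULT_DT,
) -> FeatureMatrix:
    """Run the sensory layer over a labelled recording and sample features.

    Rows are the instantaneous per-channel y values every `feature_period`
    ms (row count = floor(duration / feature_period)); each row carries the
    gesture label active at its sampling instant.  `mode` selects the
    network: "isolated" (no lateral connections) or "inhibitory" (mutual
    inhibition with the configured w, g).
    """
    if mode not in ("isolated", "inhibitory"):
        raise ValueError("mode must be 'isolated' or 'inhibitory'")
    if coupling is None:
        coupling = LateralCouplingParams()
    if mode == "isolated":
        coupling = LateralCouplingParams(
            w=0.0, g=coupling.g, inhibitory=coupling.inhibitory, k=coupling.k
        )
    record_every = round(feature_period / dt)
    if record_every < 1 or abs(feature_period / dt - record_every) > 1e-9:
        raise ValueError("feature_period must be a positive multiple of dt")

    state = SensoryLayerState.at_rest(
        recording.n_channels, neuron=neuron, synapse=synapse, coupling=coupling
    )
    duration_ms = recording.n_samples / recording.sample_rate * 1000.0
    if duration_ms < feature_period:
        warnings.warn("recording shorter than one feature period; empty features")
        return FeatureMatrix(
            np.empty(0), np.empty((0, recording.n_channels)), np.empty(0, dtype=int)
        )
    y_samples, _, _ = run_layer(recording, state, dt=dt, record_every=record_every)
    n_rows = y_samples.shape[0]
    times_ms = (np.arange(n_rows) + 1.0) * feature_period
    m = _steps_per_sample(recording.sample_rate, dt)
    # label of the sEMG sample that drove the last step before each readout
    idx = ((np.arange(n_rows) + 1) * record_every - 1) // m
    if recording.labels is not None:
        labels = recording.labels[idx]
    else:
        labels = np.zeros(n_rows, dtype=np.int64)
    return FeatureMatrix(times_ms, y_samples, labels)
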