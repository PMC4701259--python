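"""Tsodyks-Markram short-term synaptic plasticity.

A unit synaptic resource is partitioned into recovered (x), active (y) and
inactivated (z) pools; a utilization variable u_f carries frequency-dependent
facilitation.  Between presynaptic spikes the dynamics are linear:

    dx/dt  =  z / tau_rec
    dy/dt  = -y / tau_I
    dz/dt  =  y / tau_I - z / tau_rec
    du_f/dt = -u_f / tau_facil

and each spike triggers the discrete event map (facilitation first, then
release): u_f <- u_f + U (1 - u_f), then a fraction u_f * x of the recovered
pool transfers to the active pool.  The active fraction y(t) is the synaptic
output signal used as the classification feature.

Because the between-spike system is linear with constant coefficients, each
step applies its exact closed-form propagator (no truncation error), so the
sampled trajectory coincides with the matrix-exponential solution between
events for any step size, resource conservation x + y + z = 1 holds to
rounding, and all pools stay in [0, 1].  Spikes are applied as discrete
event updates at the start of the step containing them.

Two presets matter here: `FIG3_PRESET` (U=0.5, tau_rec=100 ms, tau_I=10 ms,
tau_facil=1000 ms) displays both depression at high spike rates and
facilitation at low rates; `FEATURE_PRESET` (U=0.05, tau_rec=1 ms,
tau_I=200 ms, tau_facil=1 ms) degenerates, by design, into a leaky spike
integrator with a 200 ms decay — the intended behaviour of the sEMG feature
extractor, where y(t) tracks recent firing rate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "FIG3_PRESET",
    "FEATURE_PRESET",
    "step_synapse",
    "simulate_synapse",
    "response_amplitudes",
]

_CONSERVATION_TOL = 1e-6


@dataclass(frozen=True)
class SynapseParams:
    """U: baseline utilization (0-1]; tau_* : time constants (ms)."""

    U: float
    tau_rec: float
    tau_I: float
    tau_facil: float

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError("U must lie in (0, 1]")
        for name in ("tau_rec", "tau_I", "tau_facil"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


FIG3_PRESET = SynapseParams(U=0.5, tau_rec=100.0, tau_I=10.0, tau_facil=1000.0)
FEATURE_PRESET = SynapseParams(U=0.05, tau_rec=1.0, tau_I=200.0, tau_facil=1.0)


@dataclass(frozen=True)
class SynapseState:
    """Resource fractions x (recovered), y (active), z (inactivated) and
    facilitation variable u_f.  x + y + z = 1 at all times."""

    x: float = 1.0
    y: float = 0.0
    z: float = 0.0
    u_f: float = 0.0

    def validate(self) -> None:
        vals = (self.x, self.y, self.z, self.u_f)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite synapse state")
        if abs(self.x + self.y + self.z - 1.0) > _CONSERVATION_TOL:
            raise ValueError(
                f"resource not conserved: x+y+z = {self.x + self.y + self.z!r}"
            )
        for name, v in zip(("x", "y", "z", "u_f"), vals):
            if not -_CONSERVATION_TOL <= v <= 1.0 + _CONSERVATION_TOL:
                raise ValueError(f"{name} = {v!r} outside [0, 1]")


def decay_coefficients(
    params: SynapseParams, dt: float
) -> tuple[float, float, float, float]:
    """Closed-form one-step propagator coefficients (Ey, Er, C, Ef).

    Over a spike-free interval of length dt:
        y  -> y * Ey
        z  -> z * Er + y * C
        u_f -> u_f * Ef
    with x reconstructed from exact resource conservation.  C is the
    y-into-z transfer coefficient tau_rec/(tau_I - tau_rec) * (Ey - Er),
    taking its dt/tau * Er limit when the two time constants coincide.
    """
    Ey = math.exp(-dt / params.tau_I)
    Er = math.exp(-dt / params.tau_rec)
    Ef = math.exp(-dt / params.tau_facil)
    if abs(params.tau_I - params.tau_rec) > 1e-12 * params.tau_I:
        C = params.tau_rec / (params.tau_I - params.tau_rec) * (Ey - Er)
    else:
        C = (dt / params.tau_rec) * Er
    return Ey, Er, C, Ef


def step_synapse(
    state: SynapseState, params: SynapseParams, dt: float, spike: bool = False
) -> SynapseState:
    """Advance the synapse by `dt` ms, applying the spike event map first.

    The continuous part uses the exact inter-spike propagator, so the update
    is valid for any positive dt, conserves x + y + z to rounding and keeps
    every pool in [0, 1].
    """
    state.validate()
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    x, y, z, u_f = state.x, state.y, state.z, state.u_f
    if spike:
        u_f = u_f + params.U * (1.0 - u_f)
        delta = u_f * x
        x = x - delta
        y = y + delta
    Ey, Er, C, Ef = decay_coefficients(params, dt)
    y_new = y * Ey
    z_new = z * Er + y * C
    return SynapseState(
        x=x + (y - y_new) + (z - z_new),
        y=y_new,
        z=z_new,
        u_f=u_f * Ef,
    )


def _check_spike_times(spike_times: np.ndarray, T: float) -> np.ndarray:
    spike_times = np.asarray(spike_times, dtype=np.float64)
    if spike_times.size and not np.all(np.diff(spike_times) > 0):
        raise ValueError("spike_times must be strictly increasing")
    if spike_times.size and (spike_times[0] < 0 or spike_times[-1] > T):
        raise ValueError("spike_times must lie within [0, T]")
    return spike_times


def simulate_synapse(
    spike_times: np.ndarray,
    params: SynapseParams,
    dt: float = 0.5,
    T: float | None = None,
) -> np.ndarray:
    """Drive a synapse from rest by a spike train; return y sampled every dt.

    Spike times are snapped to the nearest integration step.  The returned
    trace has ``round(T / dt) + 1`` samples covering t = 0 .. T.
    """
    if T is None:
        T = float(spike_times[-1]) + 5.0 * params.tau_I if len(spike_times) else 0.0
    spike_times = _check_spike_times(spike_times, T)
    n_steps = round(T / dt)
    spike_steps = set(int(round(t / dt)) for t in spike_times)
    state = SynapseState()
    y = np.zeros(n_steps + 1)
    for step in range(n_steps):
        state = step_synapse(state, params, dt, spike=step in spike_steps)
        y[step + 1] = state.y
    return y


def response_amplitudes(
    spike_times: np.ndarray,
    params: SynapseParams,
    dt: float = 0.5,
    T: float | None = None,
) -> np.ndarray:
    """Per-spike response amplitudes: the jump in y at each spike event.

    The amplitude of spike k is u_f * x evaluated just after the
    facilitation update, i.e. the fraction of resource released by that
    spike; strictly decreasing amplitudes signal depression, increasing
    pre-spike u_f signals facilitation.
    """
    if T is None:
        T = float(spike_times[-1]) + dt if len(spike_times) else 0.0
    spike_times = _check_spike_times(spike_times, T)
    n_steps = round(T / dt)
    spike_steps = {int(round(t / dt)): i for i, t in enumerate(spike_times)}
    state = SynapseState()
    amps = np.zeros(len(spike_times))
    for step in range(n_steps):
        spike = step in spike_steps
        if spike:
            u_ev = state.u_f + params.U * (1.0 - state.u_f)
            amps[spike_steps[step]] = u_ev * state.x
        state = step_synapse(state, params, dt, spike=spike)
    return amps
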