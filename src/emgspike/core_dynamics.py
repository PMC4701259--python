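"""Izhikevich spiking-neuron dynamics.

The neuron is the two-variable quadratic integrate model

    dV/dt = 0.04 V^2 + 5 V + 140 - u + I
    du/dt = a (b V - u)

with the after-spike reset: if V >= 30 mV then V <- c, u <- u + d.
`V` is the transmembrane potential in mV, `u` a recovery variable on the
same scale, and `I` the external drive in the model's dimensionless current
units.  Integration is explicit Euler (the scheme the model was published
with); the step is configurable with a 0.5 ms default and a 1 ms stability
cap.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "REGULAR_SPIKING",
    "step_neuron",
    "resting_state",
    "simulate_neuron",
]

#: Default integration step (ms).
DEFAULT_DT = 0.5


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich model parameters.

    `a` is the recovery time-scale (1/ms), `b` the recovery sensitivity,
    `c` the reset potential (mV), `d` the recovery increment applied after
    each spike, and `v_peak` the 30 mV spike cut-off.  The defaults are the
    cortical "regular spiking" preset.
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("a must be positive")
        if not self.v_peak > self.c:
            raise ValueError("v_peak must exceed the reset potential c")


#: Regular-spiking preset: tonic firing with spike-frequency adaptation.
REGULAR_SPIKING = NeuronParams()


@dataclass(frozen=True)
class NeuronState:
    """Membrane potential V (mV) and recovery variable u of one neuron."""

    V: float
    u: float


def step_neuron(
    state: NeuronState, params: NeuronParams, I: float, dt: float = DEFAULT_DT
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one Euler step of `dt` ms.

    The spike test (V >= v_peak) is applied after the Euler update; on a
    spike the returned state is the reset state (V = c, u incremented by d)
    and the flag is set.

    Returns
    -------
    (NeuronState, bool)
        The post-step (possibly reset) state and whether a spike occurred.
    """
    if not 0.0 < dt <= 1.0:
        raise ValueError("dt must lie in (0, 1] ms for stable explicit stepping")
    for name, val in (("V", state.V), ("u", state.u), ("I", I)):
        if not math.isfinite(val):
            raise ValueError(f"non-finite {name}: {val!r}")
    V, u = state.V, state.u
    V_new = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + I)
    u_new = u + dt * (params.a * (params.b * V - u))
    spiked = V_new >= params.v_peak
    if spiked:
        V_new = params.c
        u_new = u_new + params.d
    return NeuronState(V_new, u_new), spiked


def resting_state(params: NeuronParams) -> NeuronState:
    """Stable fixed point (V*, u*) of the zero-input dynamics.

    Sets u* = b V* (the u-nullcline) and solves the quadratic
    0.04 V^2 + (5 - b) V + 140 = 0; among the real roots the one whose
    Jacobian eigenvalues have negative real parts is returned.  This is the
    canonical initial condition for all simulations.

    Raises
    ------
    ValueError
        If no real root exists, or no root is stable ("no resting state").
    """
    b = params.b
    disc = (5.0 - b) ** 2 - 4.0 * 0.04 * 140.0
    if disc < 0:
        raise ValueError("no resting state: nullclines do not intersect")
    sq = math.sqrt(disc)
    roots = ((-(5.0 - b) - sq) / 0.08, (-(5.0 - b) + sq) / 0.08)
    for V in roots:
        jac = np.array([[0.08 * V + 5.0, -1.0], [params.a * b, -params.a]])
        if np.all(np.linalg.eigvals(jac).real < 0):
            return NeuronState(V, b * V)
    raise ValueError("no resting state: no stable fixed point")


def simulate_neuron(
    I_trace: np.ndarray,
    params: NeuronParams = REGULAR_SPIKING,
    dt: float = DEFAULT_DT,
    sample_dt: float | None = None,
    initial: NeuronState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a single neuron driven by a sampled current trace.

    The current is zero-order-held between its samples, whose interval
    `sample_dt` (default: equal to `dt`) must be an integer multiple of the
    integration step.  At spike steps the recorded trace holds the clipped
    peak `v_peak` rather than the Euler overshoot, so plotted spikes reach
    30 mV reproducibly; the integration state itself is reset.

    Returns
    -------
    (V_trace, spike_times)
        Membrane potential at the end of every integration step (mV), and
        the strictly increasing spike times (ms).
    """
    I_trace = np.asarray(I_trace, dtype=np.float64)
    if I_trace.size == 0:
        return np.empty(0), np.empty(0)
    if not np.all(np.isfinite(I_trace)):
        raise ValueError("non-finite I in current trace")
    sample_dt = dt if sample_dt is None else sample_dt
    ratio = sample_dt / dt
    m = round(ratio)
    if m < 1 or abs(ratio - m) > 1e-9:
        raise ValueError("sample_dt must be an integer multiple of dt")
    state = resting_state(params) if initial is None else initial

    n_steps = I_trace.size * m
    V_trace = np.empty(n_steps)
    spike_steps = []
    V, u = state.V, state.u
    a, b, c, d, v_peak = params.a, params.b, params.c, params.d, params.v_peak
    for step in range(n_steps):
        I = I_trace[step // m]
        V_next = V + dt * (0.04 * V * V + 5.0 * V + 140.0 - u + I)
        u_next = u + dt * (a * (b * V - u))
        if V_next >= v_peak:
            V_trace[step] = v_peak
            V_next = c
            u_next += d
            spike_steps.append(step)
        else:
            V_trace[step] = V_next
        V, u = V_next, u_next
    spike_times = (np.asarray(spike_steps, dtype=np.float64) + 1.0) * dt
    return V_trace, spike_times


def export_trace_csv(path, V_trace: np.ndarray, dt: float = DEFAULT_DT) -> None:
    """Write a two-column (time_ms, V_mV) CSV of a simulated trace."""
    import pandas as pd

    t = (np.arange(len(V_trace)) + 1.0) * dt
    pd.DataFrame({"time_ms": t, "V_mV": V_trace}).to_csv(path, index=False)
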