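"""Synthetic gesture-structured multichannel sEMG.

Real interference-pattern sEMG is well approximated, for pipeline purposes,
by amplitude-modulated zero-mean band-limited noise: each gesture turns on a
distinct sparse subset of channels whose envelopes multiply independent
20-150 Hz Gaussian noise carriers.  On top of that the generator adds a
common-mode (in-phase) noise component shared identically by all channels —
emulating the crosstalk of closely spaced electrodes on a forearm ring,
which carries no pattern information — and independent per-channel baseline
noise.

The acquisition protocol emulated is: several series, each containing the
full gesture set once in random order, gestures lasting 2-3 s with relaxed
rest between them, rendered at either 400 Hz or 2000 Hz.  The gesture
schedule is drawn in continuous time before any noise, so the same seed
produces the same label structure (and per-gesture RMS profile) at both
rates.

Voltage scale: active envelopes are tens of microvolts RMS so that the
sensory layer's default input gain k = 2e6 puts gesture activity in the
neurons' spiking range while rest stays near-quiescent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .data import EMGRecording

__all__ = [
    "GestureProfile",
    "SeriesSpec",
    "make_gesture_profiles",
    "generate_recording",
    "generate_dataset",
]

#: Envelope on/off ramp (s): avoids unphysical steps at gesture boundaries.
RAMP_S = 0.1


@dataclass
class GestureProfile:
    """Per-gesture, per-channel activation amplitudes (volts RMS).

    Row g of `amplitudes` is gesture g's channel activation pattern; row 0
    is the rest class and is all zeros.  `common_mode_amp` and
    `baseline_amp` are the RMS amplitudes of the shared in-phase noise and
    the independent per-channel background noise.
    """

    amplitudes: np.ndarray
    common_mode_amp: float = 5e-6
    baseline_amp: float = 1.5e-6
    duration_range: tuple[float, float] = (2.0, 3.0)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.ndim != 2:
            raise ValueError("amplitudes must be (n_gestures, n_channels)")
        if np.any(self.amplitudes < 0):
            raise ValueError("activation amplitudes must be non-negative")
        if self.common_mode_amp < 0 or self.baseline_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @property
    def n_gestures(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.amplitudes.shape[1]

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.amplitudes.tolist(),
            "common_mode_amp": self.common_mode_amp,
            "baseline_amp": self.baseline_amp,
            "duration_range": list(self.duration_range),
        }


@dataclass
class SeriesSpec:
    """Acquisition-protocol parameters for one synthetic session."""

    n_series: int = 4
    sample_rate: float = 400.0
    seed: int = 0
    rest_duration: float = 1.0
    band_hz: tuple[float, float] = (20.0, 150.0)

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ValueError("need at least one series")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def to_dict(self) -> dict:
        return {
            "n_series": self.n_series,
            "sample_rate": self.sample_rate,
            "seed": self.seed,
            "rest_duration": self.rest_duration,
            "band_hz": list(self.band_hz),
        }


def make_gesture_profiles(
    n_gestures: int = 9, n_channels: int = 8, seed: int = 0
) -> GestureProfile:
    """Draw a reproducible set of distinct sparse activation patterns.

    Gesture 0 is rest (all zeros).  Every other gesture has a dedicated
    primary channel at high amplitude plus one or two secondary channels at
    lower amplitude, so the nine patterns are pairwise well separated while
    still overlapping on individual channels.
    """
    if n_gestures < 1 or n_channels < 1:
        raise ValueError("need at least one gesture and one channel")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        amps = np.zeros((n_gestures, n_channels))
        for g in range(1, n_gestures):
            base = (g - 1) % n_channels
            amps[g, base] = rng.uniform(7e-5, 1.2e-4)
            others = [c for c in range(n_channels) if c != base]
            n_extra = int(rng.integers(1, min(3, len(others)) + 1)) if others else 0
            extras = rng.choice(others, size=n_extra, replace=False)
            amps[g, extras] = rng.uniform(3e-5, 7e-5, size=n_extra)
        diffs = amps[:, None, :] - amps[None, :, :]
        dist = np.sqrt((diffs**2).sum(axis=2))
        dist[np.diag_indices(n_gestures)] = np.inf
        if dist.min() > 1e-5:
            return GestureProfile(amplitudes=amps)
    raise RuntimeError("could not draw pairwise-distinct gesture patterns")


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to `band` Hz."""
    raw = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.45 * rate)
    sos = sp_signal.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    filt = sp_signal.sosfiltfilt(sos, raw)
    sd = filt.std()
    return filt / sd if sd > 0 else filt


def _series_schedule(
    rng: np.random.Generator, profile: GestureProfile, spec: SeriesSpec
) -> tuple[list[tuple[int, float, float]], float]:
    """(label, t_start, t_end) spans for one series, drawn in continuous time."""
    order = rng.permutation(profile.n_gestures)
    lo, hi = profile.duration_range
    spans = []
    t = spec.rest_duration
    for g in order:
        dur = rng.uniform(lo, hi)
        spans.append((int(g), t, t + dur))
        t += dur + spec.rest_duration
    return spans, t


def _render_series(
    seed_seq: np.random.SeedSequence, profile: GestureProfile, spec: SeriesSpec
) -> EMGRecording:
    rng = np.random.default_rng(seed_seq)
    spans, total_s = _series_schedule(rng, profile, spec)
    rate = spec.sample_rate
    n = round(total_s * rate)
    t = np.arange(n) / rate

    labels = np.zeros(n, dtype=np.int64)
    env_per_gesture = np.zeros((profile.n_gestures, n))
    for g, t0, t1 in spans:
        ramp_up = np.clip((t - t0) / RAMP_S, 0.0, 1.0)
        ramp_down = np.clip((t1 - t) / RAMP_S, 0.0, 1.0)
        env = np.minimum(ramp_up, ramp_down)
        env[(t < t0) | (t >= t1)] = 0.0
        env_per_gesture[g] = np.maximum(env_per_gesture[g], env)
        labels[(t >= t0) & (t < t1)] = g
    envelopes = profile.amplitudes.T @ env_per_gesture  # (channels, samples)

    common = _bandlimited_noise(rng, n, rate, spec.band_hz) * profile.common_mode_amp
    data = np.empty((profile.n_channels, n))
    for c in range(profile.n_channels):
        carrier = _bandlimited_noise(rng, n, rate, spec.band_hz)
        baseline = _bandlimited_noise(rng, n, rate, spec.band_hz)
        data[c] = envelopes[c] * carrier + common + baseline * profile.baseline_amp
    return EMGRecording(rate, data, labels)


def generate_recording(profile: GestureProfile, spec: SeriesSpec) -> EMGRecording:
    """Render all series of one session as a single labelled recording."""
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_series)
    parts = [_render_series(s, profile, spec) for s in seqs]
    return _concat(parts, spec.sample_rate)


def _concat(parts: list[EMGRecording], rate: float) -> EMGRecording:
    data = np.concatenate([p.data for p in parts], axis=1)
    labels = np.concatenate([p.labels for p in parts])
    return EMGRecording(rate, data, labels)


def generate_dataset(
    spec: SeriesSpec,
    train_series: int = 3,
    test_series: int = 1,
    profile: GestureProfile | None = None,
) -> tuple[EMGRecording, EMGRecording]:
    """Disjoint train/test recordings from whole series (default 3 / 1).

    Each series contains every gesture once, so both splits cover all
    classes.  The profile defaults to `make_gesture_profiles` seeded from
    the spec.
    """
    if train_series < 1 or test_series < 1:
        raise ValueError("both splits need at least one series")
    if train_series + test_series > spec.n_series:
        raise ValueError(
            f"cannot allocate {train_series}+{test_series} series out of {spec.n_series}"
        )
    if profile is None:
        profile = make_gesture_profiles(seed=spec.seed)
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_series)
    parts = [_render_series(s, profile, spec) for s in seqs]
    train = _concat(parts[:train_series], spec.sample_rate)
    test = _concat(parts[train_series : train_series + test_series], spec.sample_rate)
    return train, test


def write_manifest(path, profile: GestureProfile, spec: SeriesSpec) -> None:
    """JSON manifest sufficient to regenerate a recording exactly."""
    with open(path, "w") as fh:
        json.dump({"profile": profile.to_dict(), "spec": spec.to_dict()}, fh, indent=2)
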