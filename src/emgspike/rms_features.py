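"""Sliding-window RMS features: the classical baseline extractor.

Each channel is segmented into 100 ms windows advanced every 50 ms (40- and
20-sample windows at 400 Hz), and the root mean square

    RMS = sqrt( (1/N) * sum_n x_n^2 )

of each window is the per-channel muscle-contraction-amplitude feature.
Windows are specified in milliseconds and converted to samples, so the same
100 ms / 50 ms geometry applies at any device rate.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import EMGRecording, FeatureMatrix

__all__ = ["WindowConfig", "rms", "segment_windows", "extract_rms_features"]


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry in milliseconds (defaults: 100 ms window, 50 ms step)."""

    window_ms: float = 100.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.step_ms <= self.window_ms:
            raise ValueError("require 0 < step_ms <= window_ms")

    def in_samples(self, sample_rate: float) -> tuple[int, int]:
        """(window, step) lengths in samples at the given rate."""
        N = round(self.window_ms * sample_rate / 1000.0)
        step = round(self.step_ms * sample_rate / 1000.0)
        if N < 1 or step < 1:
            raise ValueError("window and step must be at least one sample")
        return N, step


def rms(window: np.ndarray) -> float:
    """Root mean square sqrt(mean(x^2)) of a non-empty window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(window**2)))


def segment_windows(
    n_samples: int, rate: float, config: WindowConfig = WindowConfig()
) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of the sliding windows.

    The start advances by the step; a trailing incomplete window is dropped,
    so the count is floor((n_samples - N) / step) + 1.  A recording shorter
    than one window yields an empty list with a warning.
    """
    N, step = config.in_samples(rate)
    if n_samples < N:
        warnings.warn("recording shorter than one window; no features")
        return []
    starts = range(0, n_samples - N + 1, step)
    return [(s, s + N) for s in starts]


def extract_rms_features(
    recording: EMGRecording, config: WindowConfig = WindowConfig()
) -> FeatureMatrix:
    """Per-window, per-channel RMS features with majority-vote labels.

    Row times are window-end times in ms, aligning the 50 ms step with the
    spiking extractor's feature instants.
    """
    windows = segment_windows(recording.n_samples, recording.sample_rate, config)
    n_rows = len(windows)
    X = np.empty((n_rows, recording.n_channels))
    times = np.empty(n_rows)
    labels = np.zeros(n_rows, dtype=np.int64)
    sq = recording.data**2
    for i, (start, end) in enumerate(windows):
        X[i] = np.sqrt(np.mean(sq[:, start:end], axis=1))
        times[i] = end * (1000.0 / recording.sample_rate)
        if recording.labels is not None:
            counts = np.bincount(recording.labels[start:end])
            labels[i] = int(np.argmax(counts))  # majority; ties -> lowest class
    return FeatureMatrix(times, X, labels)
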