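"""Shared data containers: multichannel sEMG recordings and feature matrices.

Both extractors (sliding-window RMS and the spiking sensory layer) emit the
same :class:`FeatureMatrix` container and CSV dialect, so the classifier is
agnostic to which extractor produced its input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EMGRecording", "FeatureMatrix"]


@dataclass
class EMGRecording:
    """A multichannel surface-EMG recording with optional per-sample labels.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (400 for MYO-class devices, 2000 for
        DELSYS-class devices).
    data : ndarray, shape (n_channels, n_samples)
        Signal in volts.
    labels : ndarray of int, shape (n_samples,), optional
        Gesture class active at each sample (0 = rest by convention).
    """

    sample_rate: float
    data: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.data.shape[1],):
                raise ValueError(
                    "labels length must equal sample count "
                    f"({self.labels.shape[0]} != {self.data.shape[1]})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def to_csv(self, path) -> None:
        """Write `time_s,ch1..chN[,label]` CSV."""
        t = np.arange(self.n_samples) / self.sample_rate
        cols = {"time_s": t}
        for i in range(self.n_channels):
            cols[f"ch{i + 1}"] = self.data[i]
        if self.labels is not None:
            cols["label"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sample_rate: float | None = None) -> "EMGRecording":
        """Read the module CSV dialect; the rate is inferred from the time
        column unless given explicitly."""
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError("recording CSV must have a time_s column")
        chan_cols = [c for c in df.columns if c.startswith("ch")]
        if not chan_cols:
            raise ValueError("recording CSV has no channel columns (ch1..chN)")
        if sample_rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            if len(dt) == 0:
                raise ValueError("cannot infer sample rate from a single sample")
            sample_rate = 1.0 / float(np.median(dt))
        labels = df["label"].to_numpy() if "label" in df.columns else None
        return cls(sample_rate, df[chan_cols].to_numpy().T, labels)


@dataclass
class FeatureMatrix:
    """Time-indexed per-channel feature vectors with class labels.

    Rows are sampled at the feature instants (window ends for RMS, every
    `feature_period` for the spiking extractor); `X[i]` is the 8-vector fed
    to the classifier and `labels[i]` the gesture class active at `times_ms[i]`.
    """

    times_ms: np.ndarray
    X: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (rows x channels)")
        if self.times_ms.shape[0] != self.X.shape[0]:
            raise ValueError("times and feature rows disagree in length")
        if self.labels is None:
            self.labels = np.zeros(self.X.shape[0], dtype=np.int64)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape[0] != self.X.shape[0]:
                raise ValueError("labels and feature rows disagree in length")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path) -> None:
        """Write `t_ms,f1..fN,label` CSV."""
        cols = {"t_ms": self.times_ms}
        for i in range(self.n_features):
            cols[f"f{i + 1}"] = self.X[:, i]
        cols["label"] = self.labels
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        feat_cols = [c for c in df.columns if c.startswith("f") and c != "label"]
        labels = df["label"].to_numpy() if "label" in df.columns else None
        return cls(df["t_ms"].to_numpy(), df[feat_cols].to_numpy(), labels)
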