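"""End-to-end orchestration: generate/load, extract, train, classify, evaluate.

Replicates the comparison design of the study setting: the same recordings
and train/test split are pushed through either the RMS baseline extractor or
the spiking sensory layer (isolated or with lateral inhibition), a sigmoid
MLP is trained per extractor, and window-level accuracies are compared as
DELTA = accuracy(spiking) - accuracy(RMS).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .core_dynamics import NeuronParams
from .data import EMGRecording, FeatureMatrix
from .mlp_classifier import (
    MLPModel,
    TrainingHistory,
    classify_batch,
    init_mlp,
    train,
)
from .rms_features import WindowConfig, extract_rms_features
from .sensory_network import (
    FEATURE_PERIOD_MS,
    LateralCouplingParams,
    extract_spiking_features,
)
from .synapse_tm import SynapseParams
from .synthetic_semg import SeriesSpec, generate_dataset, make_gesture_profiles

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "TrainedPipeline",
    "extract_features",
    "run_training_pipeline",
    "run_streaming_classification",
    "evaluate",
    "compare",
]

log = logging.getLogger("emgspike")

EXTRACTORS = ("rms", "spiking_isolated", "spiking_inhibitory")


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run, nested per module."""

    extractor: str = "spiking_inhibitory"
    sample_rate: float = 400.0
    seed: int = 0
    dt_ms: float = 0.5
    feature_period_ms: float = FEATURE_PERIOD_MS
    neuron: dict = field(default_factory=lambda: dict(a=0.02, b=0.2, c=-65.0, d=8.0))
    synapse: dict = field(
        default_factory=lambda: dict(U=0.05, tau_rec=1.0, tau_I=200.0, tau_facil=1.0)
    )
    coupling: dict = field(
        default_factory=lambda: dict(w=0.5, g=60.0, inhibitory=True, k=2e6)
    )
    window: dict = field(default_factory=lambda: dict(window_ms=100.0, step_ms=50.0))
    mlp: dict = field(
        default_factory=lambda: dict(
            hidden=9, lr=0.01, max_epochs=4000, patience=50, update="online"
        )
    )
    synthetic: dict = field(
        default_factory=lambda: dict(
            n_gestures=9, n_channels=8, n_series=4, train_series=3, test_series=1,
            rest_duration=1.0,
        )
    )

    def __post_init__(self) -> None:
        if self.extractor not in EXTRACTORS:
            raise ValueError(f"extractor must be one of {EXTRACTORS}")

    def neuron_params(self) -> NeuronParams:
        return NeuronParams(**self.neuron)

    def synapse_params(self) -> SynapseParams:
        return SynapseParams(**self.synapse)

    def coupling_params(self) -> LateralCouplingParams:
        return LateralCouplingParams(**self.coupling)

    def window_config(self) -> WindowConfig:
        return WindowConfig(**self.window)

    def series_spec(self) -> SeriesSpec:
        return SeriesSpec(
            n_series=self.synthetic["n_series"],
            sample_rate=self.sample_rate,
            seed=self.seed,
            rest_duration=self.synthetic["rest_duration"],
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = cls()
        for key, val in raw.items():
            if not hasattr(base, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(base, key)
            if isinstance(current, dict):
                unknown = set(val) - set(current)
                if unknown:
                    raise ValueError(f"unknown keys in {key}: {sorted(unknown)}")
                current.update(val)
            else:
                setattr(base, key, val)
        return base


@dataclass
class EvaluationReport:
    """Window-level classification quality of one run."""

    accuracy_pct: float
    confusion: np.ndarray
    per_class_recall_pct: np.ndarray
    n_windows: int
    extractor: str = ""
    config_hash: str = ""
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "confusion": self.confusion.tolist(),
            "per_class_recall_pct": self.per_class_recall_pct.tolist(),
            "n_windows": self.n_windows,
            "extractor": self.extractor,
            "config_hash": self.config_hash,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class FeatureScaler:
    """Per-feature standardization fitted on the training set only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        std = X.std(axis=0)
        return cls(X.mean(axis=0), np.where(std > 0, std, 1.0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class TrainedPipeline:
    """A trained classifier bound to its extractor config and scaler."""

    config: PipelineConfig
    scaler: FeatureScaler
    model: MLPModel
    history: TrainingHistory | None = None

    def save(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "scaler": {"mean": self.scaler.mean.tolist(), "std": self.scaler.std.tolist()},
            "model": {
                "sizes": list(self.model.sizes),
                "weights": [w.tolist() for w in self.model.weights],
                "biases": [b.tolist() for b in self.model.biases],
                "seed": self.model.seed,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedPipeline":
        with open(path) as fh:
            payload = json.load(fh)
        config = PipelineConfig(**payload["config"])
        scaler = FeatureScaler(
            np.asarray(payload["scaler"]["mean"]), np.asarray(payload["scaler"]["std"])
        )
        m = payload["model"]
        model = MLPModel(
            tuple(m["sizes"]),
            [np.asarray(w) for w in m["weights"]],
            [np.asarray(b) for b in m["biases"]],
            int(m["seed"]),
        )
        return cls(config, scaler, model)


def extract_features(recording: EMGRecording, config: PipelineConfig) -> FeatureMatrix:
    """Dispatch to the configured extractor on one recording."""
    log.info(
        "extracting %s features: %d channels x %d samples @ %g Hz",
        config.extractor, recording.n_channels, recording.n_samples,
        recording.sample_rate,
    )
    if config.extractor == "rms":
        return extract_rms_features(recording, config.window_config())
    mode = "isolated" if config.extractor == "spiking_isolated" else "inhibitory"
    return extract_spiking_features(
        recording,
        feature_period=config.feature_period_ms,
        mode=mode,
        neuron=config.neuron_params(),
        synapse=config.synapse_params(),
        coupling=config.coupling_params(),
        dt=config.dt_ms,
    )


def _make_dataset(config: PipelineConfig) -> tuple[EMGRecording, EMGRecording]:
    syn = config.synthetic
    profile = make_gesture_profiles(
        n_gestures=syn["n_gestures"], n_channels=syn["n_channels"], seed=config.seed
    )
    return generate_dataset(
        config.series_spec(),
        train_series=syn["train_series"],
        test_series=syn["test_series"],
        profile=profile,
    )


def run_training_pipeline(
    config: PipelineConfig,
    train_recording: EMGRecording | None = None,
    test_recording: EMGRecording | None = None,
) -> tuple[TrainedPipeline, EvaluationReport]:
    """Full run: data -> features -> MLP training -> test-set report.

    Recordings default to the synthetic session defined by the config
    (seeded, 4 series split 3 train / 1 test).
    """
    if (train_recording is None) != (test_recording is None):
        raise ValueError("provide both train and test recordings, or neither")
    if train_recording is None:
        train_recording, test_recording = _make_dataset(config)
    feats_tr = extract_features(train_recording, config)
    feats_te = extract_features(test_recording, config)
    n_classes = config.synthetic["n_gestures"]
    scaler = FeatureScaler.fit(feats_tr.X)
    mlp_cfg = config.mlp
    model = init_mlp(
        (feats_tr.n_features, mlp_cfg["hidden"], n_classes), seed=config.seed
    )
    log.info(
        "training MLP %s on %d windows (test %d), lr=%g",
        model.sizes, len(feats_tr), len(feats_te), mlp_cfg["lr"],
    )
    model, history = train(
        model,
        (scaler.transform(feats_tr.X), feats_tr.labels),
        (scaler.transform(feats_te.X), feats_te.labels),
        lr=mlp_cfg["lr"],
        max_epochs=mlp_cfg["max_epochs"],
        patience=mlp_cfg["patience"],
        update=mlp_cfg["update"],
    )
    predictions = classify_batch(model, scaler.transform(feats_te.X))
    report = evaluate(predictions, feats_te.labels, n_classes=n_classes)
    report.extractor = config.extractor
    report.config_hash = config.config_hash()
    report.seed = config.seed
    pipeline = TrainedPipeline(config, scaler, model, history)
    log.info("%s accuracy: %.2f%% over %d windows",
             config.extractor, report.accuracy_pct, report.n_windows)
    return pipeline, report


def run_streaming_classification(
    pipeline: TrainedPipeline, recording: EMGRecording
) -> tuple[np.ndarray, np.ndarray]:
    """Causal pass over a recording: one class decision per feature instant.

    Returns (times_ms, classes); decisions are spaced by the feature period
    (window step for the RMS extractor).
    """
    feats = extract_features(recording, pipeline.config)
    if feats.n_features != pipeline.model.n_inputs:
        raise ValueError(
            f"extractor width {feats.n_features} does not match model input "
            f"{pipeline.model.n_inputs}"
        )
    classes = classify_batch(pipeline.model, pipeline.scaler.transform(feats.X))
    return feats.times_ms, classes


def evaluate(
    predictions: np.ndarray, truth: np.ndarray, n_classes: int | None = None
) -> EvaluationReport:
    """Window-level accuracy (%), confusion matrix and per-class recall."""
    predictions = np.asarray(predictions, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    if n_classes is None:
        n_classes = int(max(predictions.max(), truth.max())) + 1
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (truth, predictions), 1)
    total = confusion.sum()
    accuracy = 100.0 * np.trace(confusion) / total if total else 0.0
    row_sums = confusion.sum(axis=1)
    recall = 100.0 * np.diag(confusion) / np.where(row_sums > 0, row_sums, 1)
    return EvaluationReport(
        accuracy_pct=float(accuracy),
        confusion=confusion,
        per_class_recall_pct=recall,
        n_windows=int(total),
    )


def compare(spiking: EvaluationReport, rms: EvaluationReport) -> float:
    """Paired accuracy delta (percentage points): spiking minus RMS."""
    return spiking.accuracy_pct - rms.accuracy_pct
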