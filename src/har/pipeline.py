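"""End-to-end experiment harness: preprocess, segment, featurize, classify,
score — the glue the CLI and the shipped experiments run.

Segmentation at prediction time is run per stream: adaptive segmentation
consumes the 6 filtered original channels with K chosen as
``round(rate_per_minute * duration_minutes)``, where ``rate_per_minute`` is
a profile value calibrated on training streams (the published analyses used
roughly 7/min for the scripted smartphone runs and 2/min for hour-long
smartwatch sessions).  The regulariser defaults to 1e-3 times the median
channel variance of the stream it segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, evaluate, features, preprocess, segmentation
from .sensor_io import LabelTrack, SensorStream


@dataclass
class ExperimentConfig:
    """Profile-level knobs for a segmentation-vs-classification experiment."""

    model: classify.ModelSpec = field(default_factory=classify.ModelSpec)
    sizes_s: tuple[float, ...] = (0.8, 3.0, 8.0, 30.0)
    ggs_rate_per_minute: float = 4.0
    ggs_lambda: float | None = None  # None -> 1e-3 * median channel variance
    min_seg_len: int = 5
    median_kernel: int = 3
    butter_order: int = 3
    cutoff_hz: float | None = None  # None -> skip low-pass
    classes: tuple[str, ...] | None = None


PROFILES: dict[str, ExperimentConfig] = {
    # scripted ~7 min smartphone runs: equal ~20 s bouts, 50 Hz
    "harus": ExperimentConfig(
        model=classify.ModelSpec(max_depth=2),
        sizes_s=(0.2, 0.8, 3.0, 8.0),
        ggs_rate_per_minute=7.0,
        cutoff_hz=20.0,
    ),
    # ~55 min smartwatch sessions shuffled into ~60 unequal bouts, 10->50 Hz
    "breathe": ExperimentConfig(
        model=classify.ModelSpec(max_depth=3),
        sizes_s=(0.2, 0.8, 3.0, 8.0, 12.0, 40.0),
        ggs_rate_per_minute=2.0,
        cutoff_hz=20.0,
    ),
    # scaled-down synthetic sessions (5.5 min, 20 Hz) with equal 30-60 s bouts
    "desk_equal": ExperimentConfig(
        model=classify.ModelSpec(max_depth=3),
        sizes_s=(0.8, 3.0, 8.0, 30.0),
        ggs_rate_per_minute=4.0,
        cutoff_hz=8.0,
    ),
    # the same sessions shuffled into ~60 unequal bouts
    "desk_shuffled": ExperimentConfig(
        model=classify.ModelSpec(max_depth=3),
        sizes_s=(0.8, 3.0, 8.0, 30.0),
        ggs_rate_per_minute=12.0,
        cutoff_hz=8.0,
    ),
}


def preprocess_stream(stream: SensorStream, config: ExperimentConfig) -> SensorStream:
    """Median filter then (optionally) the zero-phase low-pass."""
    out = preprocess.median_filter(stream, kernel=config.median_kernel)
    if config.cutoff_hz is not None:
        out = preprocess.butterworth_lowpass(
            out, order=config.butter_order, cutoff_hz=config.cutoff_hz
        )
    return out


def ggs_segments(stream: SensorStream, config: ExperimentConfig) -> list[tuple[int, int]]:
    """Run adaptive segmentation on one stream with the profile's K policy."""
    duration_min = stream.n_samples / stream.rate_hz / 60.0
    K = max(1, int(round(config.ggs_rate_per_minute * duration_min)))
    lam = config.ggs_lambda
    if lam is None:
        lam = 1e-3 * float(np.median(stream.data.var(axis=0)))
    seg = segmentation.ggs(
        stream.data, K=K, lam=lam, min_seg_len=config.min_seg_len, force_K=True
    )
    return seg.segments


@dataclass
class ExperimentResult:
    accuracy_pct: float
    confusion: evaluate.ConfusionMatrix
    truth: classify.PredictionTrace
    pred: classify.PredictionTrace
    model: classify.FittedModel


def _segments_for(stream: SensorStream, method: str, size_s, config) -> list[tuple[int, int]]:
    if method == "ggs":
        return ggs_segments(stream, config)
    if method == "fixed":
        return segmentation.fixed_windows(stream.n_samples, stream.rate_hz, size_s)
    raise ValueError(f"unknown method {method!r}")


def run_experiment(
    train: list[tuple[SensorStream, LabelTrack]],
    test: list[tuple[SensorStream, LabelTrack]],
    method: str = "ggs",
    size_s: float | None = None,
    config: ExperimentConfig | None = None,
    preprocessed: bool = True,
) -> ExperimentResult:
    """Train on pooled per-segment features, score instantaneously on test.

    With ``preprocessed=False`` the median/low-pass stage is applied here.
    """
    config = config or ExperimentConfig()
    frames = []
    labels: list[str] = []
    for stream, track in train:
        if not preprocessed:
            stream = preprocess_stream(stream, config)
        segs = _segments_for(stream, method, size_s, config)
        F = features.segment_features(features.augment_signals(stream), segs)
        lab = classify.assign_segment_labels(segs, track, T=stream.n_samples)
        keep = lab["label"].notna()
        frames.append(F[keep.to_numpy()])
        labels.extend(lab.loc[keep, "label"])
    model = classify.train_classifier(pd.concat(frames, ignore_index=True), labels, config.model)

    truth_all: list[np.ndarray] = []
    pred_all: list[np.ndarray] = []
    for stream, track in test:
        if not preprocessed:
            stream = preprocess_stream(stream, config)
        segs = _segments_for(stream, method, size_s, config)
        F = features.segment_features(features.augment_signals(stream), segs)
        seg_labels, _ = classify.predict_segments(model, F)
        trace = classify.to_instantaneous(seg_labels, segs, stream.n_samples, provenance=method)
        truth_all.append(track.to_sample_labels(stream.n_samples))
        pred_all.append(trace.labels)
    truth = classify.PredictionTrace(np.concatenate(truth_all), "truth")
    pred = classify.PredictionTrace(np.concatenate(pred_all), method)
    cm = evaluate.confusion_matrix(truth, pred, classes=config.classes)
    summary = evaluate.summarize(cm)
    return ExperimentResult(summary["accuracy_pct"], cm, truth, pred, model)
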