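"""Signal augmentation and the 168-dimension statistical feature vector.

Six raw channels are augmented to fourteen: each channel's time derivative
("jerk", central differences) and the per-sensor Euclidean norms.  For every
analysis window, six summary statistics (mean, SD, median absolute
deviation, min, max, entropy) are computed on both the raw samples (time
domain) and the one-sided magnitude spectrum of the mean-removed window
(frequency domain), giving 6 stats x 14 signals x 2 domains = 168 features.

Entropy is Shannon entropy (natural log) of the absolute values normalised
to a probability vector — spectral entropy in the frequency domain.  Windows
of any length >= 2 are supported; the spectrum is never zero-padded since
every statistic is a length-agnostic summary.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .sensor_io import CANONICAL_CHANNELS, SensorStream

STATS = ("mean", "std", "mad", "min", "max", "entropy")
DOMAINS = ("time", "freq")

#: 14-channel layout after augmentation
AUGMENTED_CHANNELS = (
    CANONICAL_CHANNELS
    + tuple(f"{c}_jerk" for c in CANONICAL_CHANNELS)
    + ("acc_norm", "gyro_norm")
)

FEATURE_NAMES = tuple(
    f"{ch}_{stat}_{dom}" for ch in AUGMENTED_CHANNELS for dom in DOMAINS for stat in STATS
)


def entropy(v: np.ndarray) -> float:
    """Shannon entropy (natural log) of a non-negative weight vector.

    The vector is normalised to a probability distribution; zero weights
    contribute nothing.  Raises on an all-zero vector.
    """
    v = np.asarray(v, dtype=np.float64)
    if np.any(v < 0):
        raise ValueError("entropy requires non-negative weights")
    total = v.sum()
    if total <= 0:
        raise ValueError("entropy requires at least one positive weight")
    p = v / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _safe_entropy(v: np.ndarray) -> float:
    # degenerate all-zero window (e.g. a constant segment after mean removal)
    # carries no information; report 0 rather than poisoning the matrix
    return 0.0 if v.sum() <= 0 else entropy(v)


def augment_signals(s: SensorStream) -> SensorStream:
    """Augment the 6 canonical channels to 14 (jerks + sensor norms)."""
    if set(s.channels) != set(CANONICAL_CHANNELS):
        raise ValueError(
            f"expected exactly the channels {CANONICAL_CHANNELS}, got {s.channels}"
        )
    x = np.column_stack([s.channel(c) for c in CANONICAL_CHANNELS])
    dt = 1.0 / s.rate_hz
    jerk = np.gradient(x, dt, axis=0) if len(x) > 1 else np.zeros_like(x)
    acc_norm = np.linalg.norm(x[:, 0:3], axis=1)
    gyro_norm = np.linalg.norm(x[:, 3:6], axis=1)
    data = np.column_stack([x, jerk, acc_norm, gyro_norm])
    return SensorStream(s.timestamps.copy(), data, AUGMENTED_CHANNELS, s.rate_hz)


def _stats_block(v: np.ndarray) -> list[float]:
    med = np.median(v)
    return [
        float(v.mean()),
        float(v.std()),
        float(np.median(np.abs(v - med))),
        float(v.min()),
        float(v.max()),
        _safe_entropy(np.abs(v)),
    ]


def segment_features(a: SensorStream, segments: Sequence[tuple[int, int]]) -> pd.DataFrame:
    """168 named features per segment.

    ``segments`` is a list of half-open ``(start, end)`` sample extents; each
    must contain at least 2 samples.  Returns a DataFrame with ``start`` and
    ``end`` columns followed by the 168 feature columns.
    """
    if tuple(a.channels) != AUGMENTED_CHANNELS:
        raise ValueError("segment_features expects an augmented 14-channel stream")
    if len(segments) == 0:
        raise ValueError("empty segmentation")
    rows = []
    for start, end in segments:
        if end - start < 2:
            raise ValueError(f"segment [{start}, {end}) has fewer than 2 samples (SD undefined)")
        seg = a.data[start:end]
        spec = np.abs(np.fft.rfft(seg - seg.mean(axis=0), axis=0))
        row: list[float] = []
        for j in range(seg.shape[1]):
            row.extend(_stats_block(seg[:, j]))
            row.extend(_stats_block(spec[:, j]))
        rows.append([start, end] + row)
    cols = ["start", "end"] + list(FEATURE_NAMES)
    df = pd.DataFrame(rows, columns=cols)
    df[["start", "end"]] = df[["start", "end"]].astype(int)
    if not np.isfinite(df[list(FEATURE_NAMES)].to_numpy()).all():
        raise ValueError("non-finite feature values computed")
    return df
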