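"""Synthetic labeled activity streams with the statistical structure the
segmentation model assumes.

Each activity class is a stationary 6-channel process: a mean vector plus
multivariate Gaussian noise, and — for dynamic activities (walking, stairs,
running) — an additive sinusoid whose per-channel amplitude and frequency
mimic gait oscillation.  Static postures (sitting, standing, lying) differ
mainly in the orientation of gravity across the accelerometer axes, with
deliberately modest separations: a sub-second window sees a noisy estimate
of the class mean, while a multi-second segment pins it down.  That contrast
— short windows noisy, adaptive segments clean — is exactly the regime the
segmentation comparison probes.

The oscillatory term intentionally violates the within-segment i.i.d.
Gaussian assumption, as real gait data do; segmentation must cope.

`shuffle_bouts` implements the unequal-bout construction: each activity
session is cut at uniform-random interior points into ``n_sub`` non-empty
subsessions, all subsessions are shuffled and concatenated, and adjacent
same-activity subsessions merge into single bouts.

`degrade` turns one clean 6-channel stream into a realistic pair of raw
per-sensor files: independent timestamp jitter, a constant inter-sensor
offset, and wholesale missing spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sensor_io import (
    CANONICAL_CHANNELS,
    LabelInterval,
    LabelTrack,
    SensorStream,
    _grid_period_ms,
)

ACTIVITIES = ("sit", "stand", "lie", "walk", "stairs", "run")


@dataclass
class ActivityModel:
    """Stationary generative model for one activity class."""

    name: str
    mean: np.ndarray  # (6,)
    cov: np.ndarray  # (6, 6) SPD
    amplitude: np.ndarray  # (6,) sinusoid amplitude per channel
    freq_hz: float  # 0 for static postures

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        try:
            self._chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"covariance for {self.name!r} is not positive definite") from None


@dataclass
class Protocol:
    """Ordered (activity, duration_s) schedule at a fixed sampling rate."""

    steps: list[tuple[str, float]]
    rate_hz: float
    seed: int | None = None

    def __post_init__(self) -> None:
        for activity, dur in self.steps:
            if dur <= 0:
                raise ValueError(f"non-positive duration for {activity!r}")


def _diag(*sd: float) -> np.ndarray:
    return np.diag(np.square(sd))


def default_models() -> dict[str, ActivityModel]:
    """Six activity classes: 3 static postures and 3 gait-like activities.

    Units: accelerometer in g, gyroscope in rad/s.  Static postures differ
    by gravity orientation with ~0.5-1 noise-SD mean separations; dynamic
    classes differ in oscillation frequency, amplitude and noise level.
    """
    s_acc, s_gyr = 0.10, 0.12
    zero = np.zeros(6)
    return {
        "sit": ActivityModel(
            "sit",
            mean=[0.05, 0.06, 1.00, 0.0, 0.0, 0.0],
            cov=_diag(s_acc, s_acc, s_acc, s_gyr, s_gyr, s_gyr),
            amplitude=zero,
            freq_hz=0.0,
        ),
        "stand": ActivityModel(
            "stand",
            mean=[0.00, 0.00, 1.03, 0.0, 0.0, 0.0],
            cov=_diag(s_acc, s_acc, s_acc, s_gyr, s_gyr, s_gyr),
            amplitude=zero,
            freq_hz=0.0,
        ),
        "lie": ActivityModel(
            "lie",
            mean=[0.90, 0.10, 0.20, 0.0, 0.0, 0.0],
            cov=_diag(s_acc, s_acc, s_acc, s_gyr, s_gyr, s_gyr),
            amplitude=zero,
            freq_hz=0.0,
        ),
        "walk": ActivityModel(
            "walk",
            mean=[0.10, 0.00, 1.00, 0.0, 0.0, 0.0],
            cov=_diag(0.15, 0.15, 0.15, 0.30, 0.30, 0.30),
            amplitude=[0.25, 0.10, 0.25, 0.50, 0.30, 0.20],
            freq_hz=1.6,
        ),
        "stairs": ActivityModel(
            "stairs",
            mean=[0.15, 0.05, 0.95, 0.0, 0.0, 0.0],
            cov=_diag(0.18, 0.18, 0.18, 0.35, 0.35, 0.35),
            amplitude=[0.30, 0.12, 0.30, 0.60, 0.35, 0.25],
            freq_hz=1.3,
        ),
        "run": ActivityModel(
            "run",
            mean=[0.20, 0.00, 1.00, 0.0, 0.0, 0.0],
            cov=_diag(0.30, 0.30, 0.30, 0.50, 0.50, 0.50),
            amplitude=[0.60, 0.20, 0.60, 1.00, 0.50, 0.40],
            freq_hz=2.6,
        ),
    }


def default_protocol(profile: str = "desk") -> Protocol:
    """Shipped schedules.

    - ``breathe``: 5 activities x 600 s + running x 300 s at 10 Hz
      (smartwatch-style session).
    - ``harus``: twelve ~20 s bouts cycling the 6 classes at 50 Hz
      (smartphone-style scripted run).
    - ``desk``: 5 activities x 60 s + running x 30 s at 20 Hz — a
      tractable scaled-down session used by the shipped experiments.
    """
    if profile == "breathe":
        steps = [(a, 600.0) for a in ("stand", "sit", "lie", "walk", "stairs")]
        steps.append(("run", 300.0))
        return Protocol(steps, rate_hz=10.0)
    if profile == "harus":
        order = ("stand", "sit", "lie", "walk", "stairs", "run")
        steps = [(a, 20.0) for a in order] + [(a, 20.0) for a in order]
        return Protocol(steps, rate_hz=50.0)
    if profile == "desk":
        steps = [(a, 60.0) for a in ("stand", "sit", "lie", "walk", "stairs")]
        steps.append(("run", 30.0))
        return Protocol(steps, rate_hz=20.0)
    raise ValueError(f"unknown protocol profile {profile!r}")


def simulate_activity_stream(
    protocol: Protocol,
    models: dict[str, ActivityModel] | None = None,
    seed: int | None = None,
) -> tuple[SensorStream, LabelTrack]:
    """Draw one labeled 6-channel stream following the protocol.

    Per bout of class c:  x_t = mu_c + A_c sin(2 pi f_c t + phi) + eps_t,
    eps_t ~ MVN(0, Sigma_c), with a fresh uniform phase per bout.
    """
    models = models if models is not None else default_models()
    rng = np.random.default_rng(seed if seed is not None else protocol.seed)
    period = _grid_period_ms(protocol.rate_hz)
    blocks: list[np.ndarray] = []
    intervals: list[LabelInterval] = []
    pos = 0
    t_global = 0
    for activity, dur in protocol.steps:
        if activity not in models:
            raise ValueError(f"no model for activity {activity!r}")
        mdl = models[activity]
        n = int(round(dur * protocol.rate_hz))
        t = (t_global + np.arange(n)) / protocol.rate_hz
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = np.sin(2.0 * np.pi * mdl.freq_hz * t + phase)[:, None] * mdl.amplitude[None, :]
        noise = rng.standard_normal((n, 6)) @ mdl._chol.T
        blocks.append(mdl.mean[None, :] + osc + noise)
        intervals.append(LabelInterval(pos, pos + n, activity))
        pos += n
        t_global += n
    data = np.vstack(blocks)
    ts = np.arange(len(data), dtype=np.int64) * period
    stream = SensorStream(ts, data, CANONICAL_CHANNELS, protocol.rate_hz)
    return stream, LabelTrack(intervals)


def subdivide_sessions(
    labels: LabelTrack, n_sub: int = 10, seed: int | None = None
) -> list[LabelInterval]:
    """Cut each labeled session into ``n_sub`` non-empty subsessions.

    Interior cut points are drawn uniformly without replacement over
    admissible sample indices.  Returns the subsession intervals in original
    order (len = n_sessions * n_sub).
    """
    rng = np.random.default_rng(seed)
    out: list[LabelInterval] = []
    for iv in labels:
        length = iv.end - iv.start
        if length < n_sub:
            raise ValueError(
                f"session {iv} has {length} samples, too short for {n_sub} subsessions"
            )
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_sub - 1, replace=False))
        edges = np.concatenate([[0], cuts, [length]])
        for a, b in zip(edges[:-1], edges[1:]):
            out.append(LabelInterval(iv.start + int(a), iv.start + int(b), iv.activity))
    return out


def shuffle_bouts(
    stream: SensorStream,
    labels: LabelTrack,
    n_sub: int = 10,
    seed: int | None = None,
) -> tuple[SensorStream, LabelTrack]:
    """Subdivide every session into ``n_sub`` subsessions, shuffle all of
    them uniformly, and concatenate.

    Sample count is conserved; timestamps are regenerated on the nominal
    grid (shuffling has no physical timeline).  Adjacent same-activity
    subsessions merge in the output track, so the result may have fewer
    distinct bouts than subsessions.
    """
    rng = np.random.default_rng(seed)
    blocks = subdivide_sessions(labels, n_sub=n_sub, seed=rng.integers(2**31))
    order = rng.permutation(len(blocks))
    data = np.vstack([stream.data[blocks[i].start : blocks[i].end] for i in order])
    period = _grid_period_ms(stream.rate_hz)
    ts = np.arange(len(data), dtype=np.int64) * period
    out_stream = SensorStream(ts, data, stream.channels, stream.rate_hz)

    intervals: list[LabelInterval] = []
    pos = 0
    for i in order:
        blk = blocks[i]
        n = blk.end - blk.start
        if intervals and intervals[-1].activity == blk.activity and intervals[-1].end == pos:
            intervals[-1] = LabelInterval(intervals[-1].start, pos + n, blk.activity)
        else:
            intervals.append(LabelInterval(pos, pos + n, blk.activity))
        pos += n
    return out_stream, LabelTrack(intervals)


def degrade(
    stream: SensorStream,
    jitter_ms: float = 0.0,
    missing_spans: tuple[int, float] | None = None,
    sensor_offset_ms: float = 0.0,
    seed: int | None = None,
) -> tuple[SensorStream, SensorStream]:
    """Split a clean 6-channel stream into raw per-sensor acc/gyro streams
    with acquisition artifacts.

    ``jitter_ms`` — SD of independent Gaussian timestamp jitter per sensor;
    ``missing_spans`` — ``(count, mean_s)`` wholesale spans removed from both
    sensors (lengths uniform in [0.75, 1.25] x mean_s);
    ``sensor_offset_ms`` — constant shift added to the gyro timestamps.
    """
    rng = np.random.default_rng(seed)
    keep = np.ones(stream.n_samples, dtype=bool)
    if missing_spans is not None:
        count, mean_s = missing_spans
        total_needed = count * 1.25 * mean_s * stream.rate_hz
        if total_needed >= stream.n_samples:
            raise ValueError("requested missing spans exceed the stream length")
        placed = 0
        guard = 0
        span_bounds: list[tuple[int, int]] = []
        while placed < count and guard < 1000:
            guard += 1
            length = int(round(rng.uniform(0.75, 1.25) * mean_s * stream.rate_hz))
            length = max(length, 1)
            start = int(rng.integers(0, stream.n_samples - length))
            pad = int(stream.rate_hz)  # keep spans separated by >= 1 s
            if any(start < e + pad and s - pad < start + length for s, e in span_bounds):
                continue
            span_bounds.append((start, start + length))
            keep[start : start + length] = False
            placed += 1
        if placed < count:
            raise ValueError("could not place the requested missing spans")

    out: list[SensorStream] = []
    for cols, offset in (((0, 3), 0.0), ((3, 6), sensor_offset_ms)):
        ts = stream.timestamps[keep].astype(np.float64) + offset
        if jitter_ms > 0:
            ts = ts + rng.normal(0.0, jitter_ms, size=len(ts))
        ts = np.round(ts).astype(np.int64)
        order = np.argsort(ts, kind="stable")
        ts, data = ts[order], stream.data[keep][:, cols[0] : cols[1]][order]
        # collapse any jitter-induced timestamp collisions by averaging
        uniq, inverse, counts = np.unique(ts, return_inverse=True, return_counts=True)
        if len(uniq) < len(ts):
            sums = np.zeros((len(uniq), data.shape[1]))
            np.add.at(sums, inverse, data)
            data = sums / counts[:, None]
            ts = uniq
        out.append(
            SensorStream(ts, data, stream.channels[cols[0] : cols[1]], stream.rate_hz)
        )
    return out[0], out[1]
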