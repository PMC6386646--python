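"""Sensor stream containers and file IO.

Wearable devices deliver two triaxial streams (accelerometer, gyroscope)
whose timestamps drift, collide and go missing.  This module reads the raw
delimited files, snaps both sensors onto a common fixed-rate grid (default
50 Hz, i.e. 20 ms spacing), fills the resulting per-sample holes with local
least-squares lines, and cuts the record wherever all channels are missing
for more than a configurable gap.

Timestamps are integer milliseconds throughout; the grid is anchored at the
first sample's floor-to-grid time so that re-runs are bit-reproducible.
Indices are 0-based and every interval is half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical 6-channel layout produced by a paired accelerometer + gyroscope
CANONICAL_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")


class SensorIOError(Exception):
    """Malformed sensor/label file or inconsistent stream."""


@dataclass
class SensorStream:
    """Time-stamped multichannel real-valued series.

    Parameters
    ----------
    timestamps
        int64 milliseconds, strictly increasing.
    data
        float64 array of shape ``(n_samples, n_channels)``.
    channels
        channel names, one per data column.
    rate_hz
        nominal sampling rate (> 0).
    """

    timestamps: np.ndarray
    data: np.ndarray
    channels: tuple[str, ...]
    rate_hz: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        self.channels = tuple(self.channels)
        if self.data.shape[0] != self.timestamps.shape[0]:
            raise SensorIOError(
                f"data has {self.data.shape[0]} rows but {len(self.timestamps)} timestamps"
            )
        if self.data.shape[1] != len(self.channels):
            raise SensorIOError(
                f"data has {self.data.shape[1]} columns for {len(self.channels)} channel names"
            )
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise SensorIOError("timestamps must be strictly increasing")
        if not self.rate_hz > 0:
            raise SensorIOError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) / 1000.0

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[:, self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel {name!r}; have {self.channels}") from None

    def with_data(self, data: np.ndarray, channels: Sequence[str] | None = None) -> "SensorStream":
        return SensorStream(
            self.timestamps.copy(),
            data,
            tuple(channels) if channels is not None else self.channels,
            self.rate_hz,
        )


@dataclass
class GriddedStream:
    """A :class:`SensorStream` on an exact fixed-rate grid plus a missing mask.

    ``missing[i, j]`` is True where grid point ``i`` received no sample for
    channel ``j``.  Consecutive timestamps differ by exactly the grid period.
    """

    stream: SensorStream
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.stream.data.shape:
            raise SensorIOError("missing mask shape must match data shape")
        period = _grid_period_ms(self.stream.rate_hz)
        ts = self.stream.timestamps
        if len(ts) > 1 and not np.all(np.diff(ts) == period):
            raise SensorIOError("gridded timestamps must advance by exactly one grid period")

    @property
    def grid_period_ms(self) -> int:
        return _grid_period_ms(self.stream.rate_hz)

    @property
    def missing_fraction(self) -> float:
        return float(self.missing.mean())


@dataclass(frozen=True)
class LabelInterval:
    start: int
    end: int
    activity: str


@dataclass
class LabelTrack:
    """Ordered, non-overlapping activity intervals over sample indices."""

    intervals: list[LabelInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = [
            iv if isinstance(iv, LabelInterval) else LabelInterval(*iv) for iv in self.intervals
        ]
        self.intervals.sort(key=lambda iv: iv.start)
        for iv in self.intervals:
            if iv.end <= iv.start:
                raise SensorIOError(f"empty interval {iv}")
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise SensorIOError(f"overlapping intervals {a} and {b}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def activities(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.activity, None)
        return list(seen)

    def to_sample_labels(self, n_samples: int) -> np.ndarray:
        """Per-sample label array (object dtype); unlabeled spans are None."""
        out = np.full(n_samples, None, dtype=object)
        for iv in self.intervals:
            out[iv.start : min(iv.end, n_samples)] = iv.activity
        return out

    def shifted(self, offset: int) -> "LabelTrack":
        return LabelTrack(
            [LabelInterval(iv.start + offset, iv.end + offset, iv.activity) for iv in self.intervals]
        )


def _grid_period_ms(grid_hz: float) -> int:
    period = 1000.0 / grid_hz
    if abs(period - round(period)) > 1e-9:
        raise SensorIOError(f"grid rate {grid_hz} Hz has a non-integer millisecond period")
    return int(round(period))


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def _sniff_delimiter(header: str) -> str:
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_sensor_stream(
    path: str | Path,
    dialect: str = "simple",
    *,
    rate_hz: float = 50.0,
    sensor: str | None = None,
) -> SensorStream:
    """Read a sensor file.

    ``simple`` dialect: delimited text (comma or tab), header row with
    ``timestamp_ms`` followed by channel names.  Rows are sorted by timestamp
    and duplicated timestamps are averaged (with a logged warning).

    ``harus_raw`` dialect: three space-separated columns at a fixed rate with
    no timestamps; timestamps are synthesized from ``rate_hz`` and channels
    named from ``sensor`` ("acc" or "gyro", guessed from the filename if not
    given).
    """
    path = Path(path)
    if dialect == "simple":
        return _read_simple(path)
    if dialect == "harus_raw":
        return _read_harus_raw(path, rate_hz=rate_hz, sensor=sensor)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_simple(path: Path) -> SensorStream:
    lines = path.read_text().splitlines()
    if not lines:
        raise SensorIOError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    if header[0] != "timestamp_ms":
        raise SensorIOError(f"{path}: first column must be timestamp_ms, got {header[0]!r}")
    channels = tuple(header[1:])
    ts: list[int] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(delim)
        if len(parts) != len(header):
            raise SensorIOError(f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}")
        try:
            ts.append(int(round(float(parts[0]))))
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise SensorIOError(f"{path}:{lineno}: {exc}") from None
    if not ts:
        raise SensorIOError(f"{path}: no data rows")
    t = np.asarray(ts, dtype=np.int64)
    x = np.asarray(rows, dtype=np.float64)
    order = np.argsort(t, kind="stable")
    t, x = t[order], x[order]
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    if len(uniq) < len(t):
        logger.warning("%s: %d duplicated timestamps averaged", path, len(t) - len(uniq))
        sums = np.zeros((len(uniq), x.shape[1]))
        np.add.at(sums, inverse, x)
        x = sums / counts[:, None]
        t = uniq
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise SensorIOError(f"{path}: timestamps not strictly increasing after dedup")
    rate = _infer_rate(t)
    return SensorStream(t, x, channels, rate)


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        return 50.0
    dt = float(np.median(np.diff(t)))
    return 1000.0 / dt if dt > 0 else 50.0


def _read_harus_raw(path: Path, rate_hz: float, sensor: str | None) -> SensorStream:
    if sensor is None:
        name = path.name.lower()
        sensor = "acc" if "acc" in name else "gyro" if "gyro" in name else None
        if sensor is None:
            raise SensorIOError(f"{path}: cannot infer sensor kind; pass sensor='acc'|'gyro'")
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise SensorIOError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise SensorIOError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise SensorIOError(f"{path}: no data rows")
    period = _grid_period_ms(rate_hz)
    t = np.arange(len(rows), dtype=np.int64) * period
    channels = tuple(f"{sensor}_{axis}" for axis in "xyz")
    return SensorStream(t, np.asarray(rows), channels, rate_hz)


def write_sensor_stream(stream: SensorStream, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(("timestamp_ms",) + stream.channels) + "\n")
        for t, row in zip(stream.timestamps, stream.data):
            fh.write(delimiter.join([str(int(t))] + [repr(float(v)) for v in row]) + "\n")


def read_labels(
    path: str | Path,
    dialect: str = "interval_table",
    *,
    activity_names: dict[int, str] | None = None,
    experiment: int | None = None,
    user: int | None = None,
) -> LabelTrack:
    """Read an activity label file.

    ``interval_table``: delimited text with header ``start\tend\tactivity``.
    ``harus_raw``: 5 integer columns (experiment, user, activity_id,
    start_sample, end_sample); rows are filtered to ``experiment``/``user``
    when given, and activity ids are mapped through ``activity_names``.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    intervals: list[LabelInterval] = []
    if dialect == "interval_table":
        if not lines:
            return LabelTrack([])
        delim = _sniff_delimiter(lines[0])
        body = lines[1:] if lines[0].split(delim)[0].strip() in ("start", "start_idx") else lines
        for lineno, line in enumerate(body, start=1):
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) != 3:
                raise SensorIOError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                intervals.append(LabelInterval(int(parts[0]), int(parts[1]), parts[2]))
            except ValueError as exc:
                raise SensorIOError(f"{path}:{lineno}: {exc}") from None
    elif dialect == "harus_raw":
        for lineno, line in enumerate(lines, start=1):
            parts = line.split()
            if len(parts) != 5:
                raise SensorIOError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            exp, usr, act, start, end = (int(p) for p in parts)
            if experiment is not None and exp != experiment:
                continue
            if user is not None and usr != user:
                continue
            if activity_names is not None:
                if act not in activity_names:
                    raise SensorIOError(
                        f"{path}:{lineno}: unknown activity id {act}; known: {sorted(activity_names)}"
                    )
                label = activity_names[act]
            else:
                label = str(act)
            # HARuS end_sample is inclusive; convert to half-open
            intervals.append(LabelInterval(start, end + 1, label))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return LabelTrack(intervals)


def write_labels(track: LabelTrack, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(("start", "end", "activity")) + "\n")
        for iv in track:
            fh.write(delimiter.join((str(iv.start), str(iv.end), iv.activity)) + "\n")


# ---------------------------------------------------------------------------
# gridding, interpolation, gap truncation, alignment
# ---------------------------------------------------------------------------


def snap_to_grid(
    stream: SensorStream,
    grid_hz: float = 50.0,
    *,
    t_start: int | None = None,
    t_end: int | None = None,
) -> GriddedStream:
    """Assign every sample to its nearest point on an exact ``grid_hz`` grid.

    Grid points receiving no sample are masked missing; points receiving
    several samples hold their mean; ties in "nearest" go to the earlier grid
    point.  The grid is anchored at the floor-to-grid of the first covered
    timestamp, so the same input always yields the same grid.
    """
    if stream.n_samples == 0:
        raise SensorIOError("cannot grid an empty stream")
    period = _grid_period_ms(grid_hz)
    t0 = int(stream.timestamps[0]) if t_start is None else int(t_start)
    anchor = (t0 // period) * period
    if t_end is None:
        # cover the last sample's full nominal period so that ideal r Hz
        # input yields a missing fraction of exactly 1 - r/grid_hz
        nominal = _grid_period_ms(stream.rate_hz)
        t1 = int(stream.timestamps[-1]) + nominal
        n_grid = int(-(-(t1 - anchor) // period))  # ceil, half-open end
    else:
        n_grid = int(int(t_end) - anchor) // period + 1
    off = stream.timestamps - anchor
    idx = (2 * off + period - 1) // (2 * period)  # round half down -> earlier point
    keep = (idx >= 0) & (idx < n_grid)
    idx = idx[keep].astype(np.intp)
    data = stream.data[keep]

    n_ch = data.shape[1]
    sums = np.zeros((n_grid, n_ch))
    counts = np.zeros((n_grid, n_ch))
    finite = np.isfinite(data)
    np.add.at(sums, idx, np.where(finite, data, 0.0))
    np.add.at(counts, idx, finite.astype(float))
    missing = counts == 0
    values = np.divide(sums, counts, out=np.zeros_like(sums), where=~missing)
    ts = anchor + np.arange(n_grid, dtype=np.int64) * period
    gridded = SensorStream(ts, values, stream.channels, grid_hz)
    return GriddedStream(gridded, missing)


def _fit_local_line(t: np.ndarray, y: np.ndarray) -> float:
    """OLS line through (t, y) evaluated at t=0; degenerate cases fall back."""
    if len(t) == 1:
        return float(y[0])
    tbar = t.mean()
    ybar = y.mean()
    denom = np.sum((t - tbar) ** 2)
    if denom == 0.0:
        return float(ybar)
    slope = np.sum((t - tbar) * (y - ybar)) / denom
    return float(ybar - slope * tbar)


def interpolate_missing(g: GriddedStream, side_window: int = 5) -> SensorStream:
    """Fill masked grid points channel-wise from local least-squares lines.

    Each missing point is estimated by an ordinary least-squares line fitted
    through up to ``side_window`` non-missing neighbours on each side
    (fewer at stream edges), evaluated at the missing timestamp.  Non-missing
    values are untouched; a second application is a no-op.
    """
    values = g.stream.data.copy()
    ts = g.stream.timestamps.astype(np.float64)
    for j, name in enumerate(g.stream.channels):
        miss = g.missing[:, j]
        if not miss.any():
            continue
        nm = np.flatnonzero(~miss)
        if len(nm) < 2:
            raise SensorIOError(f"channel {name!r} has fewer than 2 non-missing samples")
        col = values[:, j]
        positions = np.searchsorted(nm, np.flatnonzero(miss))
        for i, pos in zip(np.flatnonzero(miss), positions):
            left = nm[max(0, pos - side_window) : pos]
            right = nm[pos : pos + side_window]
            pts = np.concatenate([left, right])
            values[i, j] = _fit_local_line(ts[pts] - ts[i], col[pts])
    return g.stream.with_data(values)


def truncate_gaps(g: GriddedStream, max_gap_s: float = 10.0) -> list[GriddedStream]:
    """Split at runs of all-channel-missing grid points strictly longer than
    ``max_gap_s``; the gap samples themselves are discarded."""
    all_missing = g.missing.all(axis=1)
    period = g.grid_period_ms
    max_run = int(max_gap_s * 1000 / period)  # split when run length > max_run
    n = len(all_missing)
    chunks: list[GriddedStream] = []
    # find runs of all-missing
    cut_spans: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if all_missing[i]:
            j = i
            while j < n and all_missing[j]:
                j += 1
            if j - i > max_run:
                cut_spans.append((i, j))
            i = j
        else:
            i += 1
    start = 0
    for a, b in cut_spans + [(n, n)]:
        if a > start:
            sub = SensorStream(
                g.stream.timestamps[start:a],
                g.stream.data[start:a],
                g.stream.channels,
                g.stream.rate_hz,
            )
            chunks.append(GriddedStream(sub, g.missing[start:a]))
        start = b
    return chunks


def align_sensors(
    acc: SensorStream, gyro: SensorStream, grid_hz: float = 50.0, side_window: int = 5
) -> GriddedStream:
    """Snap both sensors onto a common grid over their temporal overlap,
    interpolate per-sensor holes, and merge into one 6-channel stream.

    The returned :class:`GriddedStream` keeps the pre-fill missing mask so the
    caller can apply :func:`truncate_gaps` afterwards.
    """
    lo = max(int(acc.timestamps[0]), int(gyro.timestamps[0]))
    hi = min(int(acc.timestamps[-1]), int(gyro.timestamps[-1]))
    if hi <= lo:
        raise SensorIOError(
            "no temporal overlap: "
            f"acc covers [{acc.timestamps[0]}, {acc.timestamps[-1]}] ms, "
            f"gyro covers [{gyro.timestamps[0]}, {gyro.timestamps[-1]}] ms"
        )
    parts = []
    masks = []
    channels: tuple[str, ...] = ()
    for s in (acc, gyro):
        g = snap_to_grid(s, grid_hz, t_start=lo, t_end=hi)
        filled = interpolate_missing(g, side_window=side_window)
        parts.append(filled.data)
        masks.append(g.missing)
        channels = channels + filled.channels
    merged = SensorStream(
        snap_to_grid(acc, grid_hz, t_start=lo, t_end=hi).stream.timestamps,
        np.hstack(parts),
        channels,
        grid_hz,
    )
    return GriddedStream(merged, np.hstack(masks))
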