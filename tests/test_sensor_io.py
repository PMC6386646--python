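"""Reading, gridding, interpolation, gap truncation and sensor alignment."""

import numpy as np
import pytest

from har import (
    GriddedStream,
    LabelTrack,
    SensorStream,
    align_sensors,
    interpolate_missing,
    read_labels,
    read_sensor_stream,
    snap_to_grid,
    truncate_gaps,
    write_labels,
    write_sensor_stream,
)
from har.sensor_io import SensorIOError

from conftest import make_stream


class TestReadWrite:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("timestamp_ms\tacc_x\tacc_y\n0\t1.5\t2.0\n20\t2.5\t3.0\n40\t3.5\t4.0\n")
        s = read_sensor_stream(p)
        assert s.n_samples == 3
        assert s.channels == ("acc_x", "acc_y")
        np.testing.assert_allclose(s.channel("acc_x"), [1.5, 2.5, 3.5])

    def test_duplicate_timestamps_averaged(self, tmp_path, caplog):
        p = tmp_path / "s.tsv"
        p.write_text("timestamp_ms\tacc_x\n0\t1.0\n20\t2.0\n20\t4.0\n")
        with caplog.at_level("WARNING"):
            s = read_sensor_stream(p)
        assert s.n_samples == 2
        np.testing.assert_allclose(s.channel("acc_x"), [1.0, 3.0])
        assert any("duplicated" in r.message for r in caplog.records)

    def test_roundtrip(self, tmp_path, rng):
        s = make_stream(rng.standard_normal((50, 6)))
        write_sensor_stream(s, tmp_path / "s.tsv")
        back = read_sensor_stream(tmp_path / "s.tsv")
        np.testing.assert_array_equal(back.timestamps, s.timestamps)
        np.testing.assert_allclose(back.data, s.data)
        assert back.channels == s.channels

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("timestamp_ms\tacc_x\n0\t1.0\n20\tnope_a_number_x\n")
        with pytest.raises(SensorIOError, match=":3"):
            read_sensor_stream(p)

    def test_harus_raw_synthesizes_timestamps(self, tmp_path):
        p = tmp_path / "acc_exp01_user01.txt"
        p.write_text("1.0 2.0 3.0\n4.0 5.0 6.0\n")
        s = read_sensor_stream(p, dialect="harus_raw", rate_hz=50.0)
        assert s.channels == ("acc_x", "acc_y", "acc_z")
        np.testing.assert_array_equal(s.timestamps, [0, 20])


class TestLabels:
    def test_interval_table(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("start\tend\tactivity\n0\t100\twalk\n100\t200\tsit\n")
        track = read_labels(p)
        assert len(track) == 2
        assert track.intervals[0].activity == "walk"

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("start\tend\tactivity\n0\t100\twalk\n50\t150\tsit\n")
        with pytest.raises(SensorIOError, match="overlap"):
            read_labels(p)

    def test_empty_file_is_valid_empty_track(self, tmp_path):
        p = tmp_path / "l.tsv"
        p.write_text("")
        assert len(read_labels(p)) == 0

    def test_harus_unknown_activity_id(self, tmp_path):
        p = tmp_path / "labels.txt"
        p.write_text("1 1 99 0 100\n")
        with pytest.raises(SensorIOError, match="unknown activity id 99"):
            read_labels(p, dialect="harus_raw", activity_names={1: "walk"})

    def test_roundtrip(self, tmp_path):
        track = LabelTrack([(0, 50, "walk"), (50, 80, "sit")])
        write_labels(track, tmp_path / "l.tsv")
        back = read_labels(tmp_path / "l.tsv")
        assert [(iv.start, iv.end, iv.activity) for iv in back] == [
            (0, 50, "walk"),
            (50, 80, "sit"),
        ]


class TestSnapToGrid:
    def test_ideal_10hz_to_50hz_is_80pct_missing(self):
        # 10 Hz samples land exactly on every 5th 50 Hz grid point
        s = make_stream(np.ones((100, 1)), rate_hz=10.0, channels=("acc_x",))
        g = snap_to_grid(s, grid_hz=50.0)
        assert g.missing_fraction == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("r", [5, 10, 25])
    def test_missing_fraction_formula(self, r):
        s = make_stream(np.ones((60, 1)), rate_hz=float(r), channels=("acc_x",))
        g = snap_to_grid(s, grid_hz=50.0)
        assert g.missing_fraction == pytest.approx(1 - r / 50, abs=1e-9)

    def test_already_on_grid_unchanged(self, rng):
        s = make_stream(rng.standard_normal((40, 2)), rate_hz=50.0)
        g = snap_to_grid(s, grid_hz=50.0)
        assert g.missing_fraction == 0.0
        np.testing.assert_allclose(g.stream.data, s.data)

    def test_collision_averaged_and_tie_goes_earlier(self):
        # 8 ms and 12 ms are both nearest to grid point 20... no: nearest to 0 and 20
        ts = np.array([0, 8, 12], dtype=np.int64)
        data = np.array([[1.0], [3.0], [5.0]])
        s = SensorStream(ts, data, ("acc_x",), 50.0)
        g = snap_to_grid(s, grid_hz=50.0)
        # 8 -> grid 0 (8 < 10), 12 -> grid 20: values (1+3)/2 at 0... 8ms rounds to 0
        np.testing.assert_allclose(g.stream.data[0, 0], 2.0)
        np.testing.assert_allclose(g.stream.data[1, 0], 5.0)
        # exact tie at 10 ms goes to the earlier grid point
        s2 = SensorStream(np.array([0, 10]), np.array([[1.0], [9.0]]), ("acc_x",), 50.0)
        g2 = snap_to_grid(s2, grid_hz=50.0)
        np.testing.assert_allclose(g2.stream.data[0, 0], 5.0)
        assert bool(g2.missing[1, 0]) if g2.missing.shape[0] > 1 else True

    def test_mass_conservation(self, rng):
        ts = np.sort(rng.choice(np.arange(0, 2000), size=60, replace=False)).astype(np.int64)
        s = SensorStream(ts, rng.standard_normal((60, 2)), ("acc_x", "acc_y"), 50.0)
        g = snap_to_grid(s, grid_hz=50.0)
        assert (~g.missing[:, 0]).sum() <= s.n_samples


class TestInterpolateMissing:
    def test_linear_ramp_recovered_exactly(self):
        n = 50
        vals = np.linspace(0.0, 10.0, n)[:, None]
        missing = np.zeros((n, 1), dtype=bool)
        missing[7:12] = True
        missing[30] = True
        g = GriddedStream(make_stream(vals, channels=("acc_x",)), missing)
        filled = interpolate_missing(g)
        np.testing.assert_allclose(filled.data[:, 0], vals[:, 0], atol=1e-9)

    def test_no_mask_is_identity(self, rng):
        vals = rng.standard_normal((30, 2))
        g = GriddedStream(make_stream(vals), np.zeros((30, 2), bool))
        filled = interpolate_missing(g)
        np.testing.assert_array_equal(filled.data, vals)

    def test_matches_bruteforce_local_line_oracle(self, rng):
        n = 200
        t = np.arange(n, dtype=float)
        vals = (0.02 * t**2 - t + 3)[:, None]
        missing = np.zeros((n, 1), bool)
        missing[rng.choice(n, size=60, replace=False)] = True
        g = GriddedStream(make_stream(vals, channels=("acc_x",)), missing)
        filled = interpolate_missing(g, side_window=5)

        ts = g.stream.timestamps.astype(float)
        nm = np.flatnonzero(~missing[:, 0])
        for i in np.flatnonzero(missing[:, 0]):
            left = nm[nm < i][-5:]
            right = nm[nm > i][:5]
            pts = np.concatenate([left, right])
            # independent oracle: polyfit line through the neighbour points
            coef = np.polyfit(ts[pts], vals[pts, 0], 1)
            expect = np.polyval(coef, ts[i])
            assert filled.data[i, 0] == pytest.approx(expect, abs=1e-8)

    def test_idempotent(self, rng):
        vals = rng.standard_normal((40, 1))
        missing = np.zeros((40, 1), bool)
        missing[5:9] = True
        g = GriddedStream(make_stream(vals, channels=("acc_x",)), missing)
        once = interpolate_missing(g)
        twice = interpolate_missing(GriddedStream(once, np.zeros((40, 1), bool)))
        np.testing.assert_array_equal(once.data, twice.data)

    def test_fully_missing_channel_errors(self):
        g = GriddedStream(make_stream(np.zeros((10, 1)), channels=("acc_x",)), np.ones((10, 1), bool))
        with pytest.raises(SensorIOError, match="acc_x"):
            interpolate_missing(g)


class TestTruncateGaps:
    def _gridded(self, n, missing_runs, rate=50.0):
        missing = np.zeros((n, 1), bool)
        for a, b in missing_runs:
            missing[a:b] = True
        return GriddedStream(make_stream(np.ones((n, 1)), rate_hz=rate, channels=("acc_x",)), missing)

    def test_no_long_gap_single_chunk(self):
        g = self._gridded(100, [(10, 20)])
        chunks = truncate_gaps(g, max_gap_s=10.0)
        assert len(chunks) == 1
        assert chunks[0].stream.n_samples == 100

    def test_eleven_second_gap_splits(self):
        # 11 s at 50 Hz = 550 all-missing points
        g = self._gridded(2000, [(600, 1150)])
        chunks = truncate_gaps(g, max_gap_s=10.0)
        assert len(chunks) == 2
        assert sum(c.stream.n_samples for c in chunks) == 2000 - 550

    def test_exactly_ten_seconds_not_split(self):
        g = self._gridded(2000, [(600, 1100)])  # exactly 500 points = 10.0 s
        assert len(truncate_gaps(g, max_gap_s=10.0)) == 1

    def test_chunks_reproduce_input_mask(self):
        g = self._gridded(3000, [(0, 600), (1000, 1551), (2990, 3000)])
        chunks = truncate_gaps(g, max_gap_s=10.0)
        rebuilt = np.ones(3000, bool)  # gaps default missing
        for c in chunks:
            i0 = int((c.stream.timestamps[0] - g.stream.timestamps[0]) // g.grid_period_ms)
            rebuilt[i0 : i0 + c.stream.n_samples] = c.missing[:, 0]
        np.testing.assert_array_equal(rebuilt, g.missing[:, 0])


class TestAlignSensors:
    def test_identical_timestamps_is_column_concat(self, rng):
        acc = make_stream(rng.standard_normal((100, 3)), channels=("acc_x", "acc_y", "acc_z"))
        gyro = make_stream(rng.standard_normal((100, 3)), channels=("gyro_x", "gyro_y", "gyro_z"))
        merged = align_sensors(acc, gyro)
        assert merged.stream.channels == (
            "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z",
        )
        np.testing.assert_allclose(merged.stream.data[:, :3], acc.data)
        np.testing.assert_allclose(merged.stream.data[:, 3:], gyro.data)

    def test_shifted_gyro_snaps_to_common_grid(self, rng):
        acc = make_stream(rng.standard_normal((100, 3)), channels=("acc_x", "acc_y", "acc_z"))
        gyro_ts = acc.timestamps + 7
        gyro = SensorStream(
            gyro_ts, rng.standard_normal((100, 3)), ("gyro_x", "gyro_y", "gyro_z"), 50.0
        )
        merged = align_sensors(acc, gyro)
        diffs = np.diff(merged.stream.timestamps)
        assert (diffs == 20).all()

    def test_no_overlap_errors_with_both_ranges(self):
        acc = make_stream(np.ones((10, 3)), channels=("acc_x", "acc_y", "acc_z"))
        gyro = SensorStream(
            np.arange(10, dtype=np.int64) * 20 + 100000,
            np.ones((10, 3)),
            ("gyro_x", "gyro_y", "gyro_z"),
            50.0,
        )
        with pytest.raises(SensorIOError, match="overlap"):
            align_sensors(acc, gyro)
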