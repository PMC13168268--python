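"""Event data model, file round trips, segmentation and feature preprocessing."""

import numpy as np
import pytest

from hdflow import events as ev
from hdflow.exceptions import (
    ArgumentError,
    BoundsError,
    EventParseError,
    WindowError,
)

from conftest import random_stream


# ---------------------------------------------------------------------------
# CSV / HDF5 I/O
# ---------------------------------------------------------------------------


class TestEventCsv:
    def test_three_row_transcription(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("t,x,y,p\n0,1,1,1\n5,2,0,0\n5,0,0,1\n")
        s = ev.read_event_csv(path, (4, 4))
        assert len(s) == 3
        assert list(s.p) == [1, -1, 1]
        assert list(s.t) == [0, 5, 5]

    def test_header_only_gives_empty_stream(self, tmp_path):
        path = tmp_path / "ev.csv"
        path.write_text("t,x,y,p\n")
        assert len(ev.read_event_csv(path, (4, 4))) == 0

    def test_unsorted_rows_match_reference_stable_sort(self, tmp_path, rng):
        rows = [
            (int(rng.integers(0, 50)), int(rng.integers(0, 4)), int(rng.integers(0, 4)), int(rng.integers(0, 2)))
            for _ in range(60)
        ]
        path = tmp_path / "ev.csv"
        path.write_text("t,x,y,p\n" + "\n".join(",".join(map(str, r)) for r in rows) + "\n")
        s = ev.read_event_csv(path, (4, 4))
        # independent oracle: python's stable sort on the raw rows
        expected = sorted(rows, key=lambda r: r[0])
        assert list(s.t) == [r[0] for r in expected]
        assert list(s.x) == [r[1] for r in expected]
        assert list(s.y) == [r[2] for r in expected]
        assert [1 if v == 1 else -1 for v in (r[3] for r in expected)] == list(s.p)

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,x,y,p\n0,1,1,1\n5,zap,0,0\n")
        with pytest.raises(EventParseError, match="line 3"):
            ev.read_event_csv(path, (4, 4))

    def test_bad_polarity_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,x,y,p\n0,1,1,7\n")
        with pytest.raises(EventParseError, match="polarity"):
            ev.read_event_csv(path, (4, 4))

    def test_out_of_bounds_coordinate_rejected(self, tmp_path):
        path = tmp_path / "oob.csv"
        path.write_text("t,x,y,p\n0,9,1,1\n")
        with pytest.raises(BoundsError, match="line 2"):
            ev.read_event_csv(path, (4, 4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, seed):
        s = random_stream(np.random.default_rng(seed))
        path = tmp_path / "rt.csv"
        ev.write_event_csv(s, path)
        assert ev.read_event_csv(path, (s.sensor_width, s.sensor_height)) == s

    def test_empty_stream_round_trip(self, tmp_path):
        empty = np.empty(0, dtype=np.int64)
        s = ev.EventStream(4, 4, empty, empty, empty, empty.astype(np.int8))
        path = tmp_path / "empty.csv"
        ev.write_event_csv(s, path)
        assert path.read_text().splitlines()[0] == "t,x,y,p"
        assert ev.read_event_csv(path, (4, 4)) == s

    def test_duplicate_timestamps_preserve_order(self, tmp_path):
        t = np.array([3, 3, 3, 3])
        x = np.array([0, 1, 2, 3])
        y = np.array([0, 0, 0, 0])
        p = np.array([1, -1, 1, -1], dtype=np.int8)
        s = ev.EventStream(4, 4, t, x, y, p)
        path = tmp_path / "dup.csv"
        ev.write_event_csv(s, path)
        assert ev.read_event_csv(path, (4, 4)) == s


class TestEventH5:
    @pytest.mark.parametrize("seed", [3, 4])
    def test_round_trip_identity(self, tmp_path, seed):
        s = random_stream(np.random.default_rng(seed))
        path = tmp_path / "rt.h5"
        ev.write_event_h5(s, path)
        assert ev.read_event_h5(path) == s


class TestEventStreamInvariants:
    def test_rejects_decreasing_time(self):
        with pytest.raises(ArgumentError):
            ev.EventStream(4, 4, [5, 3], [0, 0], [0, 0], [1, 1])

    def test_rejects_out_of_bounds(self):
        with pytest.raises(BoundsError):
            ev.EventStream(4, 4, [0], [4], [0], [1])

    def test_rejects_bad_polarity(self):
        with pytest.raises(ArgumentError):
            ev.EventStream(4, 4, [0], [0], [0], [2])


# ---------------------------------------------------------------------------
# Transit segmentation
# ---------------------------------------------------------------------------


def _bin_histogram_windows(stream, bin_us, min_rate, min_gap):
    """Independent hand-rolled oracle: count per bin, scan runs, merge gaps."""
    if len(stream) == 0:
        return []
    t0 = int(stream.t[0])
    nbins = (int(stream.t[-1]) - t0) // bin_us + 1
    counts = [0] * nbins
    for t in stream.t:
        counts[(int(t) - t0) // bin_us] += 1
    windows = []
    cur = None
    quiet = 0
    for i, c in enumerate(counts):
        if c >= min_rate:
            if cur is None:
                cur = [i, i + 1]
            elif quiet < min_gap:
                cur[1] = i + 1
            else:
                windows.append(cur)
                cur = [i, i + 1]
            quiet = 0
        else:
            quiet += 1
    if cur is not None:
        windows.append(cur)
    return [(t0 + a * bin_us, t0 + b * bin_us) for a, b in windows]


class TestSegmentTransits:
    def test_single_burst(self, rng):
        t = np.sort(rng.integers(50_000, 52_000, size=500))
        s = ev.EventStream(8, 8, t, np.zeros(500, int), np.zeros(500, int), np.ones(500, np.int8))
        wins = ev.segment_transits(s, bin_us=100, min_rate=5)
        assert wins == _bin_histogram_windows(s, 100, 5, 1)
        assert len(wins) == 1
        (a, b), = wins
        assert a <= t[0] < t[-1] < b

    def test_sparse_background_yields_nothing(self):
        t = np.arange(0, 100_000, 1000)
        n = t.size
        s = ev.EventStream(8, 8, t, np.zeros(n, int), np.zeros(n, int), np.ones(n, np.int8))
        assert ev.segment_transits(s, bin_us=100, min_rate=5) == []

    def test_two_bursts_separated_by_gap(self, rng):
        t1 = np.sort(rng.integers(0, 2_000, size=300))
        t2 = np.sort(rng.integers(10_000, 12_000, size=300))
        t = np.concatenate([t1, t2])
        n = t.size
        s = ev.EventStream(8, 8, t, np.zeros(n, int), np.zeros(n, int), np.ones(n, np.int8))
        wins = ev.segment_transits(s, bin_us=100, min_rate=5, min_gap=3)
        assert wins == _bin_histogram_windows(s, 100, 5, 3)
        assert len(wins) == 2

    def test_close_bursts_are_merged(self, rng):
        t1 = np.sort(rng.integers(0, 1_000, size=200))
        t2 = np.sort(rng.integers(1_300, 2_300, size=200))
        t = np.sort(np.concatenate([t1, t2]))
        n = t.size
        s = ev.EventStream(8, 8, t, np.zeros(n, int), np.zeros(n, int), np.ones(n, np.int8))
        # quiet gap of ~3 bins < min_gap=10 -> one window
        assert len(ev.segment_transits(s, bin_us=100, min_rate=5, min_gap=10)) == 1

    def test_empty_stream(self):
        empty = np.empty(0, dtype=np.int64)
        s = ev.EventStream(4, 4, empty, empty, empty, empty.astype(np.int8))
        assert ev.segment_transits(s, 100, 1) == []

    def test_invalid_arguments(self, rng):
        s = random_stream(rng)
        with pytest.raises(ArgumentError):
            ev.segment_transits(s, 0, 1)
        with pytest.raises(ArgumentError):
            ev.segment_transits(s, 100, 0)


# ---------------------------------------------------------------------------
# Frame accumulation / binarization
# ---------------------------------------------------------------------------


class TestAccumulateFrame:
    def test_counting_example(self):
        s = ev.EventStream(4, 4, [0, 1, 2], [2, 2, 2], [1, 1, 1], [1, 1, -1])
        f = ev.accumulate_frame(s, (0, 10))
        assert f.pos_counts[1, 2] == 2
        assert f.neg_counts[1, 2] == 1
        assert f.total == 3
        assert f.pos_counts.sum() == 2 and f.neg_counts.sum() == 1

    def test_window_with_no_events(self):
        s = ev.EventStream(4, 4, [0], [0], [0], [1])
        f = ev.accumulate_frame(s, (100, 200))
        assert f.total == 0

    def test_inverted_window_rejected(self):
        s = ev.EventStream(4, 4, [0], [0], [0], [1])
        with pytest.raises(WindowError):
            ev.accumulate_frame(s, (10, 5))

    def test_random_stream_matches_filter_and_count(self, rng):
        s = random_stream(rng, n=10_000, width=20, height=15, t_max=5_000)
        window = (1_000, 3_000)
        f = ev.accumulate_frame(s, window)
        # independent oracle: filter rows, count per polarity
        in_win = [(int(x), int(y), int(p)) for t, x, y, p in zip(s.t, s.x, s.y, s.p) if window[0] <= t < window[1]]
        assert f.pos_counts.sum() == sum(1 for *_xy, p in in_win if p == 1)
        assert f.neg_counts.sum() == sum(1 for *_xy, p in in_win if p == -1)
        xi, yi = 7, 4
        assert f.pos_counts[yi, xi] == sum(1 for x, y, p in in_win if (x, y, p) == (xi, yi, 1))

    def test_partition_conserves_event_count(self, rng):
        s = random_stream(rng, n=2_000, t_max=10_000)
        cuts = [0, 2_500, 5_000, 7_500, 10_001]
        total = sum(
            ev.accumulate_frame(s, (a, b)).total for a, b in zip(cuts, cuts[1:])
        )
        assert total == len(s)


class TestBinarize:
    def test_threshold_at_one(self):
        pos = np.array([[7, 0], [1, 0]])
        neg = np.array([[0, 0], [0, 3]])
        maps = ev.binarize(ev.EventFrame(pos, neg, (0, 1)))
        assert maps.pos.tolist() == [[True, False], [True, False]]
        assert maps.neg.tolist() == [[False, False], [False, True]]

    def test_random_counts_match_elementwise_oracle(self, rng):
        pos = rng.integers(0, 4, size=(9, 11))
        neg = rng.integers(0, 4, size=(9, 11))
        maps = ev.binarize(ev.EventFrame(pos, neg, (0, 1)))
        assert np.array_equal(maps.pos, pos >= 1)
        assert np.array_equal(maps.neg, neg >= 1)


# ---------------------------------------------------------------------------
# Down-sampling and feature assembly
# ---------------------------------------------------------------------------


def _or_pool_oracle(grid, bh, bw):
    """Exhaustive block scan."""
    h, w = grid.shape
    hp = -(-h // bh)
    wp = -(-w // bw)
    out = np.zeros((hp, wp), dtype=bool)
    for i in range(hp):
        for j in range(wp):
            out[i, j] = grid[i * bh : (i + 1) * bh, j * bw : (j + 1) * bw].any()
    return out


class TestDownsampleOr:
    def test_full_sensor_block5_shape(self):
        grid = np.zeros((480, 640), dtype=bool)
        out = ev.downsample_or(grid, (5, 5))
        assert out.shape == (96, 128)

    def test_block_one_is_identity(self, rng):
        grid = rng.random((10, 13)) < 0.3
        assert np.array_equal(ev.downsample_or(grid, (1, 1)), grid)

    def test_single_bit_lands_in_right_block(self):
        grid = np.zeros((4, 4), dtype=bool)
        grid[3, 3] = True
        out = ev.downsample_or(grid, (2, 2))
        assert out.shape == (2, 2)
        assert out[1, 1] and out.sum() == 1

    @pytest.mark.parametrize("shape,block", [((12, 16), (3, 4)), ((10, 10), (4, 4)), ((7, 5), (2, 3))])
    def test_matches_exhaustive_block_scan(self, rng, shape, block):
        grid = rng.random(shape) < 0.2
        assert np.array_equal(ev.downsample_or(grid, block), _or_pool_oracle(grid, *block))

    def test_monotone_in_added_bits(self, rng):
        grid = rng.random((12, 12)) < 0.15
        before = ev.downsample_or(grid, (3, 3))
        zeros = np.argwhere(~grid)
        i, j = zeros[rng.integers(len(zeros))]
        grid[i, j] = True
        after = ev.downsample_or(grid, (3, 3))
        assert np.all(after >= before)

    def test_stride_mode(self, rng):
        grid = rng.random((8, 8)) < 0.5
        assert np.array_equal(ev.downsample_or(grid, (2, 2), pool="stride"), grid[::2, ::2])

    def test_invalid_block_rejected(self):
        with pytest.raises(ArgumentError):
            ev.downsample_or(np.zeros((4, 4), dtype=bool), (0, 2))


class TestMakeFeature:
    def test_split_concatenation(self):
        maps = ev.PolarityMaps(np.array([[1, 0]]), np.array([[0, 1]]))
        f = ev.make_feature(maps, "split")
        assert f.bits.tolist() == [1, 0, 0, 1]
        assert len(f) == 4

    def test_merged_or(self):
        maps = ev.PolarityMaps(np.array([[1, 0]]), np.array([[0, 1]]))
        f = ev.make_feature(maps, "merged")
        assert f.bits.tolist() == [1, 1]
        assert len(f) == 2

    def test_split_is_twice_merged_length(self, rng):
        maps = ev.PolarityMaps(rng.random((17, 23)) < 0.4, rng.random((17, 23)) < 0.4)
        assert len(ev.make_feature(maps, "split")) == 2 * len(ev.make_feature(maps, "merged"))

    def test_full_resolution_split_length(self):
        maps = ev.PolarityMaps(np.zeros((480, 640), bool), np.zeros((480, 640), bool))
        assert len(ev.make_feature(maps, "split")) == 614_400
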