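"""Event-camera data model, file I/O and feature preprocessing.

An event-based camera (dynamic vision sensor, DVS) emits an asynchronous
stream of ``(t, x, y, p)`` records: a microsecond timestamp, a pixel
coordinate and a polarity (+1 for a local brightness increase, -1 for a
decrease).  This module provides

* :class:`EventStream` -- the in-memory container, column-oriented numpy
  arrays sorted by timestamp;
* CSV and HDF5 readers/writers for a documented plain-text and
  compressed-binary on-disk dialect (polarity is stored as {0, 1} on disk,
  0 encoding -1);
* activity-based transit segmentation (one particle crossing the beam is
  one burst of events);
* frame accumulation, binarization, OR-pooling down-sampling and the
  polarity split/merge step that turns one transit into a binary
  :class:`FeatureVector`.

Conventions: coordinates are 0-based with ``x`` the column and ``y`` the
row, origin at the top-left of the sensor; all time windows are half-open
``[t_start, t_end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import (
    ArgumentError,
    BoundsError,
    EventParseError,
    WindowError,
)

_CSV_COLUMNS = ("t", "x", "y", "p")


@dataclass
class EventStream:
    """A time-sorted stream of DVS events from one recording.

    Attributes
    ----------
    sensor_width, sensor_height:
        Sensor dimensions in pixels (the experimental sensor is 640x480).
    t, x, y, p:
        Parallel int64/int64/int64/int8 arrays; ``p`` is +1 or -1.
    """

    sensor_width: int
    sensor_height: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=np.int8)
        n = self.t.size
        if not (self.x.size == self.y.size == self.p.size == n):
            raise ArgumentError("event columns have unequal lengths")
        if n:
            if np.any(np.diff(self.t) < 0):
                raise ArgumentError("event timestamps must be non-decreasing")
            if np.any(self.t < 0):
                raise ArgumentError("event timestamps must be non-negative")
            if (
                self.x.min() < 0
                or self.x.max() >= self.sensor_width
                or self.y.min() < 0
                or self.y.max() >= self.sensor_height
            ):
                raise BoundsError("event coordinates fall outside the sensor")
            if not np.isin(self.p, (-1, 1)).all():
                raise ArgumentError("polarity must be +1 or -1")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def time_span(self) -> tuple[int, int]:
        """(first, last) timestamp; (0, 0) for an empty stream."""
        if len(self) == 0:
            return (0, 0)
        return (int(self.t[0]), int(self.t[-1]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.sensor_width == other.sensor_width
            and self.sensor_height == other.sensor_height
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.p, other.p)
        )


@dataclass
class EventFrame:
    """Per-pixel positive/negative event counts accumulated over a window."""

    pos_counts: np.ndarray
    neg_counts: np.ndarray
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.pos_counts.shape != self.neg_counts.shape:
            raise ArgumentError("count grids must share dimensions")

    @property
    def total(self) -> int:
        return int(self.pos_counts.sum() + self.neg_counts.sum())


@dataclass
class PolarityMaps:
    """Binary presence maps for positive and negative events."""

    pos: np.ndarray
    neg: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=bool)
        self.neg = np.asarray(self.neg, dtype=bool)
        if self.pos.shape != self.neg.shape:
            raise ArgumentError("polarity maps must share dimensions")


@dataclass
class FeatureVector:
    """Flat binary feature vector for one transit.

    ``polarity_mode='split'`` concatenates the flattened positive map and
    negative map (length ``2*H*W``); ``'merged'`` ORs them (length ``H*W``).
    """

    bits: np.ndarray
    polarity_mode: str

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ArgumentError("feature bits must be one-dimensional")
        if self.polarity_mode not in ("split", "merged"):
            raise ArgumentError(f"unknown polarity_mode {self.polarity_mode!r}")

    def __len__(self) -> int:
        return int(self.bits.size)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _stable_sort_by_time(t, x, y, p):
    order = np.argsort(t, kind="stable")
    return t[order], x[order], y[order], p[order]


def read_event_csv(path, sensor_dims: tuple[int, int]) -> EventStream:
    """Read the plain-text event dialect: header ``t,x,y,p``, integer rows.

    Polarity on disk is {0, 1} with 0 encoding -1.  Rows out of time order
    are stably sorted, preserving row order among equal timestamps.
    Malformed rows raise :class:`EventParseError` naming the 1-based line
    number; out-of-bounds coordinates raise :class:`BoundsError`.
    """
    width, height = sensor_dims
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if tuple(c.strip() for c in df.columns) != _CSV_COLUMNS:
        raise EventParseError(f"{path}: expected header 't,x,y,p'")
    cols = {}
    for name in _CSV_COLUMNS:
        num = pd.to_numeric(df[name], errors="coerce")
        bad = num.isna() | (np.mod(num.fillna(0), 1) != 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise EventParseError(
                f"{path}: malformed integer in column '{name}' at line {line}"
            )
        cols[name] = num.to_numpy(dtype=np.int64)
    p_raw = cols["p"]
    if not np.isin(p_raw, (0, 1)).all():
        line = int(np.flatnonzero(~np.isin(p_raw, (0, 1)))[0]) + 2
        raise EventParseError(f"{path}: polarity must be 0 or 1 at line {line}")
    x, y = cols["x"], cols["y"]
    oob = (x < 0) | (x >= width) | (y < 0) | (y >= height)
    if oob.any():
        line = int(np.flatnonzero(oob)[0]) + 2
        raise BoundsError(f"{path}: coordinate outside {width}x{height} sensor at line {line}")
    p = np.where(p_raw == 1, 1, -1).astype(np.int8)
    t, x, y, p = _stable_sort_by_time(cols["t"], x, y, p)
    return EventStream(width, height, t, x, y, p)


def write_event_csv(stream: EventStream, path) -> None:
    """Write the plain-text dialect; inverse of :func:`read_event_csv`."""
    df = pd.DataFrame(
        {
            "t": stream.t,
            "x": stream.x,
            "y": stream.y,
            "p": (stream.p > 0).astype(np.uint8),
        }
    )
    df.to_csv(path, index=False)


def read_event_h5(path) -> EventStream:
    """Read the compressed-binary container (HDF5, keys t/x/y/p + dims)."""
    with h5py.File(path, "r") as f:
        width = int(f.attrs["sensor_width"])
        height = int(f.attrs["sensor_height"])
        t = f["t"][:].astype(np.int64)
        x = f["x"][:].astype(np.int64)
        y = f["y"][:].astype(np.int64)
        p_raw = f["p"][:]
    p = np.where(p_raw == 1, 1, -1).astype(np.int8)
    t, x, y, p = _stable_sort_by_time(t, x, y, p)
    return EventStream(width, height, t, x, y, p)


def write_event_h5(stream: EventStream, path) -> None:
    """Write the compressed-binary container; inverse of :func:`read_event_h5`."""
    with h5py.File(path, "w") as f:
        f.attrs["sensor_width"] = stream.sensor_width
        f.attrs["sensor_height"] = stream.sensor_height
        opts = {"compression": "gzip", "compression_opts": 4}
        f.create_dataset("t", data=stream.t, **opts)
        f.create_dataset("x", data=stream.x.astype(np.uint16), **opts)
        f.create_dataset("y", data=stream.y.astype(np.uint16), **opts)
        f.create_dataset("p", data=(stream.p > 0).astype(np.uint8), **opts)


def read_event_file(path) -> EventStream:
    """Dispatch on extension: ``.csv`` -> text dialect, else HDF5 container."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        raise ArgumentError(
            "read_event_file cannot infer sensor dims for CSV; use read_event_csv"
        )
    return read_event_h5(path)


# ---------------------------------------------------------------------------
# Segmentation and accumulation
# ---------------------------------------------------------------------------


def segment_transits(
    stream: EventStream, bin_us: int, min_rate: int, min_gap: int = 1
) -> list[tuple[int, int]]:
    """Find particle-transit windows as runs of high event activity.

    The stream's span is divided into bins of ``bin_us`` microseconds; a bin
    is active when it holds at least ``min_rate`` events.  A window is a
    maximal run of active bins, with runs separated by fewer than
    ``min_gap`` quiet bins merged into one.  Returns disjoint, sorted,
    bin-aligned half-open windows in microseconds.
    """
    if bin_us <= 0:
        raise ArgumentError("bin_us must be positive")
    if min_rate < 1:
        raise ArgumentError("min_rate must be at least 1")
    if min_gap < 1:
        raise ArgumentError("min_gap must be at least 1")
    if len(stream) == 0:
        return []
    t0 = int(stream.t[0])
    idx = (stream.t - t0) // bin_us
    counts = np.bincount(idx.astype(np.int64))
    active = counts >= min_rate
    if not active.any():
        return []
    # run-length extraction of active bins
    edges = np.diff(active.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(active.size)
    runs: list[list[int]] = []
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] < min_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    return [(t0 + s * bin_us, t0 + e * bin_us) for s, e in runs]


def accumulate_frame(stream: EventStream, window: tuple[int, int]) -> EventFrame:
    """Count events per pixel and polarity over half-open ``window``."""
    t_start, t_end = window
    if not t_start < t_end:
        raise WindowError(f"inverted window ({t_start}, {t_end})")
    h, w = stream.sensor_height, stream.sensor_width
    mask = (stream.t >= t_start) & (stream.t < t_end)
    flat = stream.y[mask] * w + stream.x[mask]
    pol = stream.p[mask]
    pos = np.bincount(flat[pol > 0], minlength=h * w).reshape(h, w)
    neg = np.bincount(flat[pol < 0], minlength=h * w).reshape(h, w)
    return EventFrame(pos.astype(np.int64), neg.astype(np.int64), (int(t_start), int(t_end)))


def binarize(frame: EventFrame) -> PolarityMaps:
    """Presence/absence maps: a bit is 1 iff at least one event occurred."""
    return PolarityMaps(frame.pos_counts >= 1, frame.neg_counts >= 1)


def downsample_or(grid: np.ndarray, block: tuple[int, int], pool: str = "block") -> np.ndarray:
    """Reduce a binary grid by ``block``, preserving presence.

    ``pool='block'`` (default) ORs each non-overlapping ``bh x bw`` block, so
    an output cell is 1 iff any input bit in its block is 1; the grid is
    zero-padded up to a block multiple, giving shape ``(ceil(H/bh),
    ceil(W/bw))``.  ``pool='stride'`` is plain subsampling, kept for
    comparison.  ``block=(1, 1)`` is the identity.
    """
    bh, bw = block
    if bh < 1 or bw < 1:
        raise ArgumentError("block sizes must be positive")
    g = np.asarray(grid, dtype=bool)
    if g.ndim != 2:
        raise ArgumentError("grid must be two-dimensional")
    if pool == "stride":
        return g[::bh, ::bw].copy()
    if pool != "block":
        raise ArgumentError(f"unknown pool mode {pool!r}")
    return _downsample_or_batch(g[None], (bh, bw))[0]


def _downsample_or_batch(grids: np.ndarray, block: tuple[int, int]) -> np.ndarray:
    """OR-pool a stack of binary grids of shape (n, H, W)."""
    bh, bw = block
    n, h, w = grids.shape
    hp, wp = math.ceil(h / bh), math.ceil(w / bw)
    if (hp * bh, wp * bw) != (h, w):
        padded = np.zeros((n, hp * bh, wp * bw), dtype=bool)
        padded[:, :h, :w] = grids
    else:
        padded = grids
    return padded.reshape(n, hp, bh, wp, bw).any(axis=(2, 4))


def make_feature(maps: PolarityMaps, polarity_mode: str = "split") -> FeatureVector:
    """Flatten polarity maps into one binary feature vector.

    ``split`` row-major-flattens the positive map followed by the negative
    map, doubling the feature length; ``merged`` ORs the two maps first.
    """
    if polarity_mode == "split":
        bits = np.concatenate([maps.pos.ravel(), maps.neg.ravel()])
    elif polarity_mode == "merged":
        bits = (maps.pos | maps.neg).ravel()
    else:
        raise ArgumentError(f"unknown polarity_mode {polarity_mode!r}")
    return FeatureVector(bits.astype(np.uint8), polarity_mode)
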