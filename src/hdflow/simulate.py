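"""Synthetic optics + event-sensor simulator for the classification pipeline.

The experimental system illuminates polystyrene microspheres (9/12/16/20 um)
flowing through a vertical microfluidic channel with a 632.8 nm He-Ne beam;
the diffraction pattern of each particle is recorded by a 640x480 event
camera with 10.56 um pixels, optionally after a ground-glass diffuser.
Those recordings are not publicly deposited, so this module generates event
datasets with the same statistical structure:

* an Airy-type radial interference pattern whose first-ring radius scales
  as 1/diameter (Fraunhofer diffraction of a circular obstruction), drifting
  vertically across the sensor to model flow;
* a ground-glass diffuser as a fixed seeded multiplicative speckle field
  followed by a Gaussian envelope blur; coarser grit (lower grit number)
  means a wider envelope, matching the fine-to-coarse grit series;
* a standard per-pixel DVS model: an event fires each time log intensity
  crosses a multiple of the contrast threshold away from the pixel's last
  reference level, with linear-in-time interpolated timestamps, Poisson
  background noise and an optional refractory period;
* per-session drift (gain, intensity offset, beam-centre jitter) that can
  be drawn per (class, session) block -- emulating sequential acquisition,
  which is what couples drift to class labels and produces measurement
  bias -- or per session shared across classes.

All randomness flows from ``master_seed`` through named ``SeedSequence``
spawns, so a dataset is byte-reproducible.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import j1

from . import events as ev
from .evaluation import Sample, SessionDataset
from .exceptions import ArgumentError, ConfigError

#: First zero of the Bessel function J1, locating the first Airy minimum.
AIRY_FIRST_ZERO = 3.8317059702075125

#: Default envelope half-width (pixels, 640x480 sensor) per diffuser grit.
#: Coarser grit (lower number) scatters over a wider envelope.
GRIT_ENVELOPE_SIGMA = {120: 16.0, 600: 8.0, 1500: 4.0}


@dataclass(frozen=True)
class OpticsConfig:
    """Geometry of the illumination, sensor and particle transit.

    The first-ring radius (pixels) of a particle of diameter d (um) defaults
    to the Fraunhofer form ``1.22 * lambda * z / (d * pixel_pitch)`` with
    ``z = propagation_mm``; an explicit ``pattern_scale`` table (diameter ->
    radius, strictly decreasing) overrides it.
    """

    wavelength_nm: float = 632.8
    sensor: tuple[int, int] = (640, 480)  # (width, height) pixels
    pixel_pitch_um: float = 10.56
    propagation_mm: float = 5.8
    pattern_scale: tuple[tuple[float, float], ...] | None = None
    transit_duration_us: float = 2000.0
    frames_per_transit: int = 10
    travel_frac: float = 0.25  # vertical travel as a fraction of sensor height
    transit_jitter_px: float = 1.0  # per-transit random centre jitter (sd)

    def __post_init__(self) -> None:
        if min(self.wavelength_nm, self.pixel_pitch_um, self.propagation_mm) <= 0:
            raise ConfigError("optical quantities must be positive")
        if self.transit_duration_us <= 0 or self.frames_per_transit < 2:
            raise ConfigError("need a positive transit duration and >= 2 frames")
        if self.pattern_scale is not None:
            radii = [r for _, r in sorted(self.pattern_scale)]
            if any(b >= a for a, b in zip(radii, radii[1:])):
                raise ConfigError("pattern_scale must be strictly decreasing in diameter")

    def first_ring_radius(self, diameter_um: float) -> float:
        """First-ring (first Airy minimum) radius in pixels."""
        if diameter_um <= 0:
            raise ArgumentError("particle diameter must be positive")
        if self.pattern_scale is not None:
            table = dict(self.pattern_scale)
            if diameter_um in table:
                return float(table[diameter_um])
            ds = sorted(table)
            return float(np.interp(diameter_um, ds, [table[d] for d in ds]))
        lam_um = self.wavelength_nm / 1000.0
        z_um = self.propagation_mm * 1000.0
        return 1.22 * lam_um * z_um / (diameter_um * self.pixel_pitch_um)


@dataclass(frozen=True)
class DiffuserConfig:
    """Ground-glass diffuser: seeded speckle modulation + envelope blur.

    ``grit`` of ``None`` means no diffuser (identity).  ``envelope_sigma``
    defaults to the grit table scaled by ``envelope_scale`` (use the sensor
    width ratio when simulating a reduced sensor).
    """

    grit: int | None = None
    envelope_sigma: float | None = None
    speckle_grain: float = 4.0
    envelope_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grit is not None and self.grit not in GRIT_ENVELOPE_SIGMA:
            if self.envelope_sigma is None:
                raise ConfigError(
                    f"unknown grit {self.grit}; give an explicit envelope_sigma"
                )
        if self.speckle_grain <= 0 or self.envelope_scale <= 0:
            raise ConfigError("speckle_grain and envelope_scale must be positive")

    @property
    def resolved_sigma(self) -> float | None:
        if self.grit is None:
            return None
        if self.envelope_sigma is not None:
            return self.envelope_sigma * self.envelope_scale
        return GRIT_ENVELOPE_SIGMA[self.grit] * self.envelope_scale


@dataclass(frozen=True)
class SensorConfig:
    """Event-sensor model parameters.

    ``contrast_threshold`` is the log-intensity step per event (typical DVS
    hardware sits near 0.1-0.2); ``noise_rate`` is the background event rate
    per pixel per second; ``log_eps`` floors the log at dark pixels.
    """

    contrast_threshold: float = 0.15
    noise_rate: float = 5.0
    refractory_us: float = 0.0
    log_eps: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast_threshold <= 0:
            raise ConfigError("contrast_threshold must be positive")
        if self.noise_rate < 0 or self.refractory_us < 0 or self.log_eps <= 0:
            raise ConfigError("noise_rate/refractory_us/log_eps out of range")


@dataclass(frozen=True)
class DriftSample:
    """One realisation of session drift applied to a transit's intensity."""

    gain: float = 1.0
    offset: float = 0.0
    dx: float = 0.0
    dy: float = 0.0


@dataclass(frozen=True)
class DriftConfig:
    """Per-session acquisition drift.

    With ``class_correlated=True`` a fresh drift realisation is drawn for
    every (class, session) block, emulating sequential acquisition (class A,
    then B, then C, then D within one session); with ``False`` a single
    realisation per session is shared by all classes.
    """

    gain_sd: float = 0.05
    offset_sd: float = 1e-4
    center_jitter_sd: float = 10.0
    class_correlated: bool = True

    def __post_init__(self) -> None:
        if min(self.gain_sd, self.offset_sd, self.center_jitter_sd) < 0:
            raise ConfigError("drift scales must be non-negative")

    @classmethod
    def none(cls) -> "DriftConfig":
        return cls(gain_sd=0.0, offset_sd=0.0, center_jitter_sd=0.0, class_correlated=False)


@dataclass(frozen=True)
class SimulationConfig:
    """Full study description: classes, sessions, optics, sensor, drift."""

    classes: tuple[tuple[str, float], ...] = (("A", 9.0), ("B", 12.0), ("C", 16.0), ("D", 20.0))
    n_sessions: int = 6
    samples_per_class_session: int = 1100
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    diffuser: DiffuserConfig = field(default_factory=DiffuserConfig)
    sensor: SensorConfig = field(default_factory=SensorConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ConfigError("need at least two classes")
        diameters = [d for _, d in self.classes]
        if len(set(diameters)) != len(diameters):
            raise ConfigError("class diameters must be distinct")
        if self.n_sessions < 1 or self.samples_per_class_session < 1:
            raise ConfigError("need >= 1 session and >= 1 sample per class-session")

    @classmethod
    def reduced(
        cls,
        master_seed: int = 0,
        samples_per_class_session: int = 25,
        n_sessions: int = 6,
        drift: "DriftConfig | None" = None,
        diffuser: "DiffuserConfig | None" = None,
    ) -> "SimulationConfig":
        """The desk-scale analogue of the full study: a 128x96 sensor.

        Equivalent to binning the 640x480 sensor 5x5 (pixel pitch 52.8 um),
        with every physical scale unchanged: ring radii, beam jitter and
        diffuser envelopes land at one fifth of their full-sensor pixel
        values.  Used by the test-suite and the reproduction script so that
        simulation-heavy studies complete in minutes on one CPU.
        """
        optics = OpticsConfig(
            sensor=(128, 96),
            pixel_pitch_um=52.8,
            frames_per_transit=10,
            transit_duration_us=2000.0,
            transit_jitter_px=0.5,
        )
        return cls(
            optics=optics,
            sensor=SensorConfig(),
            drift=drift if drift is not None else DriftConfig(center_jitter_sd=2.0),
            diffuser=diffuser if diffuser is not None else DiffuserConfig(),
            n_sessions=n_sessions,
            samples_per_class_session=samples_per_class_session,
            master_seed=master_seed,
        )


def reduced_diffuser(grit: int | None, seed: int = 0) -> DiffuserConfig:
    """Diffuser settings matched to :meth:`SimulationConfig.reduced` (1/5 scale)."""
    if grit is None:
        return DiffuserConfig()
    return DiffuserConfig(grit=grit, envelope_scale=0.2, speckle_grain=1.5, seed=seed)


# ---------------------------------------------------------------------------
# Optical rendering
# ---------------------------------------------------------------------------


def airy_intensity(rho_px: np.ndarray, first_ring_radius_px: float) -> np.ndarray:
    """Normalised Airy intensity (2 J1(v)/v)^2 with first zero at the ring radius."""
    v = AIRY_FIRST_ZERO * np.asarray(rho_px, dtype=float) / first_ring_radius_px
    small = v < 1e-9
    vs = np.where(small, 1.0, v)
    out = (2.0 * j1(vs) / vs) ** 2
    return np.where(small, 1.0, out)


def render_transit(
    diameter_um: float,
    optics: OpticsConfig,
    drift: DriftSample = DriftSample(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the intensity-frame sequence of one particle transit.

    The Airy-type pattern (first-ring radius from the optics geometry,
    inversely proportional to diameter) translates vertically top-to-bottom
    across ``frames_per_transit`` frames; the drift sample applies gain,
    additive offset and beam-centre displacement.  Returns ``(frames,
    timestamps_us)`` with frames of shape (F, H, W).
    """
    rng = np.random.default_rng(rng)
    w, h = optics.sensor
    r1 = optics.first_ring_radius(diameter_um)
    if optics.transit_jitter_px > 0:
        jx, jy = rng.normal(0.0, optics.transit_jitter_px, size=2)
    else:
        jx = jy = 0.0
    cx = (w - 1) / 2.0 + drift.dx + jx
    travel = optics.travel_frac * h
    nf = optics.frames_per_transit
    cy_path = (h - 1) / 2.0 + drift.dy + jy + np.linspace(-travel / 2, travel / 2, nf)
    xs = np.arange(w, dtype=float)[None, :]
    ys = np.arange(h, dtype=float)[:, None]
    frames = np.empty((nf, h, w), dtype=float)
    for i, cy in enumerate(cy_path):
        rho = np.hypot(xs - cx, ys - cy)
        frames[i] = np.clip(drift.gain * airy_intensity(rho, r1) + drift.offset, 0.0, None)
    timestamps = np.linspace(0.0, optics.transit_duration_us, nf)
    return frames, timestamps


_speckle_cache: dict[tuple, np.ndarray] = {}


def _speckle_field(shape: tuple[int, int], grain: float, seed: int) -> np.ndarray:
    """Fixed multiplicative speckle field with mean 1 and given grain size."""
    key = (shape, float(grain), int(seed))
    if key not in _speckle_cache:
        rng = np.random.default_rng(seed)
        a = gaussian_filter(rng.standard_normal(shape), grain)
        b = gaussian_filter(rng.standard_normal(shape), grain)
        intensity = a * a + b * b
        _speckle_cache[key] = intensity / intensity.mean()
    return _speckle_cache[key]


def apply_diffuser(frames: np.ndarray, diffuser: DiffuserConfig | None) -> np.ndarray:
    """Broaden frames by the grit envelope and modulate by a fixed speckle field.

    The envelope blur models the plate's angular scattering spread (coarser
    grit, lower number -> wider envelope); the multiplicative speckle field,
    fixed per plate seed, models the coherent granularity, whose grain size
    is set by the illuminated spot rather than the grit.  Blur is applied
    before the speckle so the grain contrast survives at every envelope
    width, as in the recorded scattering patterns.  Total intensity per
    frame is preserved (the plate redistributes energy, it does not absorb
    it); with ``grit=None`` the frames pass unchanged.
    """
    frames = np.asarray(frames, dtype=float)
    if diffuser is None or diffuser.grit is None:
        return frames.copy()
    sigma = diffuser.resolved_sigma
    shape = frames.shape[-2:]
    speckle = _speckle_field(shape, diffuser.speckle_grain, diffuser.seed)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        spread = gaussian_filter(frame, sigma, mode="nearest") * speckle
        total_in, total_out = frame.sum(), spread.sum()
        out[i] = spread * (total_in / total_out) if total_out > 0 else spread
    return out


# ---------------------------------------------------------------------------
# Event-sensor model
# ---------------------------------------------------------------------------


def _apply_refractory(t, x, y, p, width, refractory_us):
    pix = y * width + x
    order = np.lexsort((t, pix))
    keep = np.ones(t.size, dtype=bool)
    last_pix = -1
    last_t = 0
    for i in order:
        if pix[i] != last_pix:
            last_pix = pix[i]
            last_t = t[i]
        elif t[i] - last_t < refractory_us:
            keep[i] = False
        else:
            last_t = t[i]
    return t[keep], x[keep], y[keep], p[keep]


def simulate_dvs(
    frames: np.ndarray,
    timestamps_us: np.ndarray,
    sensor: SensorConfig,
    rng: np.random.Generator | int | None = None,
) -> ev.EventStream:
    """Convert an intensity-frame sequence into a DVS event stream.

    Each pixel keeps a log-intensity reference level; between consecutive
    frames, every multiple of ``contrast_threshold`` crossed away from the
    reference emits one event (+1 upward, -1 downward) with a timestamp
    interpolated linearly in log intensity, and the reference advances by
    the quantised amount.  Poisson background noise at ``noise_rate`` is
    superposed and an optional refractory period suppresses same-pixel
    events closer than ``refractory_us``.
    """
    frames = np.asarray(frames, dtype=float)
    timestamps_us = np.asarray(timestamps_us, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ArgumentError("need at least two frames")
    if timestamps_us.shape[0] != frames.shape[0]:
        raise ArgumentError("one timestamp per frame required")
    if np.any(np.diff(timestamps_us) <= 0):
        raise ArgumentError("timestamps must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(sensor.seed)
    else:
        rng = np.random.default_rng(rng)

    theta = sensor.contrast_threshold
    nf, h, w = frames.shape
    logI = np.log(frames + sensor.log_eps)
    ref = logI[0].copy()
    ts_out, xs_out, ys_out, ps_out = [], [], [], []
    for i in range(1, nf):
        t_lo, t_hi = timestamps_us[i - 1], timestamps_us[i]
        delta = (logI[i] - ref).ravel()
        for sign in (1, -1):
            k = np.floor(sign * delta / theta).astype(np.int64)
            np.maximum(k, 0, out=k)
            total = int(k.sum())
            if total == 0:
                continue
            flat = np.flatnonzero(k)
            kv = k[flat]
            reps = np.repeat(flat, kv)
            rank = np.arange(total) - np.repeat(np.cumsum(kv) - kv, kv) + 1
            frac = rank * theta / (sign * delta[reps])
            ts_out.append(t_lo + frac * (t_hi - t_lo))
            xs_out.append(reps % w)
            ys_out.append(reps // w)
            ps_out.append(np.full(total, sign, dtype=np.int8))
            ref.ravel()[flat] += sign * kv * theta

    # background noise events
    duration_s = (timestamps_us[-1] - timestamps_us[0]) * 1e-6
    lam = sensor.noise_rate * h * w * duration_s
    n_noise = int(rng.poisson(lam)) if lam > 0 else 0
    if n_noise:
        ts_out.append(rng.uniform(timestamps_us[0], timestamps_us[-1], n_noise))
        xs_out.append(rng.integers(0, w, n_noise))
        ys_out.append(rng.integers(0, h, n_noise))
        ps_out.append(rng.choice(np.array([-1, 1], dtype=np.int8), n_noise))

    if not ts_out:
        empty = np.empty(0, dtype=np.int64)
        return ev.EventStream(w, h, empty, empty, empty, empty.astype(np.int8))

    t = np.round(np.concatenate(ts_out)).astype(np.int64)
    np.clip(t, 0, None, out=t)
    x = np.concatenate(xs_out).astype(np.int64)
    y = np.concatenate(ys_out).astype(np.int64)
    p = np.concatenate(ps_out).astype(np.int8)
    if sensor.refractory_us > 0:
        t, x, y, p = _apply_refractory(t, x, y, p, w, sensor.refractory_us)
    order = np.argsort(t, kind="stable")
    return ev.EventStream(w, h, t[order], x[order], y[order], p[order])


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def draw_session_drift(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, int], DriftSample]:
    """Draw drift per (class, session) or per session, per ``cfg.drift``."""
    d = cfg.drift
    out: dict[tuple[str, int], DriftSample] = {}
    for session in range(1, cfg.n_sessions + 1):
        shared: DriftSample | None = None
        for label, _ in cfg.classes:
            if d.class_correlated or shared is None:
                gain = max(0.1, 1.0 + rng.normal(0.0, d.gain_sd))
                offset = rng.normal(0.0, d.offset_sd)
                dx, dy = rng.normal(0.0, d.center_jitter_sd, size=2)
                shared = DriftSample(gain=gain, offset=offset, dx=dx, dy=dy)
            out[(label, session)] = shared
    return out


def synthesize_transit(
    diameter_um: float,
    cfg: SimulationConfig,
    drift: DriftSample = DriftSample(),
    rng: np.random.Generator | int | None = None,
) -> ev.EventStream:
    """Full pipeline for one transit: render -> diffuser -> DVS events."""
    rng = np.random.default_rng(rng)
    frames, timestamps = render_transit(diameter_um, cfg.optics, drift, rng)
    frames = apply_diffuser(frames, cfg.diffuser)
    return simulate_dvs(frames, timestamps, cfg.sensor, rng)


def _iter_transits(
    cfg: SimulationConfig,
) -> Iterator[tuple[str, int, int, ev.EventStream]]:
    """Deterministic (label, session, sample_id, stream) iterator."""
    root_ss = np.random.SeedSequence(cfg.master_seed)
    drift_ss, samples_ss = root_ss.spawn(2)
    drift = draw_session_drift(cfg, np.random.default_rng(drift_ss))
    n_total = len(cfg.classes) * cfg.n_sessions * cfg.samples_per_class_session
    children = samples_ss.spawn(n_total)
    i = 0
    for label, diameter in cfg.classes:
        for session in range(1, cfg.n_sessions + 1):
            for k in range(cfg.samples_per_class_session):
                rng = np.random.default_rng(children[i])
                i += 1
                yield label, session, k, synthesize_transit(
                    diameter, cfg, drift[(label, session)], rng
                )


def _maps_of(stream: ev.EventStream) -> ev.PolarityMaps:
    if len(stream) == 0:
        zeros = np.zeros((stream.sensor_height, stream.sensor_width), dtype=bool)
        return ev.PolarityMaps(zeros, zeros.copy())
    t0, t1 = stream.time_span
    return ev.binarize(ev.accumulate_frame(stream, (t0, t1 + 1)))


def simulate_session_dataset(cfg: SimulationConfig) -> SessionDataset:
    """Generate the study's dataset fully in memory (binarized maps)."""
    w, h = cfg.optics.sensor
    samples = []
    for label, session, k, stream in _iter_transits(cfg):
        maps = _maps_of(stream)
        samples.append(Sample(label, session, k, maps.pos, maps.neg))
    return SessionDataset(samples, w, h)


def generate_dataset(cfg: SimulationConfig, out_dir, fmt: str = "h5") -> pd.DataFrame:
    """Write the dataset to disk: per-transit event files plus a manifest.

    Layout: ``<out>/<class>/s<session>/transit<k>.<ext>`` with a
    ``manifest.csv`` of columns class, session, sample, file.  Returns the
    manifest frame.  Byte-reproducible from ``cfg.master_seed``.
    """
    if fmt not in ("h5", "csv"):
        raise ArgumentError(f"unknown dataset format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, session, k, stream in _iter_transits(cfg):
        rel = Path(label) / f"s{session:02d}" / f"transit{k:04d}.{fmt}"
        dest = out_dir / rel
        dest.parent.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            ev.write_event_csv(stream, dest)
        else:
            ev.write_event_h5(stream, dest)
        rows.append(
            {"class": label, "session": session, "sample": k, "file": rel.as_posix()}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_dataset(root, sensor_dims: tuple[int, int] | None = None) -> SessionDataset:
    """Load a generated dataset from disk into a :class:`SessionDataset`.

    ``sensor_dims`` is required when the event files are CSV (the text
    dialect does not embed the sensor size).
    """
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    samples = []
    w = h = None
    for _, row in manifest.iterrows():
        path = root / str(row["file"])
        if path.suffix.lower() == ".csv":
            if sensor_dims is None:
                raise ArgumentError("sensor_dims required to load a CSV dataset")
            stream = ev.read_event_csv(path, sensor_dims)
        else:
            stream = ev.read_event_h5(path)
        w, h = stream.sensor_width, stream.sensor_height
        maps = _maps_of(stream)
        samples.append(
            Sample(str(row["class"]), int(row["session"]), int(row["sample"]), maps.pos, maps.neg)
        )
    if w is None:
        raise ArgumentError(f"empty manifest in {root}")
    return SessionDataset(samples, w, h)


def polarity_swap_dataset(
    n_per_class_session: int = 40,
    n_sessions: int = 2,
    shape: tuple[int, int] = (32, 32),
    flip_prob: float = 0.05,
    seed: int = 0,
) -> SessionDataset:
    """A constructed dataset whose classes differ only in polarity structure.

    Class P fires positive events on region A and negative events on region
    B; class Q swaps them.  The OR of the two maps is identical for both
    classes, so merged-polarity features carry no class signal while split
    features separate the classes -- the extreme case of the polarity
    ablation.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    region_a = rng.random((h, w)) < 0.25
    region_b = ~region_a & (rng.random((h, w)) < 0.33)
    samples = []
    for label, pos_base, neg_base in (("P", region_a, region_b), ("Q", region_b, region_a)):
        for session in range(1, n_sessions + 1):
            for k in range(n_per_class_session):
                flips_p = rng.random((h, w)) < flip_prob
                flips_n = rng.random((h, w)) < flip_prob
                samples.append(
                    Sample(label, session, k, pos_base ^ flips_p, neg_base ^ flips_n)
                )
    return SessionDataset(samples, w, h)


# ---------------------------------------------------------------------------
# Config-file loading (flat INI sections per sub-config)
# ---------------------------------------------------------------------------


def load_sim_config(path) -> SimulationConfig:
    """Parse a flat ``key = value`` config file with one section per sub-config.

    Sections: ``[simulation]`` (classes as ``A:9,B:12,...``, n_sessions,
    samples_per_class_session, master_seed), ``[optics]``, ``[diffuser]``,
    ``[sensor]``, ``[drift]``; every key optional, defaulting to the
    dataclass defaults.
    """
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise ConfigError(f"config file {path} not found or unreadable")

    def section(name):
        return parser[name] if parser.has_section(name) else {}

    sim = section("simulation")
    kwargs: dict = {}
    if "classes" in sim:
        classes = []
        for item in sim["classes"].split(","):
            label, diam = item.split(":")
            classes.append((label.strip(), float(diam)))
        kwargs["classes"] = tuple(classes)
    for key, conv in (
        ("n_sessions", int),
        ("samples_per_class_session", int),
        ("master_seed", int),
    ):
        if key in sim:
            kwargs[key] = conv(sim[key])

    opt = section("optics")
    okw: dict = {}
    for key, conv in (
        ("wavelength_nm", float),
        ("pixel_pitch_um", float),
        ("propagation_mm", float),
        ("transit_duration_us", float),
        ("frames_per_transit", int),
        ("travel_frac", float),
        ("transit_jitter_px", float),
    ):
        if key in opt:
            okw[key] = conv(opt[key])
    if "sensor_width" in opt or "sensor_height" in opt:
        okw["sensor"] = (int(opt.get("sensor_width", 640)), int(opt.get("sensor_height", 480)))
    kwargs["optics"] = OpticsConfig(**okw)

    dif = section("diffuser")
    dkw: dict = {}
    if "grit" in dif:
        dkw["grit"] = None if dif["grit"].strip().lower() == "none" else int(dif["grit"])
    for key, conv in (
        ("envelope_sigma", float),
        ("speckle_grain", float),
        ("envelope_scale", float),
        ("seed", int),
    ):
        if key in dif:
            dkw[key] = conv(dif[key])
    kwargs["diffuser"] = DiffuserConfig(**dkw)

    sen = section("sensor")
    skw: dict = {}
    for key, conv in (
        ("contrast_threshold", float),
        ("noise_rate", float),
        ("refractory_us", float),
        ("log_eps", float),
        ("seed", int),
    ):
        if key in sen:
            skw[key] = conv(sen[key])
    kwargs["sensor"] = SensorConfig(**skw)

    dr = section("drift")
    drkw: dict = {}
    for key, conv in (
        ("gain_sd", float),
        ("offset_sd", float),
        ("center_jitter_sd", float),
    ):
        if key in dr:
            drkw[key] = conv(dr[key])
    if "class_correlated" in dr:
        drkw["class_correlated"] = dr["class_correlated"].strip().lower() in ("1", "true", "yes")
    kwargs["drift"] = DriftConfig(**drkw)

    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# Measurement helpers used by tests and the diffuser comparison
# ---------------------------------------------------------------------------


def radial_second_moment(frame: np.ndarray) -> float:
    """Intensity-weighted radial second moment about the centroid (pixels^2)."""
    frame = np.asarray(frame, dtype=float)
    total = frame.sum()
    if total <= 0:
        raise ArgumentError("frame carries no intensity")
    h, w = frame.shape
    ys, xs = np.mgrid[0:h, 0:w]
    cy = (frame * ys).sum() / total
    cx = (frame * xs).sum() / total
    return float((frame * ((xs - cx) ** 2 + (ys - cy) ** 2)).sum() / total)


def first_ring_minimum(frame: np.ndarray, center: tuple[float, float]) -> float:
    """Radius (pixels) of the first radial intensity minimum from ``center``.

    Averages intensity in 0.5 px annuli and returns the first local minimum
    of the profile -- an independent geometric probe of the rendered ring.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    cy, cx = center
    ys, xs = np.mgrid[0:h, 0:w]
    rho = np.hypot(xs - cx, ys - cy).ravel()
    vals = frame.ravel()
    nbins = int(rho.max() / 0.5)
    idx = np.minimum((rho / 0.5).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    cnts = np.bincount(idx, minlength=nbins)
    valid = cnts > 0  # annuli near the centre may contain no pixel centres
    profile = (sums / np.maximum(cnts, 1))[valid]
    radii = ((np.arange(nbins) + 0.5) * 0.5)[valid]
    # a genuine diffraction null sits far below the central lobe; ignore
    # shallow discretization dips near the peak
    floor = 0.05 * profile[:5].max()
    for i in range(1, profile.size - 1):
        if profile[i] <= profile[i - 1] and profile[i] < profile[i + 1] and profile[i] < floor:
            return float(radii[i])
    raise ArgumentError("no radial minimum found")
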