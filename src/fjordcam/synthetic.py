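"""Synthetic seafloor-deployment generator.

Everything the analysis pipeline consumes can be generated here with known
ground truth: a semidiurnal tide with a spring–neap envelope, tide-driven
marine-snow scenes rendered as RGB frame stacks, transient lens anomalies,
the intermittent recording schedule of the camera, a release-sensor log,
tone-plus-noise test audio, and an annotated detection table.

The imaging model is deliberately simple — Gaussian-profile bright discs
drifting over a dark, red-dominant background with a few static structures
(a diagonal mooring line, a bright elliptical reflector) — but every imposed
quantity (per-frame particle positions and count, the uniform flow vector,
injected anomalies, true foreground area) is recorded in a
:class:`SceneTruth`, so recovery by the measurement stages can be tested
quantitatively.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import line as _draw_line

from .video_io import FrameStack

#: Principal lunar semidiurnal (M2) period, hours.
T_M2_H = 12.42
#: Spring–neap envelope period, days.
T_SPRING_NEAP_D = 14.8

__all__ = [
    "T_M2_H",
    "T_SPRING_NEAP_D",
    "TideSeries",
    "SceneConfig",
    "SceneTruth",
    "FirstFrameSpike",
    "LensBlob",
    "SedimentGlow",
    "generate_tide",
    "generate_scene",
    "inject_anomalies",
    "generate_schedule",
    "generate_test_audio",
    "generate_sensor_log",
    "generate_detection_table",
    "DEFAULT_TAXON_COUNTS",
]


# ---------------------------------------------------------------------------
# Tide
# ---------------------------------------------------------------------------

@dataclass
class TideSeries:
    """Sea-level time series on a uniform grid.

    Attributes
    ----------
    timestamps : ndarray
        Seconds since the Unix epoch (UTC), strictly increasing, uniform.
    level : ndarray
        Sea level in metres relative to the mean.
    rate : ndarray, optional
        Smoothed rate of change of sea level in m/h (filled by
        :func:`fjordcam.tides.sea_level_rate`).
    """

    timestamps: np.ndarray
    level: np.ndarray
    rate: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size != self.level.size:
            raise ValueError("timestamps and level must be 1-D and equal length")
        if self.timestamps.size >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("sampling must be uniform")
        if not np.all(np.isfinite(self.level)):
            raise ValueError("level must be finite")
        if self.rate is not None:
            self.rate = np.asarray(self.rate, dtype=float)
            if self.rate.size != self.timestamps.size:
                raise ValueError("rate must align with timestamps")

    @property
    def interval_s(self) -> float:
        """Sampling interval in seconds."""
        if self.timestamps.size < 2:
            raise ValueError("need at least two samples")
        return float(self.timestamps[1] - self.timestamps[0])

    def to_frame(self) -> pd.DataFrame:
        """Tide as a DataFrame with ISO-8601 UTC timestamps."""
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(self.timestamps, unit="s", utc=True),
                "level_m": self.level,
            }
        )
        if self.rate is not None:
            df["rate_m_per_h"] = self.rate
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TideSeries":
        t = pd.to_datetime(df["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
        rate = df["rate_m_per_h"].to_numpy() if "rate_m_per_h" in df else None
        return cls(t, df["level_m"].to_numpy(dtype=float), rate)


def generate_tide(
    duration_s: float,
    mean_level: float = 0.0,
    semidiurnal_amp: float = 0.75,
    spring_neap_mod: float = 0.5,
    sample_interval_s: float = 60.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    start_time_s: float = 0.0,
) -> TideSeries:
    """Generate a single-constituent (M2) tide with a spring–neap envelope.

    level(t) = mean + A(t) sin(2*pi*t / T_M2), where the amplitude envelope
    A(t) = amp * (1 - mod * (1 + cos(2*pi*t / T_sn)) / 2) starts at its neap
    minimum ``amp*(1-mod)`` and reaches ``amp`` at spring, with a 14.8-day
    envelope period. The deployment emulated here began near neap tide, so
    t = 0 is placed at the envelope minimum.

    Parameters
    ----------
    duration_s : float
        Length of the series; at least two M2 cycles.
    semidiurnal_amp : float
        M2 amplitude in metres (half the spring peak-to-trough range).
    spring_neap_mod : float
        Envelope depth in [0, 1]; 0 gives a pure sinusoid.
    noise_sigma : float
        Optional white measurement noise, metres.
    """
    if sample_interval_s <= 0:
        raise ValueError("sample_interval_s must be positive")
    if semidiurnal_amp < 0:
        raise ValueError("semidiurnal_amp must be non-negative")
    if not 0.0 <= spring_neap_mod <= 1.0:
        raise ValueError("spring_neap_mod must be within [0, 1]")
    if duration_s < 2 * T_M2_H * 3600:
        raise ValueError("duration must cover at least two tidal cycles")

    n = int(math.floor(duration_s / sample_interval_s)) + 1
    t = start_time_s + np.arange(n) * sample_interval_s
    trel = t - start_time_s
    envelope = semidiurnal_amp * (
        1.0 - spring_neap_mod * (1.0 + np.cos(2 * np.pi * trel / (T_SPRING_NEAP_D * 86400))) / 2.0
    )
    level = mean_level + envelope * np.sin(2 * np.pi * trel / (T_M2_H * 3600))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        level = level + rng.normal(0.0, noise_sigma, size=n)
    return TideSeries(t, level)


# ---------------------------------------------------------------------------
# Scene configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of a synthetic camera deployment.

    Flow is spatially uniform per frame: the displacement between
    consecutive frames is ``flow_gain * rate(t)`` pixels along
    ``flow_axis_deg`` (degrees counterclockwise from image +x with the
    y axis pointing up), plus independent per-particle Gaussian jitter.
    """

    width: int = 640
    height: int = 480
    fps: float = 30.0
    total_hours: float = 1.0
    on_min: float = 10.0
    off_min: float = 10.0
    frames_per_segment: int = 10
    particle_density: float = 85.0        # expected particles per frame
    radius_range: tuple = (1.0, 4.0)      # px
    brightness_range: tuple = (80.0, 255.0)
    flow_gain: float = 20.0               # px/frame per (m/h)
    flow_axis_deg: float = 90.0
    jitter_sigma: float = 0.3             # px/frame, per particle
    noise_sigma: float = 3.0              # additive intensity noise
    background_elements: tuple = ("line", "ellipse")
    fibers: bool = False
    fiber_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.particle_density < 0:
            raise ValueError("particle_density must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        lo, hi = self.brightness_range
        if not (0 <= lo <= hi <= 255):
            raise ValueError("brightness_range must lie within 0-255")


@dataclass
class SceneTruth:
    """Ground truth recorded while rendering a synthetic scene.

    All lists are indexed ``[segment][frame]``. ``flow[s][f]`` is the uniform
    displacement (u, v) in px/frame imposed between frame ``f`` and
    ``f + 1`` (the final frame repeats the last transition); u is along
    image +x, v is mathematical (positive up, i.e. toward smaller rows).
    """

    counts: list = field(default_factory=list)
    positions: list = field(default_factory=list)   # arrays (n, 2) of (x, row)
    flow: list = field(default_factory=list)        # (u, v_up) px/frame
    area_px: list = field(default_factory=list)     # true foreground px
    anomalies: list = field(default_factory=list)   # dicts: type/onset/duration
    static_mask: Optional[np.ndarray] = None
    flow_axis_deg: float = 0.0
    flow_gain: float = 0.0

    def validate(self) -> None:
        for seg_counts, seg_pos in zip(self.counts, self.positions):
            for c, p in zip(seg_counts, seg_pos):
                if c != len(p):
                    raise AssertionError("truth count does not match positions")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, (counts, flows) in enumerate(zip(self.counts, self.flow)):
            for f, (c, (u, v)) in enumerate(zip(counts, flows)):
                rows.append(
                    {
                        "segment": s,
                        "frame": f,
                        "count": c,
                        "u_px_per_frame": u,
                        "v_px_per_frame": v,
                        "area_px": self.area_px[s][f],
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# Dark, red-dominant base colour emulating red-LED illumination at depth.
_BASE_RGB = (12.0, 2.0, 2.0)
_LINE_BRIGHTNESS = 60.0
_ELLIPSE_BRIGHTNESS = 90.0
#: Fraction of a particle's red brightness leaking into G and B.
_GB_LEAK = 0.15
#: Pixel threshold above which a particle's additive contribution counts
#: toward the true foreground area.
_TRUTH_AREA_LEVEL = 20.0


def _static_layer(config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Static red-channel additive layer and its boolean mask."""
    h, w = config.height, config.width
    layer = np.zeros((h, w), dtype=np.float32)
    if "line" in config.background_elements:
        # mooring line: 3-px-wide diagonal
        for off in (-1, 0, 1):
            rr, cc = _draw_line(0, max(0, off), h - 1, w - 1 + off)
            keep = (cc >= 0) & (cc < w)
            layer[rr[keep], cc[keep]] = _LINE_BRIGHTNESS
    if "ellipse" in config.background_elements:
        rr, cc = _draw_ellipse(
            int(h * 0.8), int(w * 0.15), h // 14, w // 10, shape=(h, w)
        )
        layer[rr, cc] = _ELLIPSE_BRIGHTNESS
    return layer, layer > 0


def _render_particles(
    xs: np.ndarray, rows: np.ndarray, radii: np.ndarray, bright: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Additive Gaussian-disc layer for one frame (red channel)."""
    h, w = shape
    layer = np.zeros((h, w), dtype=np.float32)
    for x, r0, rad, b in zip(xs, rows, radii, bright):
        sigma = max(rad / 2.0, 0.5)
        ext = int(math.ceil(3 * sigma))
        c0, r0i = int(round(x)), int(round(r0))
        rlo, rhi = max(0, r0i - ext), min(h, r0i + ext + 1)
        clo, chi = max(0, c0 - ext), min(w, c0 + ext + 1)
        if rlo >= rhi or clo >= chi:
            continue
        yy = np.arange(rlo, rhi, dtype=np.float32)[:, None]
        xx = np.arange(clo, chi, dtype=np.float32)[None, :]
        g = np.exp(-((xx - x) ** 2 + (yy - r0) ** 2) / (2 * sigma**2))
        layer[rlo:rhi, clo:chi] += b * g
    return layer


def _compose(
    particle_layer: np.ndarray,
    static_layer: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = particle_layer.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    red = _BASE_RGB[0] + static_layer + particle_layer
    img[..., 0] = red
    img[..., 1] = _BASE_RGB[1] + _GB_LEAK * (static_layer + particle_layer)
    img[..., 2] = _BASE_RGB[2] + _GB_LEAK * (static_layer + particle_layer)
    if config.noise_sigma > 0:
        img += config.noise_sigma * rng.standard_normal(img.shape, dtype=np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


def _tide_rate_m_per_h(tide: TideSeries) -> np.ndarray:
    """Unsmoothed central-difference rate of the tide, m/h."""
    if tide.rate is not None:
        return tide.rate
    t_h = tide.timestamps / 3600.0
    return np.gradient(tide.level, t_h)


def generate_scene(
    config: SceneConfig, tide: TideSeries, start_time: Optional[datetime] = None
) -> tuple[list[FrameStack], SceneTruth]:
    """Render a tide-driven particle deployment with ground truth.

    Segments follow the camera's duty cycle (``on_min`` minutes recording,
    ``off_min`` pause) across ``total_hours``; only the first
    ``frames_per_segment`` frames of each segment are rendered, which are
    the frames the measurement stages consume. Particle count per segment is
    a Poisson draw at ``particle_density``; particles persist within a
    segment and are re-injected on the upstream edge when they exit, holding
    the expected density.

    Returns the rendered segments and a :class:`SceneTruth` recording every
    imposed quantity.
    """
    if start_time is None:
        start_time = datetime.fromtimestamp(tide.timestamps[0], tz=timezone.utc)
    t0 = start_time.timestamp()
    t_end = t0 + config.total_hours * 3600
    if tide.timestamps[0] > t0 or tide.timestamps[-1] < t_end:
        raise ValueError("tide series must span the video duration")

    rng = np.random.default_rng(config.seed)
    rate_all = _tide_rate_m_per_h(tide)
    schedule = generate_schedule(
        start_time, config.total_hours, config.on_min, config.off_min
    )
    static_layer, static_mask = _static_layer(config)
    theta = math.radians(config.flow_axis_deg)
    h, w = config.height, config.width

    truth = SceneTruth(
        static_mask=static_mask,
        flow_axis_deg=config.flow_axis_deg,
        flow_gain=config.flow_gain,
    )
    segments: list[FrameStack] = []

    for si, (seg_start, seg_dur) in enumerate(schedule):
        n_frames = min(config.frames_per_segment, int(round(seg_dur * config.fps)))
        n_particles = rng.poisson(config.particle_density)
        xs = rng.uniform(0, w, n_particles)
        rows = rng.uniform(0, h, n_particles)
        radii = rng.uniform(*config.radius_range, n_particles)
        bright = rng.uniform(*config.brightness_range, n_particles)

        frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
        seg_counts, seg_pos, seg_flow, seg_area = [], [], [], []
        for f in range(n_frames):
            t_frame = seg_start.timestamp() + f / config.fps
            rate = float(np.interp(t_frame, tide.timestamps, rate_all))
            u = config.flow_gain * rate * math.cos(theta)
            v_up = config.flow_gain * rate * math.sin(theta)

            layer = _render_particles(xs, rows, radii, bright, (h, w))
            frames[f] = _compose(layer, static_layer, config, rng)
            seg_counts.append(len(xs))
            seg_pos.append(np.column_stack([xs, rows]) if len(xs) else np.empty((0, 2)))
            seg_flow.append((u, v_up))
            seg_area.append(int(np.count_nonzero(layer > _TRUTH_AREA_LEVEL)))

            # advect into the next frame; v_up positive moves toward smaller rows
            xs = xs + u + rng.normal(0, config.jitter_sigma, len(xs))
            rows = rows - v_up + rng.normal(0, config.jitter_sigma, len(rows))
            out = (xs < 0) | (xs >= w) | (rows < 0) | (rows >= h)
            n_out = int(np.count_nonzero(out))
            if n_out:
                # re-inject on the edge the flow enters from
                xs[out] = np.where(u >= 0, 0.0, w - 1e-3) if abs(u) >= abs(v_up) else rng.uniform(0, w, n_out)
                rows[out] = rng.uniform(0, h, n_out) if abs(u) >= abs(v_up) else (
                    np.where(-v_up >= 0, 0.0, h - 1e-3)
                )
                radii[out] = rng.uniform(*config.radius_range, n_out)
                bright[out] = rng.uniform(*config.brightness_range, n_out)

        truth.counts.append(seg_counts)
        truth.positions.append(seg_pos)
        truth.flow.append(seg_flow)
        truth.area_px.append(seg_area)
        segments.append(
            FrameStack(
                frames=frames,
                fps=config.fps,
                start_time=seg_start,
                segment_id=f"seg_{si:04d}",
            )
        )
    truth.validate()
    return segments, truth


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

@dataclass
class FirstFrameSpike:
    """Global brightness spike on frame 0 (camera switch-on artifact)."""

    amount: float = 80.0


@dataclass
class LensBlob:
    """Large static bright region: an organism attached to the lens."""

    onset: int
    duration: int
    area_px: int = 5000
    center: Optional[tuple] = None   # (row, col); defaults to frame centre


@dataclass
class SedimentGlow:
    """Gradual diffuse intensity ramp: sediment accumulating on the lens."""

    onset: int
    duration: int
    peak: float = 40.0


def inject_anomalies(
    stack: FrameStack, specs: Sequence
) -> tuple[FrameStack, list[dict]]:
    """Apply transient lens anomalies to a copy of ``stack``.

    Three kinds are supported (see the spec classes above); overlapping
    anomalies simply add. Returns the modified stack and a log of
    ``{"type", "onset", "duration", ...}`` entries. With no specs the frames
    are returned bit-identical.
    """
    frames = stack.frames.astype(np.float32).copy()
    n, h, w = frames.shape[:3]
    log: list[dict] = []
    for spec in specs:
        if isinstance(spec, FirstFrameSpike):
            frames[0] += spec.amount
            log.append({"type": "first_frame_spike", "onset": 0, "duration": 1,
                        "amount": spec.amount})
        elif isinstance(spec, LensBlob):
            if not (0 <= spec.onset < n) or spec.onset + spec.duration > n:
                raise ValueError("LensBlob frames out of range")
            r0, c0 = spec.center if spec.center else (h // 2, w // 2)
            radius = math.sqrt(spec.area_px / math.pi)
            rr, cc = _draw_ellipse(r0, c0, radius, radius, shape=(h, w))
            frames[spec.onset:spec.onset + spec.duration, rr, cc, 0] += 120.0
            frames[spec.onset:spec.onset + spec.duration, rr, cc, 1:] += 20.0
            log.append({"type": "attachment", "onset": spec.onset,
                        "duration": spec.duration, "area_px": int(len(rr))})
        elif isinstance(spec, SedimentGlow):
            if not (0 <= spec.onset < n) or spec.onset + spec.duration > n:
                raise ValueError("SedimentGlow frames out of range")
            ramp = np.linspace(0.0, spec.peak, spec.duration)
            for k, amt in enumerate(ramp):
                frames[spec.onset + k, ..., 0] += amt
            log.append({"type": "glow", "onset": spec.onset,
                        "duration": spec.duration, "peak": spec.peak})
        else:
            raise TypeError(f"unknown anomaly spec: {spec!r}")
    out = dataclasses.replace(
        stack, frames=np.clip(frames, 0, 255).astype(np.uint8)
    )
    return out, log


# ---------------------------------------------------------------------------
# Schedule, audio, sensor log, detection table
# ---------------------------------------------------------------------------

def generate_schedule(
    start: datetime, total_hours: float, on_min: float = 10.0, off_min: float = 0.0
) -> list[tuple[datetime, float]]:
    """Recording schedule: (segment start, duration s) tiling the deployment.

    Segments start every ``on_min + off_min`` minutes while the start lies
    inside ``[start, start + total_hours)``; a final segment may be partial.
    The study's duty cycle (10 min on, 10 min off over ~74.33 h) yields 223
    segments, i.e. 37 h of footage.
    """
    if on_min <= 0 or off_min < 0:
        raise ValueError("on_min must be positive and off_min non-negative")
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    period_min = on_min + off_min
    total_min = total_hours * 60.0
    out: list[tuple[datetime, float]] = []
    k = 0
    while k * period_min < total_min - 1e-9:
        seg_start = start + timedelta(minutes=k * period_min)
        dur_min = min(on_min, total_min - k * period_min)
        out.append((seg_start, dur_min * 60.0))
        k += 1
    return out


def generate_test_audio(
    duration_s: float,
    fs: float,
    tones: Sequence[tuple] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum-of-sinusoids plus white noise, for spectrogram testing.

    ``tones`` is a sequence of (frequency Hz, amplitude) pairs; every tone
    must lie strictly below the Nyquist frequency fs/2.
    """
    for f, _ in tones:
        if f >= fs / 2:
            raise ValueError(f"tone at {f} Hz is at/above Nyquist ({fs / 2} Hz)")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a in tones:
        x += a * np.sin(2 * np.pi * f * t)
    if noise_sigma > 0:
        x += np.random.default_rng(seed).normal(0, noise_sigma, n)
    return x


def generate_sensor_log(
    tide: TideSeries,
    bottom_depth_m: float = 260.0,
    temperature_c: float = -0.18,
    tilt_deg: float = 3.6,
    noise_mv: float = 169.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Release-sensor log: depth follows the tide, other channels near-constant."""
    rng = np.random.default_rng(seed)
    n = tide.timestamps.size
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(tide.timestamps, unit="s", utc=True),
            "depth_m": bottom_depth_m + tide.level + rng.normal(0, 0.05, n),
            "temperature_c": temperature_c + rng.normal(0, 0.02, n),
            "tilt_deg": tilt_deg + rng.normal(0, 0.05, n),
            "noise_mv": noise_mv + rng.normal(0, 5.0, n),
        }
    )


#: Composition of the synthetic detection table: 478 detections with integer
#: shares matching the study's printed percentages (47/26/8/8 % for the four
#: dominant taxa).
DEFAULT_TAXON_COUNTS: dict[str, int] = {
    "Amphipoda": 225,
    "Copepoda": 124,
    "Hydrozoa": 37,
    "Chaetognatha": 37,
    "Unidentified": 35,
    "Decapoda": 6,
    "Liparidae": 4,
    "Pterotracheoidea": 4,
    "Ctenophora": 4,
    "Mysida": 1,
    "Polychaeta": 1,
}


def generate_detection_table(
    start: datetime,
    video_hours: float = 223 * 10 / 60.0,
    taxon_counts: Optional[dict[str, int]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotated detection table with a known taxon composition.

    One row per detected organism: detection time (uniform over the recorded
    span), the video file index it falls in, and the taxon label. Defaults
    reproduce the study-scale composition (478 detections over 37 h).
    """
    counts = dict(taxon_counts) if taxon_counts else dict(DEFAULT_TAXON_COUNTS)
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    rng = np.random.default_rng(seed)
    taxa = [t for t, c in counts.items() for _ in range(c)]
    minutes = np.sort(rng.uniform(0, video_hours * 60.0, len(taxa)))
    rng.shuffle(taxa)
    return pd.DataFrame(
        {
            "time_utc": [start + timedelta(minutes=float(m)) for m in minutes],
            "video_id": (minutes // 10).astype(int),
            "taxon": taxa,
            "notes": "",
        }
    )
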