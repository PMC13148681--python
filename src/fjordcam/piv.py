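"""Digital particle image velocimetry (DPIV) core.

Displacement between two background-removed frames is estimated per
interrogation window as the peak of the FFT cross-correlation of the
mean-subtracted windows, refined to sub-pixel precision with a 3-point
Gaussian fit in each axis. Multi-pass refinement halves the window and
offsets the second frame's windows by the previous pass's (rounded)
displacement. Spurious vectors are rejected with the normalized median
test, and a segment's vector fields are reduced to a single dominant flow:
the mean vector magnitude and the circular mean direction.

Coordinate conventions: within a :class:`VectorField`, ``u`` is the
displacement along +x (columns) and ``v`` along +y in *image* rows
(positive downward). :class:`FlowVector` directions are reported in the
mathematical convention (degrees counterclockwise from +x with y pointing
up), i.e. the image rows are flipped before the angle is taken.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VectorField",
    "FlowVector",
    "piv_pair",
    "validate_vectors",
    "dominant_flow",
    "circular_mean_deg",
]


@dataclass
class VectorField:
    """PIV displacements on a regular interrogation grid (px/frame)."""

    x: np.ndarray            # window-centre columns, 2-D grid
    y: np.ndarray            # window-centre rows, 2-D grid
    u: np.ndarray            # px/frame along +x
    v: np.ndarray            # px/frame along +y (image rows, downward)
    valid: np.ndarray        # bool mask
    peak_ratio: np.ndarray   # first/second correlation-peak ratio
    window_px: int = 0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x, self.y, self.u, self.v, self.valid)}
        if len(shapes) != 1:
            raise ValueError("all grids must share one shape")
        if np.any(~np.isfinite(self.u[self.valid])) or np.any(
            ~np.isfinite(self.v[self.valid])
        ):
            raise ValueError("valid vectors must be finite")


@dataclass
class FlowVector:
    """Dominant flow of one video segment."""

    segment_id: str
    time: Optional[datetime]
    speed_px_s: float
    direction_deg: float       # [0, 360), CCW from +x, y-up
    n_vectors_used: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if self.speed_px_s < 0:
                raise ValueError("speed must be non-negative")
            self.direction_deg = float(self.direction_deg) % 360.0


def _gauss_interp(cm: float, c0: float, cp: float) -> float:
    """3-point Gaussian peak interpolation; 0 if not applicable."""
    if min(cm, c0, cp) <= 0:
        return 0.0
    lm, l0, lp = math.log(cm), math.log(c0), math.log(cp)
    denom = 2.0 * (lm + lp - 2.0 * l0)
    if denom >= 0:  # not a local max in log space
        return 0.0
    return (lm - lp) / denom


def _gauss_interp_vec(cm: np.ndarray, c0: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Vectorized 3-point Gaussian peak interpolation (0 where inapplicable)."""
    ok = (cm > 0) & (c0 > 0) & (cp > 0)
    lm = np.log(np.where(ok, cm, 1.0))
    l0 = np.log(np.where(ok, c0, 1.0))
    lp = np.log(np.where(ok, cp, 1.0))
    denom = 2.0 * (lm + lp - 2.0 * l0)
    ok &= denom < 0
    return np.where(ok, (lm - lp) / np.where(ok, denom, -1.0), 0.0)


def _single_pass(
    a: np.ndarray,
    b: np.ndarray,
    window: int,
    step: int,
    offsets_u: np.ndarray,
    offsets_v: np.ndarray,
) -> VectorField:
    """One interrogation pass over all windows, batched through the FFT."""
    h, w = a.shape
    rows = np.arange(0, h - window + 1, step)
    cols = np.arange(0, w - window + 1, step)
    ny, nx = len(rows), len(cols)
    half = window // 2
    search = window // 3  # restrict peak search to the central region
    centre = window // 2

    aview = np.lib.stride_tricks.sliding_window_view(a, (window, window))
    bview = np.lib.stride_tricks.sliding_window_view(b, (window, window))
    rb0 = np.clip(rows[:, None] + offsets_v.astype(int), 0, h - window)
    cb0 = np.clip(cols[None, :] + offsets_u.astype(int), 0, w - window)
    aw = aview[rows[:, None], cols[None, :]].astype(np.float64)
    bw = bview[rb0, cb0].astype(np.float64)
    aw = aw - aw.mean(axis=(-2, -1), keepdims=True)
    bw = bw - bw.mean(axis=(-2, -1), keepdims=True)
    valid = (aw.std(axis=(-2, -1)) > 1e-9) & (bw.std(axis=(-2, -1)) > 1e-9)

    # cyclic cross-correlation, zero displacement at the plane centre
    fa = np.fft.rfft2(aw)
    fb = np.fft.rfft2(bw)
    corr = np.fft.fftshift(
        np.fft.irfft2(np.conj(fa) * fb, s=(window, window)), axes=(-2, -1)
    )

    region = corr[..., centre - search:centre + search + 1,
                  centre - search:centre + search + 1]
    flat = region.reshape(ny, nx, -1)
    am = np.argmax(flat, axis=-1)
    side = 2 * search + 1
    pi = am // side + centre - search
    pj = am % side + centre - search
    ii, jj = np.indices((ny, nx))
    peak = corr[ii, jj, pi, pj]
    valid &= peak > 0

    dj = _gauss_interp_vec(corr[ii, jj, pi, pj - 1], peak, corr[ii, jj, pi, pj + 1])
    di = _gauss_interp_vec(corr[ii, jj, pi - 1, pj], peak, corr[ii, jj, pi + 1, pj])
    u = (pj - centre) + dj + (cb0 - cols[None, :])
    v = (pi - centre) + di + (rb0 - rows[:, None])

    # peak-to-second-peak ratio with a 3x3 exclusion zone around the peak
    masked = corr.copy()
    for doff in (-1, 0, 1):
        for joff in (-1, 0, 1):
            masked[ii, jj, pi + doff, pj + joff] = -np.inf
    second = masked.max(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, peak / second, np.inf)

    u = np.where(valid, u, 0.0)
    v = np.where(valid, v, 0.0)
    yy, xx = np.meshgrid(rows + half, cols + half, indexing="ij")
    return VectorField(xx.astype(float), yy.astype(float), u, v, valid, ratio, window)


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int = 64,
    overlap_fraction: float = 0.5,
    passes: int = 2,
) -> VectorField:
    """Estimate the displacement field from frame_a to frame_b.

    Frames should be background-removed grayscale residuals of equal shape.
    ``passes > 1`` runs a coarse-to-fine scheme: each pass halves the window
    (never below 16 px) and offsets the second frame's interrogation windows
    by the previous field, nearest-neighbour interpolated to the finer grid.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if a.ndim != 2:
        raise ValueError("piv_pair expects 2-D grayscale residuals")
    if window_px < 16:
        raise ValueError("window_px must be at least 16")
    if window_px > min(a.shape):
        raise ValueError("interrogation window larger than the image")
    if passes < 1:
        raise ValueError("passes must be >= 1")

    field: Optional[VectorField] = None
    win = window_px
    for p in range(passes):
        step = max(int(round(win * (1.0 - overlap_fraction))), 1)
        rows = np.arange(0, a.shape[0] - win + 1, step)
        cols = np.arange(0, a.shape[1] - win + 1, step)
        if field is None:
            off_u = np.zeros((len(rows), len(cols)))
            off_v = np.zeros((len(rows), len(cols)))
        else:
            off_u = _interp_to_grid(field, rows + win // 2, cols + win // 2, "u")
            off_v = _interp_to_grid(field, rows + win // 2, cols + win // 2, "v")
        field = _single_pass(a, b, win, step, np.round(off_u), np.round(off_v))
        if p < passes - 1:
            win = max(win // 2, 16)
    assert field is not None
    return field


def _interp_to_grid(
    field: VectorField, rows: np.ndarray, cols: np.ndarray, comp: str
) -> np.ndarray:
    """Nearest-neighbour interpolation of a component to a new grid."""
    src = getattr(field, comp)
    src = np.where(field.valid, src, 0.0)
    y_src = field.y[:, 0]
    x_src = field.x[0, :]
    iy = np.clip(np.searchsorted(y_src, rows), 0, len(y_src) - 1)
    ix = np.clip(np.searchsorted(x_src, cols), 0, len(x_src) - 1)
    return src[np.ix_(iy, ix)]


def validate_vectors(
    field: VectorField,
    eps: float = 0.1,
    residual_threshold: float = 2.0,
    min_peak_ratio: float = 1.2,
) -> VectorField:
    """Vector validation: correlation-quality filter + normalized median test.

    Vectors whose first-to-second correlation peak ratio falls below
    ``min_peak_ratio`` are rejected outright (ambiguous correlation). Then,
    for each vector, the residual against the median of its valid
    8-neighbours is normalized by the median neighbour fluctuation plus
    ``eps``; vectors whose combined (u, v) normalized residual exceeds
    ``residual_threshold`` are marked invalid. No in-fill is performed.
    """
    field = VectorField(
        field.x, field.y, field.u, field.v,
        field.valid & (field.peak_ratio > min_peak_ratio),
        field.peak_ratio, field.window_px,
    )
    ny, nx = field.u.shape
    norm = np.zeros((ny, nx))
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    for comp in (field.u, field.v):
        padded = np.full((ny + 2, nx + 2), np.nan)
        padded[1:-1, 1:-1] = np.where(field.valid, comp, np.nan)
        neigh = np.stack(
            [padded[1 + di:ny + 1 + di, 1 + dj:nx + 1 + dj] for di, dj in offsets],
            axis=-1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            med = np.nanmedian(neigh, axis=-1)
            fluct = np.nanmedian(np.abs(neigh - med[..., None]), axis=-1)
        res = np.abs(comp - med) / (fluct + eps)
        norm += np.where(np.isfinite(res), res, 0.0) ** 2
    bad = np.sqrt(norm) > residual_threshold
    new_valid = field.valid & ~bad
    return VectorField(
        field.x, field.y, field.u, field.v, new_valid, field.peak_ratio,
        field.window_px,
    )


def circular_mean_deg(angles_deg: np.ndarray, weights: Optional[np.ndarray] = None) -> float:
    """Resultant-vector mean of angles in degrees."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = float(np.sum(w * np.sin(a)))
    c = float(np.sum(w * np.cos(a)))
    ang = math.degrees(math.atan2(s, c)) % 360.0
    return 0.0 if 360.0 - ang < 1e-9 else ang


def dominant_flow(
    fields: Sequence[VectorField],
    fps: float,
    segment_id: str = "",
    time: Optional[datetime] = None,
) -> FlowVector:
    """Reduce a segment's vector fields to one dominant flow.

    Speed is the arithmetic mean of valid vector magnitudes scaled by the
    frame rate; direction is the circular mean of valid vector angles (rows
    flipped to the y-up convention). With zero valid vectors the result is
    marked missing rather than zero.
    """
    if not fields:
        raise ValueError("need at least one vector field (one frame pair)")
    us, vs = [], []
    for f in fields:
        us.append(f.u[f.valid])
        vs.append(f.v[f.valid])
    u = np.concatenate(us)
    v = np.concatenate(vs)
    if u.size == 0:
        return FlowVector(segment_id, time, float("nan"), float("nan"), 0, missing=True)
    speed = float(np.mean(np.hypot(u, v))) * fps
    angles = np.degrees(np.arctan2(-v, u))  # flip rows: y-up
    direction = circular_mean_deg(angles)
    return FlowVector(segment_id, time, speed, direction, int(u.size))
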