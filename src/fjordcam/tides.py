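"""Tidal forcing and flow–tide coupling statistics.

The forcing variable is the rate of change of sea level (central finite
difference, median-smoothed over a 2-h window). Dominant-flow directions are
linearized against the deployment's flow axis with a signed wrapped angle
(or equivalently a signed speed projection) before Pearson correlation, and
raw periodograms with chi-squared 95% confidence bounds screen the feature
series for cyclicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .piv import FlowVector
from .synthetic import TideSeries

__all__ = [
    "CorrelationResult",
    "PsdEstimate",
    "sea_level_rate",
    "align_series",
    "signed_angle",
    "signed_speed",
    "estimate_flow_axis",
    "pearson",
    "periodogram",
]


@dataclass
class CorrelationResult:
    """Pearson correlation between two aligned series."""

    r: float
    p_value: float
    n: int
    variables: str = ""
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("|r| must not exceed 1")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


@dataclass
class PsdEstimate:
    """Raw periodogram with per-ordinate chi-squared (2 dof) 95% bounds."""

    frequencies: np.ndarray   # 1/h
    power: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(self.lo95 > self.power) or np.any(self.hi95 < self.power):
            raise ValueError("bounds must bracket the power")

    def peak_frequency(self, skip_dc: bool = True) -> float:
        """Frequency (1/h) of the largest ordinate."""
        p = self.power.copy()
        if skip_dc and self.frequencies[0] == 0:
            p[0] = -np.inf
        return float(self.frequencies[int(np.argmax(p))])


def sea_level_rate(tide: TideSeries, smooth_window_h: float = 2.0) -> np.ndarray:
    """Smoothed rate of change of sea level, m/h.

    Central finite difference of the level, then a centered sliding median
    over ``smooth_window_h`` hours (2 h by default). Pass 0 to skip
    smoothing.
    """
    if tide.timestamps.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    t_h = tide.timestamps / 3600.0
    rate = np.gradient(tide.level, t_h)
    if smooth_window_h > 0:
        from .particles import sliding_median

        cadence_min = tide.interval_s / 60.0
        rate = sliding_median(rate, smooth_window_h, cadence_min)
    return rate


def align_series(
    flows: Sequence[FlowVector],
    tide: TideSeries,
    rate: Optional[np.ndarray] = None,
) -> tuple[list[FlowVector], np.ndarray]:
    """Pair each non-missing flow vector with the interpolated tide rate.

    The tide rate (computed with :func:`sea_level_rate` if not supplied) is
    linearly interpolated to each flow timestamp; flows marked missing or
    outside the tide span are dropped. Returns the kept flows and the
    matching rate values.
    """
    if rate is None:
        rate = sea_level_rate(tide)
    kept = [
        f for f in flows
        if not f.missing
        and f.time is not None
        and tide.timestamps[0] <= f.time.timestamp() <= tide.timestamps[-1]
    ]
    if not kept:
        raise ValueError("no overlap between flow series and tide series")
    t = np.array([f.time.timestamp() for f in kept])
    return kept, np.interp(t, tide.timestamps, rate)


def signed_angle(direction_deg: float | np.ndarray, flow_axis_deg: float) -> np.ndarray | float:
    """Wrapped difference direction − axis, mapped to (−180, 180].

    Linearizes the circular flow direction against a fixed deployment axis
    so that it can enter a Pearson correlation; reversal of the flow maps
    0 ↔ ±180 consistently.
    """
    d = (np.asarray(direction_deg, dtype=float) - flow_axis_deg) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    return float(d) if np.isscalar(direction_deg) else d


def signed_speed(
    speed: np.ndarray, direction_deg: np.ndarray, flow_axis_deg: float
) -> np.ndarray:
    """Speed projected onto the flow axis: speed · cos(direction − axis)."""
    return np.asarray(speed) * np.cos(
        np.radians(np.asarray(direction_deg) - flow_axis_deg)
    )


def estimate_flow_axis(directions_deg: np.ndarray) -> float:
    """Dominant flow axis (mod 180) from a sample of directions.

    The axis is the circular mean of the doubled angles (standard axial
    statistics); of its two orientations, the one closer to the circular
    mean direction of the sample is returned, which makes the choice
    deterministic for a given sample.
    """
    a2 = np.radians(2.0 * np.asarray(directions_deg, dtype=float))
    axis = math.degrees(math.atan2(np.mean(np.sin(a2)), np.mean(np.cos(a2)))) / 2.0
    axis %= 180.0
    a = np.radians(np.asarray(directions_deg, dtype=float))
    mean_dir = math.degrees(math.atan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0
    alt = (axis + 180.0) % 360.0
    d0 = abs(signed_angle(mean_dir, axis))
    d1 = abs(signed_angle(mean_dir, alt))
    return axis if d0 <= d1 else alt


def pearson(x: np.ndarray, y: np.ndarray, variables: str = "") -> CorrelationResult:
    """Pearson r with a two-sided t-distribution p-value.

    Zero variance in either input yields an invalid (flagged) result rather
    than an exception from downstream arithmetic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), x.size, variables, valid=False)
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size, variables)


def periodogram(series: np.ndarray, cadence_min: float) -> PsdEstimate:
    """Raw periodogram of a uniformly sampled series, frequencies in 1/h.

    Each ordinate of a raw periodogram is distributed as the true PSD times
    a chi-squared variable with 2 degrees of freedom; the 95% interval for
    the underlying PSD at each frequency is therefore
    ``[2 P / chi2_{0.975, 2}, 2 P / chi2_{0.025, 2}]``.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 4:
        raise ValueError("series must have at least 4 samples")
    if cadence_min <= 0:
        raise ValueError("cadence must be positive")
    fs_per_h = 60.0 / cadence_min
    freqs, power = signal.periodogram(
        series, fs=fs_per_h, detrend=False, scaling="density"
    )
    lo = 2.0 * power / stats.chi2.ppf(0.975, 2)
    hi = 2.0 * power / stats.chi2.ppf(0.025, 2)
    return PsdEstimate(freqs, power, lo, hi)
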