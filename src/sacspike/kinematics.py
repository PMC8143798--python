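"""Microsaccade detection and kinematic description of eye traces.

Gaze position is sampled uniformly (typically 1 kHz) in degrees of visual
angle.  Detection follows the field-standard adaptive-velocity-threshold
approach for microsaccades: radial eye velocity is compared against a
multiple of a median-based estimate of its noise spread, so the threshold
adapts to session-wise noise differences.  Detected events are then refined
to a lower onset/offset threshold so that onset times are accurate to the
sample level even for movements of ~0.1 deg.

Angle convention: 0 deg is rightward, angles increase counter-clockwise,
and all directions live in [0, 360).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np


class KinematicsError(ValueError):
    pass


@dataclass
class EyeTrace:
    """Uniformly sampled gaze position for one trial (time in ms, x/y in deg)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise KinematicsError("time, x, y must have identical shapes")
        if self.time.ndim != 1 or self.time.size < 2:
            raise KinematicsError("a trace needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise KinematicsError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise KinematicsError("sampling interval must be constant")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise KinematicsError("gaze samples must be finite (no gaps)")

    @property
    def dt_ms(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EyeTrace):
            return NotImplemented
        return (np.array_equal(self.time, other.time)
                and np.array_equal(self.x, other.x)
                and np.array_equal(self.y, other.y))


@dataclass
class Saccade:
    """One detected movement; amplitude is the onset-to-offset Euclidean step."""

    onset_ms: float
    peak_vel_ms: float
    offset_ms: float
    amplitude: float
    peak_velocity: float
    direction: float
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not self.onset_ms < self.peak_vel_ms < self.offset_ms:
            raise KinematicsError(
                f"saccade times must satisfy onset < peak < offset, got "
                f"{self.onset_ms}, {self.peak_vel_ms}, {self.offset_ms}")
        if self.amplitude < 0:
            raise KinematicsError("amplitude must be >= 0")
        if self.peak_velocity <= 0:
            raise KinematicsError("peak velocity must be > 0")
        self.direction = float(self.direction) % 360.0


class DirectionClass(Enum):
    TOWARD = "toward"
    OPPOSITE = "opposite"


@dataclass
class DetectParams:
    """Tunables of the adaptive-threshold detector.

    lambda_thresh
        Detection threshold as a multiple of the median-based SD of radial
        velocity (robust to the saccades themselves).
    onset_lambda
        Lower multiple used when walking the event edges outward; governs
        onset/offset accuracy.
    min_threshold
        Floor on the detection threshold (deg/s) so that noiseless traces do
        not yield a zero threshold.
    min_duration_ms
        Shortest admissible event after edge refinement.
    min_core_ms
        Minimum time the velocity must stay above the high threshold;
        rejects single-sample noise exceedances.
    merge_interval_ms
        Events separated by less than this are merged into one.
    smooth_samples
        Width (samples) of the moving-average position smoothing applied
        before differentiation.
    """

    lambda_thresh: float = 6.0
    onset_lambda: float = 3.0
    min_threshold: float = 3.0
    min_duration_ms: float = 6.0
    min_core_ms: float = 3.0
    merge_interval_ms: float = 20.0
    smooth_samples: int = 5


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def velocity_components(trace: EyeTrace, smooth_samples: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference x/y velocity (deg/s) after light position smoothing."""
    if len(trace) < 3:
        raise KinematicsError("velocity needs at least 3 samples")
    dt_s = trace.dt_ms / 1000.0
    vx = np.empty(len(trace))
    vy = np.empty(len(trace))
    xs = _smooth(trace.x, smooth_samples)
    ys = _smooth(trace.y, smooth_samples)
    vx[1:-1] = (xs[2:] - xs[:-2]) / (2 * dt_s)
    vy[1:-1] = (ys[2:] - ys[:-2]) / (2 * dt_s)
    vx[0] = (xs[1] - xs[0]) / dt_s
    vy[0] = (ys[1] - ys[0]) / dt_s
    vx[-1] = (xs[-1] - xs[-2]) / dt_s
    vy[-1] = (ys[-1] - ys[-2]) / dt_s
    return vx, vy


def radial_velocity(trace: EyeTrace, smooth_samples: int = 5) -> np.ndarray:
    """Magnitude of eye velocity (deg/s), same length as the trace."""
    vx, vy = velocity_components(trace, smooth_samples)
    return np.hypot(vx, vy)


def _median_sd(v: np.ndarray) -> float:
    # Robust spread of a SIGNED velocity component:
    # sqrt(median(v^2) - median(v)^2).  Insensitive to the saccadic samples
    # that inflate a plain SD; must be applied per component (on the
    # nonnegative radial speed it would be identically zero).
    med = np.median(v)
    var = np.median(v ** 2) - med ** 2
    return math.sqrt(max(var, 0.0))


def detect_saccades(trace: EyeTrace, params: DetectParams | None = None,
                    trial_id: str = "") -> list[Saccade]:
    """Detect (micro)saccades in one trace.

    Returns non-overlapping events sorted by onset; an empty list is a valid
    result.  Amplitude is the Euclidean displacement between the smoothed
    positions at the refined onset and offset samples.
    """
    params = params or DetectParams()
    if len(trace) < 3:
        return []
    vx, vy = velocity_components(trace, params.smooth_samples)
    v = np.hypot(vx, vy)
    # endpoint positions from the smoothed trace: averages out sample noise
    # that would otherwise inflate small amplitudes
    xs = _smooth(trace.x, params.smooth_samples)
    ys = _smooth(trace.y, params.smooth_samples)
    # elliptic threshold with per-component median-based noise spread
    sig_floor = params.min_threshold / params.lambda_thresh
    sx = max(_median_sd(vx), sig_floor)
    sy = max(_median_sd(vy), sig_floor)
    lam, lam_low = params.lambda_thresh, params.onset_lambda
    ex = (vx / sx) ** 2 + (vy / sy) ** 2
    above = ex > lam ** 2
    if not above.any():
        return []
    # contiguous super-threshold runs
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(np.flatnonzero(above[1:] & ~above[:-1]) + 1)
    ends = list(np.flatnonzero(above[:-1] & ~above[1:]) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    del edges

    dt = trace.dt_ms
    # walk each run outward to the lower threshold
    refined: list[tuple[int, int]] = []
    low2 = lam_low ** 2
    for s, e in zip(starts, ends):
        if (e - s) * dt < params.min_core_ms:
            continue
        while s > 0 and ex[s - 1] > low2:
            s -= 1
        while e < ex.size and ex[e] > low2:
            e += 1
        # continue down the flanks to the local speed minimum, which removes
        # the threshold-crossing bias from onset/offset times; capped at the
        # smoothing half-width so the smoothing skirt is not swallowed
        cap = params.smooth_samples // 2
        s0, e0 = s, e
        while s > max(0, s0 - cap) and v[s - 1] < v[s]:
            s -= 1
        while e < min(v.size, e0 + cap) and v[e] < v[e - 1]:
            e += 1
        refined.append((s, e))
    # merge events closer than merge_interval_ms (or overlapping after refinement)
    merged: list[list[int]] = []
    for s, e in refined:
        if merged and (s - merged[-1][1]) * dt < params.merge_interval_ms:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out: list[Saccade] = []
    for s, e in merged:
        if (e - s) * dt < params.min_duration_ms:
            continue
        seg = slice(s, e)
        ipk = s + int(np.argmax(v[seg]))
        if not s < ipk < e - 1:
            ipk = min(max(ipk, s + 1), e - 2)
            if not s < ipk:
                continue
        dx = xs[e - 1] - xs[s]
        dy = ys[e - 1] - ys[s]
        out.append(Saccade(
            onset_ms=float(trace.time[s]),
            peak_vel_ms=float(trace.time[ipk]),
            offset_ms=float(trace.time[e - 1]),
            amplitude=float(np.hypot(dx, dy)),
            peak_velocity=float(v[ipk]),
            direction=math.degrees(math.atan2(dy, dx)) % 360.0,
            trial_id=trial_id,
        ))
    return out


def radial_position(trace: EyeTrace, s: Saccade) -> np.ndarray:
    """Euclidean distance of each in-saccade sample from the onset position."""
    mask = (trace.time >= s.onset_ms) & (trace.time <= s.offset_ms)
    if not mask.any() or trace.time[0] > s.onset_ms or trace.time[-1] < s.offset_ms:
        raise KinematicsError("saccade interval must lie inside the trace")
    idx = np.flatnonzero(mask)
    x0, y0 = trace.x[idx[0]], trace.y[idx[0]]
    return np.hypot(trace.x[mask] - x0, trace.y[mask] - y0)


def angular_distance(a: float, b: float) -> float:
    """Absolute angular separation on the circle, in [0, 180]."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def classify_direction(s: Saccade, rf_direction: float,
                       halfwidth: float = 90.0) -> DirectionClass:
    """Toward/opposite split of a movement relative to an RF direction.

    Movements within ``halfwidth`` degrees (inclusive) of the RF direction on
    the circle are 'toward'; everything else is 'opposite'.
    """
    if not 0.0 <= rf_direction < 360.0:
        raise KinematicsError("rf_direction must lie in [0, 360)")
    if angular_distance(s.direction, rf_direction) <= halfwidth:
        return DirectionClass.TOWARD
    return DirectionClass.OPPOSITE
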