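"""Skeleton trace -> projected joint angles, smoothing, ROM extraction.

The angle for a movement is obtained by connecting the movement's two
joints into a measurement vector, projecting that vector onto the
movement's anatomical plane, and taking the signed angle to the
movement's zero reference, in degrees.  A per-frame angle series is
smoothed with an exponential moving average, its maximum is the range of
motion (ROM), and a finite-difference angular-velocity profile is
attached for movement-quality inspection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .catalog import PLANE_AXES, MovementSpec
from .joints import MissingJointError, SkeletonFrame, SkeletonTrace

#: Minimum norm of an in-plane projection before it counts as degenerate.
PROJECTION_EPS = 1e-9

#: Longest run of consecutive frames with a missing required joint that is
#: bridged by linear interpolation; longer gaps raise.
DEFAULT_MAX_GAP = 5

#: Default exponential-moving-average smoothing factor.
DEFAULT_ALPHA = 0.3


class DegenerateProjectionError(ValueError):
    """The measurement vector projects to (numerically) zero in the plane."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


@dataclass
class AngleTrace:
    """Per-frame projected angles (degrees) with optional angular velocity."""

    movement_id: str
    timestamps: np.ndarray
    angles: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.angles = np.asarray(self.angles, float)
        if self.timestamps.shape != self.angles.shape:
            raise ValueError("timestamps and angles must have equal length")
        if not np.isfinite(self.angles).all():
            raise ValueError("angles must be finite")


@dataclass
class RomResult:
    """Range-of-motion summary for one movement execution.

    ``max_angle`` is the smoothed maximum after the catalog cap, reported
    to 0.1 degree (the device's display resolution).
    """

    movement_id: str
    side: str
    max_angle: float
    time_of_max: float
    peak_velocity: float
    capped: bool = False


def measurement_vector(frame: SkeletonFrame, spec: MovementSpec) -> np.ndarray:
    """Vector from the movement's proximal joint to its distal joint."""
    v = frame.position(spec.distal_joint) - frame.position(spec.proximal_joint)
    if np.linalg.norm(v) == 0:
        raise DegenerateProjectionError(
            f"joints {spec.proximal_joint!r} and {spec.distal_joint!r} coincide"
        )
    return v


def project_to_plane(v: np.ndarray, plane: str) -> np.ndarray:
    """Drop the coordinate normal to the anatomical plane.

    Plane axes keep their body-frame order: sagittal -> (y, z),
    frontal -> (x, y), transverse -> (x, z).  A zero projection is
    returned as-is; callers flag it downstream.
    """
    v = np.asarray(v, float)
    if not np.isfinite(v).all():
        raise ValueError("vector must be finite")
    i, j = PLANE_AXES[plane]
    return np.array([v[i], v[j]])


def projected_angle(
    v: np.ndarray, spec: MovementSpec, eps: float = PROJECTION_EPS
) -> float:
    """Signed in-plane angle (degrees) from the zero reference to ``v``.

    Positive scaling of ``v`` leaves the result unchanged.  The raw
    counter-clockwise angle in the plane's (first, second)-axis frame is
    multiplied by the spec's sign so the movement direction is positive.
    """
    u = project_to_plane(spec.zero_reference_vec, spec.plane)
    w = project_to_plane(v, spec.plane)
    if np.linalg.norm(w) <= eps:
        raise DegenerateProjectionError(
            f"measurement vector is normal to the {spec.plane} plane"
        )
    if np.linalg.norm(u) <= eps:
        raise DegenerateProjectionError(
            f"zero reference is normal to the {spec.plane} plane"
        )
    raw = math.degrees(math.atan2(u[0] * w[1] - u[1] * w[0], float(u @ w)))
    return spec.positive_sign * raw


def ema_smooth(series, alpha: float) -> np.ndarray:
    """Exponential moving average: s[0]=x[0], s[t]=a*x[t]+(1-a)*s[t-1]."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    if alpha == 1.0:
        return x.copy()
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, x.size):
        out[t] = alpha * x[t] + (1 - alpha) * out[t - 1]
    return out


def angular_velocity(
    trace: AngleTrace, first: str = "zero", inplace: bool = True
) -> np.ndarray:
    """Backward-difference angular velocity in degrees/second.

    The first sample has no predecessor; it is set to 0 (``first="zero"``)
    or to a copy of the second sample (``first="repeat"``).
    """
    t = trace.timestamps
    if t.size < 2:
        raise ValueError("velocity needs at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing (no duplicates)")
    vel = np.empty_like(trace.angles)
    vel[1:] = np.diff(trace.angles) / dt
    if first == "zero":
        vel[0] = 0.0
    elif first == "repeat":
        vel[0] = vel[1]
    else:
        raise ValueError("first must be 'zero' or 'repeat'")
    if inplace:
        trace.velocity = vel
    return vel


def _interpolate_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; hold edges; else raise."""
    x = values.copy()
    bad = np.isnan(x)
    if not bad.any():
        return x
    if bad.all():
        raise MissingJointError("all frames", None)
    idx = np.arange(x.size)
    # find runs of NaN
    runs = []
    start = None
    for i, b in enumerate(bad):
        if b and start is None:
            start = i
        elif not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, x.size - 1))
    for s, e in runs:
        if e - s + 1 > max_gap:
            raise MissingJointError(f"gap of {e - s + 1} frames", s)
    good = ~bad
    x[bad] = np.interp(idx[bad], idx[good], x[good])
    return x


def angle_trace(
    trace: SkeletonTrace,
    spec: MovementSpec,
    max_gap: int = DEFAULT_MAX_GAP,
) -> AngleTrace:
    """Per-frame projected angles with missing-joint gap interpolation.

    Frames in which either required joint is missing yield NaN and are
    linearly interpolated across runs of at most ``max_gap`` frames
    (edge runs are extrapolated by holding the nearest computed angle);
    longer runs raise :class:`~romagree.joints.MissingJointError`.
    """
    angles = np.full(len(trace), np.nan)
    first_error: DegenerateProjectionError | None = None
    for i, frame in enumerate(trace):
        if frame.is_missing(spec.proximal_joint) or frame.is_missing(spec.distal_joint):
            continue
        try:
            angles[i] = projected_angle(measurement_vector(frame, spec), spec)
        except DegenerateProjectionError as err:
            if first_error is None:
                first_error = DegenerateProjectionError(
                    f"{err} (frame {i})", frame_index=i
                )
            continue
    if np.isnan(angles).all():
        raise first_error or MissingJointError(spec.proximal_joint)
    angles = _interpolate_gaps(angles, max_gap)
    # The instantaneous signed angle lives on (-180, 180]; a continuous
    # movement past 180 deg wraps.  Unwrap over time so a sweep beyond the
    # straight-up position keeps increasing (that is what lets the
    # normal-range cap engage on hyperflexible excursions).
    angles = np.degrees(np.unwrap(np.radians(angles)))
    return AngleTrace(spec.movement_id, trace.timestamps, angles)


def extract_rom(
    trace: SkeletonTrace,
    spec: MovementSpec,
    alpha: float = DEFAULT_ALPHA,
    max_gap: int = DEFAULT_MAX_GAP,
) -> RomResult:
    """Smoothed maximum angle (ROM), its time, and the peak angular velocity.

    The per-frame angle series is EMA-smoothed, its maximum located, the
    catalog cap applied to that maximum, and the result rounded to 0.1
    degree.
    """
    at = angle_trace(trace, spec, max_gap=max_gap)
    smoothed = ema_smooth(at.angles, alpha)
    at = AngleTrace(spec.movement_id, at.timestamps, smoothed)
    vel = angular_velocity(at)
    i = int(np.argmax(smoothed))
    peak = float(smoothed[i])
    capped = spec.cap_degrees is not None and peak > spec.cap_degrees
    if capped:
        peak = float(spec.cap_degrees)
    return RomResult(
        movement_id=spec.movement_id,
        side=spec.side,
        max_angle=round(peak, 1),
        time_of_max=float(at.timestamps[i]),
        peak_velocity=float(np.max(np.abs(vel))),
        capped=capped,
    )
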