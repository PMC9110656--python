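"""Orientation estimation, gravity removal and task segmentation.

Accelerometers measure specific force — movement acceleration plus
gravity — in the moving sensor frame.  To recover pure movement
acceleration the sensor orientation is tracked with a complementary
quaternion filter: gyroscope strap-down integration, with the inclination
(tilt) component continuously corrected toward the gravity direction
observed by the accelerometer.  Heading (yaw) is unobservable without a
magnetometer and is left as integrated.  Acceleration is then rotated
into the world frame (z up) and g subtracted from the vertical axis.

Recordings are finally cut into per-task segments at the annotated start
and stop times, capped at 60 s; unattempted tasks are replaced by a 10 s
non-moving window from the same recording and scored 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import IMURecording, TaskSegment
from .quaternions import (
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    quats_to_matrices,
    rotate_vector_inverse,
)

logger = logging.getLogger(__name__)

GRAVITY = 9.81  # m/s^2

#: accelerometer correction is suspended when | ||a|| - g | exceeds this
#: fraction of g (high-dynamics guard)
_DYNAMIC_GUARD_FRACTION = 0.5

#: variance threshold on the linear-acceleration norm defining "non-moving"
_STILL_VARIANCE = 0.01  # (m/s^2)^2
_SUBSTITUTE_S = 10.0
_MAX_SEGMENT_S = 60.0


@dataclass
class OrientationTrajectory:
    """Per-sample sensor-to-world unit quaternions.

    Convention: scalar-first, Hamilton product, world z-axis up;
    ``v_world = R(q) @ v_sensor``.
    """

    quats: np.ndarray  # (n, 4)
    convention: str = "scalar-first Hamilton, sensor-to-world, z-up"

    def __post_init__(self) -> None:
        self.quats = np.asarray(self.quats, dtype=float)
        if self.quats.ndim != 2 or self.quats.shape[1] != 4:
            raise ValueError("quats must be (n, 4)")
        norms = np.linalg.norm(self.quats, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("quaternions must be unit norm within 1e-6")

    def __len__(self) -> int:
        return self.quats.shape[0]


def _tilt_alignment(accel0: np.ndarray) -> tuple:
    """Initial quaternion aligning the measured gravity direction with the
    world vertical (heading left at zero)."""
    a = np.asarray(accel0, dtype=float)
    na = np.linalg.norm(a)
    if na < 1e-9:
        return (1.0, 0.0, 0.0, 0.0)
    v = a / na  # gravity direction in sensor frame
    z = np.array([0.0, 0.0, 1.0])
    # rotation taking v to z: R(q0) @ v = z, so R^T z = v as required
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, z))
    if s < 1e-12:
        if c > 0:
            return (1.0, 0.0, 0.0, 0.0)
        return (0.0, 1.0, 0.0, 0.0)  # upside down: 180 deg about x
    angle = math.atan2(s, c)
    axis = axis / s * angle
    return quat_from_rotvec(axis[0], axis[1], axis[2])


def estimate_orientation(
    recording: IMURecording,
    correction_gain: float = 0.02,
    g: float = GRAVITY,
) -> OrientationTrajectory:
    """Complementary quaternion filter over one recording.

    Each step integrates the gyroscope; whenever the specific-force norm
    is within 0.5 g of g, the tilt estimate is nudged toward the
    accelerometer-derived gravity direction by the fraction
    ``correction_gain`` of the residual angle.  ``correction_gain`` of 0
    gives pure strap-down integration.
    """
    if not 0.0 <= correction_gain <= 1.0:
        raise ValueError("correction_gain must lie in [0, 1]")
    n = recording.n_samples
    dt = 1.0 / recording.sampling_hz
    accel = recording.accel
    gyro = recording.gyro
    lo = g * (1.0 - _DYNAMIC_GUARD_FRACTION)
    hi = g * (1.0 + _DYNAMIC_GUARD_FRACTION)

    out = np.empty((n, 4))
    q = _tilt_alignment(accel[0])
    for k in range(n):
        ax, ay, az = accel[k]
        na = math.sqrt(ax * ax + ay * ay + az * az)
        if correction_gain > 0.0 and lo <= na <= hi:
            vmx, vmy, vmz = ax / na, ay / na, az / na  # measured gravity dir
            vpx, vpy, vpz = rotate_vector_inverse(q, (0.0, 0.0, 1.0))  # predicted
            # axis of the rotation taking measured to predicted; applying a
            # right-multiplied fraction of it moves the prediction toward
            # the measurement
            ux = vmy * vpz - vmz * vpy
            uy = vmz * vpx - vmx * vpz
            uz = vmx * vpy - vmy * vpx
            s = math.sqrt(ux * ux + uy * uy + uz * uz)
            if s > 1e-12:
                c = vmx * vpx + vmy * vpy + vmz * vpz
                angle = math.atan2(s, c) * correction_gain / s
                q = quat_normalize(
                    quat_multiply(q, quat_from_rotvec(ux * angle, uy * angle, uz * angle))
                )
        out[k] = q
        wx, wy, wz = gyro[k]
        q = quat_normalize(
            quat_multiply(q, quat_from_rotvec(wx * dt, wy * dt, wz * dt))
        )
    return OrientationTrajectory(quats=out)


def remove_gravity(
    recording: IMURecording,
    orientation: OrientationTrajectory,
    g: float = GRAVITY,
) -> np.ndarray:
    """Rotate specific force into the world frame and subtract gravity.

    Returns the (n, 3) world-frame linear ("pure movement") acceleration.
    """
    if len(orientation) != recording.n_samples:
        raise ValueError("orientation and recording must be sample-aligned")
    R = quats_to_matrices(orientation.quats)  # sensor -> world
    world = np.einsum("nij,nj->ni", R, recording.accel)
    world[:, 2] -= g
    return world


def _find_still_window(linear_accel: np.ndarray, fs: float) -> tuple[int, int]:
    """First window of 10 s whose acceleration-norm variance is below the
    stillness threshold; falls back to the overall lowest-variance window."""
    n = linear_accel.shape[0]
    w = int(round(_SUBSTITUTE_S * fs))
    if n < w:
        raise ValueError("recording shorter than the 10 s substitution window")
    norm = np.linalg.norm(linear_accel, axis=1)
    step = max(1, int(round(0.5 * fs)))
    starts = np.arange(0, n - w + 1, step)
    c1 = np.concatenate([[0.0], np.cumsum(norm)])
    c2 = np.concatenate([[0.0], np.cumsum(norm**2)])
    mean = (c1[starts + w] - c1[starts]) / w
    var = (c2[starts + w] - c2[starts]) / w - mean**2
    below = np.nonzero(var < _STILL_VARIANCE)[0]
    if below.size:
        i0 = int(starts[below[0]])
    else:
        i0 = int(starts[int(np.argmin(var))])
        logger.warning(
            "no non-moving 10 s window below variance %.3g; using lowest-variance "
            "window (var=%.3g)",
            _STILL_VARIANCE,
            float(var.min()),
        )
    return i0, i0 + w


def segment_tasks(
    recording: IMURecording,
    linear_accel: np.ndarray,
    annotations: pd.DataFrame,
) -> list[TaskSegment]:
    """Cut one processed recording into per-task segments.

    ``annotations`` rows are matched to the recording by (subject,
    session, arm) when the recording carries that metadata; otherwise all
    rows are used.  Attempted tasks are sliced at [t_start, t_stop) and
    truncated to the first 60 s; unattempted tasks get a 10 s non-moving
    window with score 0 and the ``substituted`` flag set.
    """
    linear_accel = np.asarray(linear_accel, dtype=float)
    if linear_accel.shape != recording.accel.shape:
        raise ValueError("linear_accel must be sample-aligned with the recording")
    fs = recording.sampling_hz
    rows = annotations
    if recording.subject:
        mask = (
            (annotations["subject"] == recording.subject)
            & (annotations["session"] == recording.session)
            & (annotations["arm"] == recording.arm)
        )
        rows = annotations[mask]

    t_end = float(recording.timestamps[-1]) + 1.0 / fs
    max_samples = int(round(_MAX_SEGMENT_S * fs))
    segments: list[TaskSegment] = []
    still: tuple[int, int] | None = None
    for row in rows.itertuples(index=False):
        attempted = bool(row.attempted)
        if attempted:
            t0, t1 = float(row.t_start), float(row.t_stop)
            if t1 <= t0:
                raise ValueError(
                    f"task {row.task}: t_stop ({t1}) must exceed t_start ({t0})"
                )
            if t0 < 0 or t1 > t_end + 1e-6:
                raise ValueError(
                    f"task {row.task}: annotation [{t0}, {t1}] outside recording span"
                )
            i0 = int(round(t0 * fs))
            i1 = min(int(round(t1 * fs)), i0 + max_samples)
            score = int(row.score)
            substituted = False
        else:
            if still is None:
                still = _find_still_window(linear_accel, fs)
            i0, i1 = still
            score = 0
            substituted = True
        segments.append(
            TaskSegment(
                linear_accel=linear_accel[i0:i1],
                gyro=recording.gyro[i0:i1],
                subject=str(row.subject),
                session=int(row.session),
                arm=str(row.arm),
                domain=str(row.domain),
                task=int(row.task),
                score=score,
                substituted=substituted,
                sampling_hz=fs,
            )
        )
    return segments


def preprocess_recording(
    recording: IMURecording,
    annotations: pd.DataFrame,
    correction_gain: float = 0.02,
    g: float = GRAVITY,
) -> list[TaskSegment]:
    """Orientation -> gravity removal -> segmentation for one recording."""
    orientation = estimate_orientation(recording, correction_gain=correction_gain, g=g)
    linear = remove_gravity(recording, orientation, g=g)
    return segment_tasks(recording, linear, annotations)
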