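"""Minimal quaternion helpers (scalar-first, Hamilton convention, z-up world).

Quaternions here represent sensor-to-world rotations: ``v_world = R(q) @
v_sensor``.  Batch conversions go through scipy; the per-sample strap-down
integration is kept as an explicit scalar loop because each step depends on
the previous estimate.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

IDENTITY = (1.0, 0.0, 0.0, 0.0)


def quat_multiply(q: tuple, r: tuple) -> tuple:
    """Hamilton product q ⊗ r, scalar-first tuples."""
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return (
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    )


def quat_from_rotvec(rx: float, ry: float, rz: float) -> tuple:
    """Quaternion of the rotation vector (axis * angle)."""
    angle = math.sqrt(rx * rx + ry * ry + rz * rz)
    if angle < 1e-12:
        # first-order expansion is exact to double precision here
        return (1.0, 0.5 * rx, 0.5 * ry, 0.5 * rz)
    s = math.sin(0.5 * angle) / angle
    return (math.cos(0.5 * angle), rx * s, ry * s, rz * s)


def quat_normalize(q: tuple) -> tuple:
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def rotate_vector(q: tuple, v: tuple) -> tuple:
    """Rotate v by q (sensor -> world for our convention)."""
    w, x, y, z = q
    vx, vy, vz = v
    # t = 2 * (q_vec x v)
    tx = 2.0 * (y * vz - z * vy)
    ty = 2.0 * (z * vx - x * vz)
    tz = 2.0 * (x * vy - y * vx)
    return (
        vx + w * tx + (y * tz - z * ty),
        vy + w * ty + (z * tx - x * tz),
        vz + w * tz + (x * ty - y * tx),
    )


def rotate_vector_inverse(q: tuple, v: tuple) -> tuple:
    """Rotate v by q^{-1} (world -> sensor)."""
    w, x, y, z = q
    return rotate_vector((w, -x, -y, -z), v)


def integrate_gyro(gyro: np.ndarray, dt: float, q0: tuple = IDENTITY) -> np.ndarray:
    """Strap-down integration of sensor-frame angular velocity.

    Returns an (n, 4) scalar-first quaternion array; sample k holds the
    orientation at time k*dt, with ``gyro[k]`` treated as the rate over
    the step [k, k+1).
    """
    gyro = np.asarray(gyro, dtype=float)
    n = gyro.shape[0]
    out = np.empty((n, 4))
    q = quat_normalize(q0)
    for k in range(n):
        out[k] = q
        wx, wy, wz = gyro[k]
        dq = quat_from_rotvec(wx * dt, wy * dt, wz * dt)
        q = quat_normalize(quat_multiply(q, dq))
    return out


def quats_to_matrices(quats: np.ndarray) -> np.ndarray:
    """(n, 4) scalar-first quaternions -> (n, 3, 3) rotation matrices."""
    q = np.asarray(quats, dtype=float)
    return Rotation.from_quat(q[:, [1, 2, 3, 0]]).as_matrix()
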