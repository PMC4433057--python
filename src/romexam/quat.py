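"""Hamilton quaternion helpers.

Conventions used throughout the package (fixed once, here):

* scalar-first storage ``[w, x, y, z]`` in numpy arrays of shape ``(..., 4)``;
* Hamilton product (right-handed, ``i*j = k``);
* quaternions are *passive* sensor-to-world maps: ``v_world = q * v_body * q⁻¹``;
* the world frame is right-handed with Z up (gravity along -Z), X anterior,
  Y to the subject's left.

All functions broadcast over leading axes.  Angles are radians unless a
function name says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "mul",
    "conj",
    "normalize",
    "rotate",
    "from_rotvec",
    "to_rotvec",
    "from_axis_angle",
    "to_matrix",
    "from_matrix",
    "geodesic",
    "ensure_continuity",
    "from_two_vectors",
]


def identity(shape: tuple = ()) -> np.ndarray:
    q = np.zeros(shape + (4,))
    q[..., 0] = 1.0
    return q


def mul(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    qw, qx, qy, qz = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize a zero quaternion")
    return q / n


def rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) v from the body frame to the world frame."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # v' = v + 2 w (u × v) + 2 u × (u × v)
    uv = np.cross(u, v)
    return v + 2.0 * w * uv + 2.0 * np.cross(u, uv)


def from_rotvec(v: np.ndarray) -> np.ndarray:
    """Quaternion exponential of a rotation vector (axis * angle, rad)."""
    v = np.asarray(v, dtype=float)
    angle = np.linalg.norm(v, axis=-1, keepdims=True)
    half = 0.5 * angle
    small = angle[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(angle > 0, np.sin(half) / np.where(angle > 0, angle, 1.0), 0.5)
    q = np.concatenate([np.cos(half), k * v], axis=-1)
    if np.any(small):
        # second-order series keeps tiny steps exact to machine precision
        qs = np.concatenate([1.0 - half**2 / 2.0, 0.5 * v], axis=-1)
        q = np.where(small[..., None], qs, q)
    return q


def to_rotvec(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    q = np.where(q[..., :1] < 0, -q, q)  # shortest representation
    u = q[..., 1:]
    sin_half = np.linalg.norm(u, axis=-1, keepdims=True)
    w = np.clip(q[..., :1], -1.0, 1.0)
    angle = 2.0 * np.arctan2(sin_half, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(sin_half > 1e-12, angle / np.where(sin_half > 0, sin_half, 1.0), 2.0)
    return scale * u


def from_axis_angle(axis: np.ndarray, angle: float | np.ndarray) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis, axis=-1, keepdims=True)
    angle = np.asarray(angle, dtype=float)[..., None]
    return np.concatenate(
        [np.cos(angle / 2.0), np.sin(angle / 2.0) * axis], axis=-1
    )


def to_matrix(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def from_matrix(m: np.ndarray) -> np.ndarray:
    """Rotation matrix to unit quaternion (Shepperd's method, single matrix)."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("from_matrix expects a single 3x3 matrix")
    tr = np.trace(m)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2.0
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(m)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(m[i, i] - m[j, j] - m[k, k] + 1.0) * 2.0
        q = np.empty(4)
        q[0] = (m[k, j] - m[j, k]) / s
        q[i + 1] = 0.25 * s
        q[j + 1] = (m[j, i] + m[i, j]) / s
        q[k + 1] = (m[k, i] + m[i, k]) / s
    return normalize(q)


def geodesic(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Geodesic angle (rad) between two rotations."""
    d = np.abs(np.sum(np.asarray(p) * np.asarray(q), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


def ensure_continuity(q: np.ndarray) -> np.ndarray:
    """Flip signs along axis 0 so consecutive quaternions stay in the same
    hemisphere (antipodal representations name the same rotation)."""
    q = np.array(q, dtype=float)
    for k in range(1, q.shape[0]):
        if np.dot(q[k], q[k - 1]) < 0:
            q[k] = -q[k]
    return q


def from_two_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest-arc rotation taking direction a to direction b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = np.cross(a, b)
    d = float(np.dot(a, b))
    if d < -1.0 + 1e-12:
        # antiparallel: pick any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return from_axis_angle(axis, np.pi)
    q = np.concatenate([[1.0 + d], c])
    return normalize(q)
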