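"""Magnetometer-free orientation estimation.

The examination system computes segment orientation continuously from angular
rate and acceleration only: strapdown integration of the gyroscope propagates
the attitude, and whenever the accelerometer reads close to pure gravity a
complementary-filter step pulls the tilt back toward the measured gravity
direction.  Heading (rotation about gravity) is not observable without a
magnetometer; it is fixed at initialization from the *expected* segment
orientation at the neutral start posture and then drifts freely with the gyro
— acceptable because a single examination repetition lasts only seconds and
the system re-initializes at every repetition start.

Quaternions are Hamilton, scalar-first, passive sensor→world (see
:mod:`romexam.quat`).  The world frame has Z up; a resting accelerometer
outputs the gravitational reaction +9.81 m/s² along its world-up axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import quat

__all__ = [
    "GRAVITY",
    "FilterConfig",
    "OrientationTrace",
    "CalibrationError",
    "init_orientation",
    "estimate_orientation",
    "quat_relative",
]

GRAVITY = 9.81  # m/s^2, world +Z reaction at rest


class CalibrationError(RuntimeError):
    """The static window required for initialization was not static/level."""


@dataclass(frozen=True)
class FilterConfig:
    """Tuning of the complementary attitude filter.

    correction_gain : per-sample blend weight toward the accelerometer tilt
        (0 disables correction; default 0.02 per sample at 100 Hz).
    accel_gate : max deviation of ``|accel|`` from gravity (m/s²) for a sample
        to be trusted as a gravity measurement.
    init_window : length (s) of the quasi-static averaging window used for
        initialization and neutral-posture calibration.
    """

    correction_gain: float = 0.02
    accel_gate: float = 0.5
    init_window: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.correction_gain <= 1.0:
            raise ValueError("correction_gain must be in [0, 1]")
        if self.accel_gate <= 0:
            raise ValueError("accel_gate must be positive")


@dataclass
class OrientationTrace:
    """Unit-quaternion trajectory, sensor frame → world frame."""

    t: np.ndarray  # (N,) seconds
    q: np.ndarray  # (N, 4) scalar-first unit quaternions

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.t.shape[0], 4):
            raise ValueError("t and q lengths disagree")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.t)))

    def geodesic_to(self, other: "OrientationTrace") -> np.ndarray:
        """Per-sample geodesic angle (degrees) to another trace."""
        return np.degrees(quat.geodesic(self.q, other.q))


def _mean_accel(stream, window: float) -> np.ndarray:
    n = max(1, int(round(window * stream.sampling_rate)))
    return np.asarray(stream.accel[:n], dtype=float).mean(axis=0)


def _expected_quaternion(expected: np.ndarray, heading_axis=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Normalize the 'expected orientation' argument.

    A quaternion (4,) is used as-is.  A world heading vector (3,) is
    interpreted as: the sensor axis ``heading_axis`` points along the
    horizontal projection of that vector while the sensor sits level
    (sensor z up); tilt is subsequently corrected from gravity.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.shape == (4,):
        return quat.normalize(expected)
    if expected.shape != (3,):
        raise ValueError("expected orientation must be a quaternion (4,) or heading vector (3,)")
    h = expected.copy()
    h[2] = 0.0
    nh = np.linalg.norm(h)
    if nh < 1e-9:
        raise ValueError("expected heading vector must have a horizontal component")
    x = h / nh
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    r_axes = np.column_stack([x, y, z])  # maps heading-frame to world
    q_axes = quat.from_matrix(r_axes)
    # rotate so that heading_axis (not necessarily sensor x) lands on x
    ha = np.asarray(heading_axis, dtype=float)
    q_align = quat.from_two_vectors(ha, [1.0, 0.0, 0.0])
    return quat.normalize(quat.mul(q_axes, q_align))


def init_orientation(stream, expected, cfg: FilterConfig | None = None) -> np.ndarray:
    """Initial orientation from the static neutral-posture window.

    Inclination comes from the averaged accelerometer (gravity) over the
    first ``cfg.init_window`` seconds; the unobservable yaw is taken from
    ``expected`` — the expected sensor orientation at the neutral posture
    (quaternion), or a world heading vector for the sensor x-axis.

    Returns the quaternion q0 with ``rotate(q0, mean_accel) ∥ world +Z`` whose
    heading matches the expectation.  Raises :class:`CalibrationError` when
    the window is not quasi-static (``| |ā| - g | >`` ``accel_gate``).
    """
    cfg = cfg or FilterConfig()
    q_exp = _expected_quaternion(expected)
    a = _mean_accel(stream, cfg.init_window)
    a_norm = float(np.linalg.norm(a))
    if abs(a_norm - GRAVITY) > cfg.accel_gate:
        raise CalibrationError(
            f"initialization window is not static: |mean accel| = {a_norm:.2f} m/s² "
            f"deviates more than {cfg.accel_gate} m/s² from {GRAVITY}; "
            "repeat the neutral start posture"
        )
    up_pred = quat.rotate(q_exp, a / a_norm)  # where expectation puts gravity
    tilt_fix = quat.from_two_vectors(up_pred, [0.0, 0.0, 1.0])
    return quat.normalize(quat.mul(tilt_fix, q_exp))


def quat_relative(qa: np.ndarray, qb: np.ndarray) -> np.ndarray:
    """Relative orientation qa⁻¹ ⊗ qb (frame-a-relative orientation of b)."""
    return quat.mul(quat.conj(qa), qb)


def estimate_orientation(stream, q0: np.ndarray, cfg: FilterConfig | None = None) -> OrientationTrace:
    """Propagate orientation through a uniformly sampled IMU stream.

    Per sample the quaternion advances by the exponential of ω·dt (exact for
    a constant rate over the step); gated accelerometer samples then rotate
    the estimate toward gravity-consistency by ``correction_gain`` of the
    remaining tilt error.  The correction axis is horizontal by construction,
    so heading is never touched.
    """
    cfg = cfg or FilterConfig()
    t = np.asarray(stream.t, dtype=float)
    if len(t) > 1:
        dts = np.diff(t)
        if np.any(np.abs(dts - dts[0]) > 1e-9):
            raise ValueError("estimate_orientation requires uniform sampling")
    omega = np.asarray(stream.omega, dtype=float)
    accel = np.asarray(stream.accel, dtype=float)
    bad = ~np.isfinite(omega).all(axis=1) | ~np.isfinite(accel).all(axis=1)
    if bad.any():
        raise ValueError(f"NaN/inf in IMU stream at sample index {int(np.argmax(bad))}")

    dt = 1.0 / stream.sampling_rate
    gain = cfg.correction_gain
    gate = cfg.accel_gate
    n = len(t)
    out = np.empty((n, 4))
    qw, qx, qy, qz = (float(v) for v in quat.normalize(np.asarray(q0, dtype=float)))
    out[0] = (qw, qx, qy, qz)
    # plain-float inner loop: called per sample, so numpy overhead matters
    om = omega
    ac = accel
    sqrt, sin, cos, atan2 = math.sqrt, math.sin, math.cos, math.atan2
    for k in range(1, n):
        wx = om[k - 1, 0] * dt
        wy = om[k - 1, 1] * dt
        wz = om[k - 1, 2] * dt
        ang = sqrt(wx * wx + wy * wy + wz * wz)
        if ang > 1e-12:
            h = 0.5 * ang
            s = sin(h) / ang
            dw, dx, dy, dz = cos(h), s * wx, s * wy, s * wz
        else:
            dw, dx, dy, dz = 1.0, 0.5 * wx, 0.5 * wy, 0.5 * wz
        # q ⊗ dq (body-frame increment)
        nw = qw * dw - qx * dx - qy * dy - qz * dz
        nx = qw * dx + qx * dw + qy * dz - qz * dy
        ny = qw * dy - qx * dz + qy * dw + qz * dx
        nz = qw * dz + qx * dy - qy * dx + qz * dw
        qw, qx, qy, qz = nw, nx, ny, nz
        if gain > 0.0:
            ax = ac[k, 0]
            ay = ac[k, 1]
            az = ac[k, 2]
            an = sqrt(ax * ax + ay * ay + az * az)
            if an > 0.0 and abs(an - GRAVITY) <= gate:
                ax /= an
                ay /= an
                az /= an
                # u = R(q) a : measured up direction in world coordinates
                tx = 2.0 * (qy * az - qz * ay)
                ty = 2.0 * (qz * ax - qx * az)
                tz = 2.0 * (qx * ay - qy * ax)
                ux = ax + qw * tx + qy * tz - qz * ty
                uy = ay + qw * ty + qz * tx - qx * tz
                uz = az + qw * tz + qx * ty - qy * tx
                # tilt error: rotation about horizontal axis u × z
                ex = uy
                ey = -ux
                en = sqrt(ex * ex + ey * ey)
                if en > 1e-12:
                    err = atan2(en, uz)
                    half = 0.5 * gain * err
                    s = sin(half) / en
                    cw, cx, cy = cos(half), s * ex, s * ey
                    # world-frame correction: q ← c ⊗ q (cz = 0)
                    nw = cw * qw - cx * qx - cy * qy
                    nx = cw * qx + cx * qw + cy * qz
                    ny = cw * qy - cx * qz + cy * qw
                    nz = cw * qz + cx * qy - cy * qx
                    qw, qx, qy, qz = nw, nx, ny, nz
        inv = 1.0 / sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
        qw *= inv
        qx *= inv
        qy *= inv
        qz *= inv
        out[k, 0] = qw
        out[k, 1] = qx
        out[k, 2] = qy
        out[k, 3] = qz
    return OrientationTrace(t=t, q=quat.ensure_continuity(out))
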