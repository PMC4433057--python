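"""Sensor-to-segment calibration, Grood–Suntay joint angles, RoM extraction.

Calibration is the simplified neutral-posture procedure of the examination
system: at the start of every repetition the subject holds the defined
neutral-zero posture for a moment; the sensor's inclination is measured from
gravity while its heading is taken from the *expected* orientation implied by
the placement protocol (no magnetometer).  The sensor→segment rotation then
follows from the catalog's neutral segment frame.  A heading (yaw) error of
the mounting that the placement protocol does not declare is unobservable and
propagates into the joint angles — the system cannot detect a subject who
fails to reach the neutral-zero start either; both limitations are inherited
deliberately and surface only as a ``residual_tilt`` quality metric.

Joint angles follow the Grood–Suntay joint coordinate system: a body-fixed
flexion axis e1 on the proximal segment (segment x, mediolateral), a
body-fixed long axis e3 on the distal segment (segment y), and a floating
mutual perpendicular e2.  This equals an intrinsic X–Z–Y Euler decomposition
of the relative rotation: flexion about e1, abduction about e2 (the deviation
of the e1–e3 angle from 90°), axial rotation about e3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import quat
from .catalog import Catalog, ExaminationAngle, SensorSite
from .fusion import (
    CalibrationError,
    FilterConfig,
    OrientationTrace,
    estimate_orientation,
    init_orientation,
    quat_relative,
)

__all__ = [
    "CalibrationResult",
    "JointAngleTrace",
    "RoMResult",
    "calibrate_neutral",
    "grood_suntay_decompose",
    "jcs_compose",
    "joint_angle_trace",
    "extract_rom",
    "process_recording",
    "process_study",
    "GIMBAL_ABDUCTION_DEG",
]

GIMBAL_ABDUCTION_DEG = 80.0
_STATIC_GYRO_LIMIT = 0.35  # rad/s RMS allowed in the calibration window


@dataclass
class CalibrationResult:
    """Sensor→segment rotation estimated at the neutral start posture."""

    site_id: str
    q_sensor_to_segment: np.ndarray  # maps sensor-frame vectors to segment frame
    q0_world: np.ndarray  # estimated sensor→world at calibration time
    residual_tilt: float  # ° mismatch between expected posture and gravity
    timestamp_window: float  # s of static data used


@dataclass
class JointAngleTrace:
    """Signed JCS angle components over one repetition."""

    angle_id: str
    t: np.ndarray
    flexion: np.ndarray  # °
    abduction: np.ndarray  # °
    rotation: np.ndarray  # °
    gimbal_proximity: bool = False

    def component(self, jcs_axis: str) -> np.ndarray:
        return getattr(self, jcs_axis)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RoMResult:
    """Min/max of one repetition, mapped to the anatomical nomenclature."""

    angle_id: str
    repetition: int
    min_deg: float
    max_deg: float
    reported_rom_deg: float


def calibrate_neutral(
    stream,
    site: SensorSite,
    cfg: FilterConfig | None = None,
    mount: np.ndarray | None = None,
) -> CalibrationResult:
    """Estimate the sensor→segment rotation from the static neutral window.

    ``mount`` is the *declared* sensor→segment rotation of the placement
    protocol (identity by default: sensor axes nominally aligned with the
    segment's anatomical axes).  The declared mounting supplies the
    unobservable heading; the measured gravity corrects its tilt.
    ``residual_tilt`` reports how far the measured gravity direction is from
    the one the declared posture predicts — large values flag a sensor
    mounted other than declared or a subject off the neutral posture.
    """
    cfg = cfg or FilterConfig()
    n = max(1, int(round(cfg.init_window * stream.sampling_rate)))
    gyro = np.asarray(stream.omega[:n], dtype=float)
    if np.sqrt(np.mean(np.sum(gyro**2, axis=1))) > _STATIC_GYRO_LIMIT:
        raise CalibrationError(
            f"motion detected during the calibration window of site {site.site_id}; "
            "repeat the neutral start posture"
        )
    q_mount = quat.identity() if mount is None else quat.normalize(np.asarray(mount, dtype=float))
    q_seg_world = quat.from_matrix(site.neutral_rotation)
    q_expected = quat.mul(q_seg_world, q_mount)  # expected sensor→world at neutral
    q0 = init_orientation(stream, q_expected, cfg)

    a = np.asarray(stream.accel[:n], dtype=float).mean(axis=0)
    a = a / np.linalg.norm(a)
    up_expected = quat.rotate(q_expected, a)
    residual = float(
        np.degrees(np.arccos(np.clip(up_expected[2], -1.0, 1.0)))
    )
    q_s2seg = quat.mul(quat.conj(q_seg_world), q0)
    return CalibrationResult(
        site_id=site.site_id,
        q_sensor_to_segment=quat.normalize(q_s2seg),
        q0_world=q0,
        residual_tilt=residual,
        timestamp_window=n / stream.sampling_rate,
    )


def grood_suntay_decompose(q_rel: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """JCS angles (°) of relative rotation(s) distal-segment → proximal-segment.

    Floating-axis construction: e1 = proximal x (flexion axis), e3 = distal y
    (long axis) expressed in the proximal frame, e2 = their mutual
    perpendicular.  flexion = rotation about e1, abduction = angle(e1, e3) −
    90°, rotation = rotation about e3.  Near the gimbal singularity
    (|abduction| > 80°) angles are still returned but flagged.
    """
    q_rel = np.asarray(q_rel, dtype=float)
    m = quat.to_matrix(q_rel)
    # e3 (distal long axis) in the proximal frame is the middle matrix column
    e3_x = m[..., 0, 1]
    e3_y = m[..., 1, 1]
    e3_z = m[..., 2, 1]
    flexion = np.degrees(np.arctan2(e3_z, e3_y))
    abduction = np.degrees(np.arcsin(np.clip(-e3_x, -1.0, 1.0)))
    rotation = np.degrees(np.arctan2(m[..., 0, 2], m[..., 0, 0]))
    gimbal = bool(np.any(np.abs(abduction) > GIMBAL_ABDUCTION_DEG))
    return flexion, abduction, rotation, gimbal


def jcs_compose(flexion_deg: float, abduction_deg: float, rotation_deg: float) -> np.ndarray:
    """Forward composition in JCS order (flexion, then floating-axis
    abduction, then axial rotation); inverse of the decomposition."""
    qf = quat.from_axis_angle([1.0, 0.0, 0.0], np.radians(flexion_deg))
    qa = quat.from_axis_angle([0.0, 0.0, 1.0], np.radians(abduction_deg))
    qr = quat.from_axis_angle([0.0, 1.0, 0.0], np.radians(rotation_deg))
    return quat.mul(quat.mul(qf, qa), qr)


def joint_angle_trace(
    exam: ExaminationAngle,
    traces: dict[str, OrientationTrace],
    cal: dict[str, CalibrationResult],
) -> JointAngleTrace:
    """JCS angle components of one examination repetition.

    Two-IMU mode decomposes the proximal-segment-relative orientation of the
    distal segment; single-IMU mode decomposes the distal sensor's rotation
    away from its own starting (neutral) orientation, expressed in the
    neutral segment frame.
    """
    for site in exam.sites:
        if site not in traces:
            raise KeyError(f"examination {exam.angle_id} requires a trace for site {site!r}")
        if site not in cal:
            raise KeyError(f"examination {exam.angle_id} requires calibration for site {site!r}")

    def segment_world(site: str) -> np.ndarray:
        c = cal[site]
        return quat.mul(traces[site].q, quat.conj(c.q_sensor_to_segment))

    q_dist = segment_world(exam.distal_site)
    if exam.method == "two_imu_relative":
        q_prox = segment_world(exam.proximal_site)
        q_rel = quat_relative(q_prox, q_dist)
    else:
        q_rel = quat_relative(q_dist[0], q_dist)
    q_rel = quat.ensure_continuity(q_rel)
    flexion, abduction, rotation, gimbal = grood_suntay_decompose(q_rel)
    t = traces[exam.distal_site].t
    return JointAngleTrace(
        angle_id=exam.angle_id,
        t=t,
        flexion=flexion,
        abduction=abduction,
        rotation=rotation,
        gimbal_proximity=gimbal,
    )


def extract_rom(trace: JointAngleTrace, exam: ExaminationAngle, repetition: int = 0) -> RoMResult:
    """Min/max of the examination's JCS component; the reported RoM is the
    unsigned extreme in the direction the nomenclature names (sign +1 → the
    maximum, sign −1 → the negated minimum), so one recording can serve both
    of a paired left/right nomenclature."""
    if len(trace) == 0:
        raise ValueError("cannot extract RoM from an empty trace")
    comp = trace.component(exam.jcs_axis)
    lo = float(np.min(comp))
    hi = float(np.max(comp))
    reported = hi if exam.sign > 0 else -lo
    return RoMResult(
        angle_id=exam.angle_id,
        repetition=repetition,
        min_deg=lo,
        max_deg=hi,
        reported_rom_deg=reported,
    )


def process_recording(
    recording,
    catalog: Catalog,
    cfg: FilterConfig | None = None,
) -> RoMResult:
    """Full measurement chain for one recording: per-site neutral calibration
    and orientation estimation, then JCS decomposition and RoM extraction."""
    cfg = cfg or FilterConfig()
    exam = catalog.lookup(recording.angle_id)
    mounts = recording.mounts or {}
    traces: dict[str, OrientationTrace] = {}
    cals: dict[str, CalibrationResult] = {}
    for site_id in exam.sites:
        if site_id not in recording.streams:
            raise KeyError(
                f"recording {recording.angle_id} rep {recording.rep} is missing "
                f"the stream for site {site_id!r}"
            )
        stream = recording.streams[site_id]
        site = catalog.site(site_id)
        cals[site_id] = calibrate_neutral(stream, site, cfg, mount=mounts.get(site_id))
        traces[site_id] = estimate_orientation(stream, cals[site_id].q0_world, cfg)
    jtrace = joint_angle_trace(exam, traces, cals)
    return extract_rom(jtrace, exam, repetition=recording.rep)


def process_study(recordings, catalog: Catalog, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Process an iterable of recordings into the machine results sheet
    (one row per repetition)."""
    rows = []
    for rec in recordings:
        rom = process_recording(rec, catalog, cfg)
        rows.append(
            (rec.subject, rec.rater, rec.angle_id, rec.rep, rom.reported_rom_deg, rom.min_deg, rom.max_deg)
        )
    return pd.DataFrame(
        rows,
        columns=["subject", "rater", "angle_id", "rep", "measured_rom_deg", "min_deg", "max_deg"],
    )
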