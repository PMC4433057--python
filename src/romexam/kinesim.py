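"""Synthetic examination simulator.

Generates ground-truth segment kinematics, raw IMU streams and examiner
rating sheets with the statistical structure an inter-rater RoM study
assumes, so that the whole measurement and analysis chain can be exercised
without hardware or subjects.

Hierarchy of random effects (all seeded, all in degrees):

* between subjects: true RoM ``θ_sa ~ N(true_rom_mean_a, true_rom_sd_a²)``;
* between sessions: each rater examines in a separate session; the executed
  motion shifts by ``N(0, session_sd²)`` per (subject, rater, angle) — this
  term is seen by *both* the sensors and the examiner;
* between repetitions: execution noise ``N(0, rep_sd²)`` per repetition;
* examiner perception: a per-(subject, rater, angle) error
  ``N(0, rater_sd_r²)`` plus the rater's constant bias; examiners anchor on
  their first impression, so ratings track only a fraction
  (``rater_anchor``) of the per-repetition execution variation and are
  rounded to the customary 5° grid;
* sensors: gyro white noise and a per-(rater, site) constant bias, accel
  white noise, a slow sinusoidal soft-tissue rotation of the sensor on the
  skin, and a per-recording deviation of the start posture from neutral-zero.

The world frame is right-handed, Z up (gravity −Z); a resting accelerometer
reads the +Z gravitational reaction.  Translational segment acceleration is
not simulated: the examination movements are quasi-static.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import quat
from .catalog import Catalog, ExaminationAngle
from .fusion import GRAVITY, OrientationTrace

__all__ = [
    "IMUStream",
    "MotionScript",
    "NoiseModel",
    "CohortSpec",
    "SegmentKinematics",
    "Recording",
    "StudyData",
    "simulate_segment_kinematics",
    "synthesize_imu",
    "simulate_study",
    "apply_mounting",
    "round_to_grid",
    "default_true_rom",
]

# segment-frame rotation axes carrying each JCS component
_JCS_AXIS_VEC = {
    "flexion": np.array([1.0, 0.0, 0.0]),  # mediolateral
    "abduction": np.array([0.0, 0.0, 1.0]),  # anterior (sagittal)
    "rotation": np.array([0.0, 1.0, 0.0]),  # segment long axis
}

_SOFT_TISSUE_FREQ = 0.25  # Hz, slow skin-on-bone oscillation


@dataclass
class IMUStream:
    """Angular rate + acceleration time series of one sensor site."""

    site_id: str
    t: np.ndarray  # (N,) s
    omega: np.ndarray  # (N, 3) rad/s, sensor frame
    accel: np.ndarray  # (N, 3) m/s², sensor frame
    sampling_rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = len(self.t)
        if self.omega.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError("stream channels must have equal length and 3 axes")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.sampling_rate) > 1e-9):
                raise ValueError("time stamps must be uniform at 1/sampling_rate")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MotionScript:
    """Commanded joint-angle profile of one examination.

    ``profile`` holds ramp-hold-return waypoints of a single repetition as
    (time s, true joint angle °) pairs; intermediate samples follow a
    smoothstep easing between waypoints (C¹, zero angular velocity at each
    waypoint).  ``rep_peaks`` optionally rescales the profile per repetition
    so each repetition reaches its own commanded peak; the start angle of a
    repetition is ``start_offset_deg`` (0 = exact neutral-zero posture), the
    end-of-motion target is always the absolute anatomical peak, so a start
    offset shifts the *relative* measured angle but not the commanded peak.
    Each repetition is preceded by a ``lead_in`` static window used for
    calibration.
    """

    angle_id: str
    profile: Sequence[tuple[float, float]] = ((0.0, 0.0), (2.0, 120.0), (3.0, 120.0), (5.0, 0.0))
    n_repetitions: int = 5
    rep_peaks: Sequence[float] | None = None
    start_offset_deg: float = 0.0
    inter_rep_pause: float = 1.0
    sampling_rate: float = 100.0
    lead_in: float = 1.0

    def __post_init__(self):
        times = [p[0] for p in self.profile]
        angles = [p[1] for p in self.profile]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("profile times must be strictly increasing")
        if any(abs(a) > 180.0 for a in angles):
            raise ValueError("profile waypoint angles must lie within ±180°")
        if self.rep_peaks is not None and any(abs(p) > 180.0 for p in self.rep_peaks):
            raise ValueError("repetition peaks must lie within ±180°")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.rep_peaks is not None and len(self.rep_peaks) != self.n_repetitions:
            raise ValueError("rep_peaks length must equal n_repetitions")

    @property
    def nominal_peak(self) -> float:
        return max((abs(a) for _, a in self.profile), default=0.0)

    def peaks(self) -> list[float]:
        if self.rep_peaks is not None:
            return [float(p) for p in self.rep_peaks]
        return [self.nominal_peak] * self.n_repetitions

    def sample_repetition(self, rep: int) -> tuple[np.ndarray, np.ndarray]:
        """Time stamps and commanded angle (°) of repetition ``rep``."""
        peak = self.peaks()[rep]
        dur = self.lead_in + self.profile[-1][0]
        n = int(round(dur * self.sampling_rate)) + 1
        t = np.arange(n) / self.sampling_rate
        tau = t - self.lead_in
        base = _eval_profile(self.profile, tau)
        nominal = self.nominal_peak
        off = self.start_offset_deg
        if nominal > 0:
            theta = off + (peak - off) * (base / nominal)
        else:
            theta = np.full_like(base, off)
        return t, theta


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _eval_profile(waypoints, tau: np.ndarray) -> np.ndarray:
    times = np.array([p[0] for p in waypoints], dtype=float)
    angles = np.array([p[1] for p in waypoints], dtype=float)
    out = np.empty_like(tau, dtype=float)
    out[tau <= times[0]] = angles[0]
    out[tau > times[-1]] = angles[-1]
    for (t1, a1), (t2, a2) in zip(waypoints, waypoints[1:]):
        m = (tau > t1) & (tau <= t2)  # right-inclusive: no sample left unset
        if m.any():
            out[m] = a1 + (a2 - a1) * _smoothstep((tau[m] - t1) / (t2 - t1))
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Sensor imperfection model (degrees / degrees-per-second where angular).

    ``gyro_bias`` is either a magnitude (°/s; the bias direction is drawn per
    sensor) or an explicit per-axis 3-vector.  ``soft_tissue_rot_amp`` is the
    amplitude of a slow sinusoidal rotation of the sensor on the skin —
    surface-mounted sensors have been observed to rotate by up to ~8° on the
    shank, clinical handling is gentler.  ``start_posture_offset_sd`` models
    the subject (or examiner) not hitting the neutral-zero start exactly.
    """

    gyro_noise_sd: float = 0.2  # °/s white
    gyro_bias: float | tuple[float, float, float] = 0.3  # °/s
    accel_noise_sd: float = 0.05  # m/s² white
    soft_tissue_rot_amp: float = 2.0  # ° sinusoidal
    start_posture_offset_sd: float = 2.0  # °
    seed: int = 0

    def __post_init__(self):
        for name in ("gyro_noise_sd", "accel_noise_sd", "soft_tissue_rot_amp", "start_posture_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0)

    @property
    def is_zero(self) -> bool:
        b = self.gyro_bias if not np.isscalar(self.gyro_bias) else (self.gyro_bias,)
        return (
            self.gyro_noise_sd == 0
            and self.accel_noise_sd == 0
            and self.soft_tissue_rot_amp == 0
            and self.start_posture_offset_sd == 0
            and all(v == 0 for v in np.atleast_1d(b))
        )


@dataclass(frozen=True)
class CohortSpec:
    """Study design: who is examined, by whom, with what variability.

    Defaults mirror the reference study design: 20 subjects, 3 raters, 5
    repetitions per examination, examiner ratings on a 5° grid.  Per-angle
    true-RoM means/SDs default to the catalog reference ranges via
    :func:`default_true_rom`.
    """

    n_subjects: int = 20
    n_raters: int = 3
    n_repetitions: int = 5
    angle_ids: tuple[str, ...] | None = None
    true_rom_mean: Mapping[str, float] | None = None
    true_rom_sd: Mapping[str, float] | float | None = None
    rep_sd: float = 3.0
    session_sd: float = 2.0
    rater_bias: Sequence[float] = (-6.0, 0.0, 6.0)
    rater_sd: Sequence[float] | float = 8.0
    rater_anchor: float = 0.2
    rating_grid: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.rating_grid < 0:
            raise ValueError("rating_grid must be >= 0")
        for name in ("rep_sd", "session_sd", "rater_anchor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def biases(self) -> np.ndarray:
        b = np.resize(np.asarray(self.rater_bias, dtype=float), self.n_raters)
        return b

    def rater_sds(self) -> np.ndarray:
        return np.resize(np.asarray(self.rater_sd, dtype=float), self.n_raters)


def default_true_rom(catalog: Catalog) -> tuple[dict[str, float], dict[str, float]]:
    """Per-angle true-RoM mean and between-subject SD derived from the
    catalog reference ranges: the mean sits at the midpoint of the normal
    range (or the screening minimum for the near-zero extension angles);
    SDs scale with the magnitude, clipped to a physiological 2–12°."""
    means, sds = {}, {}
    for aid, exam in catalog.examinations.items():
        lo, hi = exam.ref_range_1
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            mid = 0.5 * (exam.ref_range_2[0] + exam.ref_range_2[1])
        means[aid] = float(mid)
        sds[aid] = float(np.clip(0.15 * mid, 2.0, 12.0))
    return means, sds


@dataclass
class SegmentKinematics:
    """Ground-truth segment orientations of one examination recording."""

    angle_id: str
    repetitions: list[dict[str, OrientationTrace]]
    true_roms: list[float]


def simulate_segment_kinematics(
    script: MotionScript, exam: ExaminationAngle, catalog: Catalog
) -> SegmentKinematics:
    """Ground-truth segment world orientations for every involved site.

    The proximal segment (when present) holds its neutral orientation; the
    distal segment rotates about the examination's JCS axis following the
    commanded profile.  The true RoM of a repetition is that repetition's
    commanded peak.
    """
    if script.angle_id != exam.angle_id:
        raise ValueError(
            f"script is for {script.angle_id!r}, examination is {exam.angle_id!r}"
        )
    axis_seg = _JCS_AXIS_VEC[exam.jcs_axis]
    reps = []
    for k in range(script.n_repetitions):
        t, theta = script.sample_repetition(k)
        traces: dict[str, OrientationTrace] = {}
        q0_dist = quat.from_matrix(catalog.site(exam.distal_site).neutral_rotation)
        q_motion = quat.from_axis_angle(axis_seg, np.radians(exam.sign * theta))
        q_dist = quat.mul(q0_dist, q_motion)
        traces[exam.distal_site] = OrientationTrace(t=t, q=quat.ensure_continuity(q_dist))
        if exam.proximal_site is not None:
            q0_prox = quat.from_matrix(catalog.site(exam.proximal_site).neutral_rotation)
            q_prox = np.tile(q0_prox, (len(t), 1))
            traces[exam.proximal_site] = OrientationTrace(t=t, q=q_prox)
        reps.append(traces)
    return SegmentKinematics(angle_id=exam.angle_id, repetitions=reps, true_roms=script.peaks())


def apply_mounting(trace: OrientationTrace, q_mount: np.ndarray) -> OrientationTrace:
    """Attach a sensor to a segment: ``q_mount`` maps sensor-frame vectors to
    the segment frame, so the sensor's world orientation is
    ``q_segment ⊗ q_mount``."""
    return OrientationTrace(t=trace.t, q=quat.mul(trace.q, np.asarray(q_mount, dtype=float)))


def synthesize_imu(
    trace: OrientationTrace,
    noise: NoiseModel,
    site_id: str = "",
    rng: np.random.Generator | None = None,
    gyro_bias_vec: np.ndarray | None = None,
) -> IMUStream:
    """Inverse sensor model: emit the gyro/accel stream a sensor following
    ``trace`` would record.

    The angular rate of sample k is the constant body rate that carries the
    orientation from sample k to k+1 (so re-integrating the stream
    reproduces the trace); the accelerometer reads the world gravitational
    reaction (+Z, 9.81 m/s²) rotated into the sensor frame.  Noise, bias and
    the soft-tissue rotation are added per the noise model, reproducibly for
    a fixed seed.
    """
    t = trace.t
    if len(t) < 2:
        raise ValueError("trace must hold at least two samples")
    dts = np.diff(t)
    dt = dts[0]
    if np.any(np.abs(dts - dt) > 1e-9):
        raise ValueError("synthesize_imu requires a uniformly sampled trace")
    rng = np.random.default_rng(noise.seed) if rng is None else rng

    q = trace.q
    if noise.soft_tissue_rot_amp > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        phase = rng.uniform(0, 2 * np.pi)
        amp = np.radians(noise.soft_tissue_rot_amp)
        wobble = amp * np.sin(2 * np.pi * _SOFT_TISSUE_FREQ * t + phase)
        q = quat.mul(q, quat.from_rotvec(wobble[:, None] * axis[None, :]))

    dq = quat.mul(quat.conj(q[:-1]), q[1:])
    omega = quat.to_rotvec(dq) / dt
    omega = np.vstack([omega, omega[-1]])
    accel = quat.rotate(quat.conj(q), np.array([0.0, 0.0, GRAVITY]))

    if gyro_bias_vec is None:
        gb = noise.gyro_bias
        if np.isscalar(gb):
            if gb:
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                gyro_bias_vec = float(gb) * d
            else:
                gyro_bias_vec = np.zeros(3)
        else:
            gyro_bias_vec = np.asarray(gb, dtype=float)
    omega = omega + np.radians(gyro_bias_vec)[None, :]
    if noise.gyro_noise_sd > 0:
        omega = omega + np.radians(noise.gyro_noise_sd) * rng.standard_normal(omega.shape)
    if noise.accel_noise_sd > 0:
        accel = accel + noise.accel_noise_sd * rng.standard_normal(accel.shape)
    return IMUStream(
        site_id=site_id, t=t, omega=omega, accel=accel, sampling_rate=1.0 / dt
    )


def round_to_grid(x, grid: float):
    """Round to the nearest grid multiple, half away from zero upward
    (73.2° on a 5° grid → 75°); grid 0 means a continuous scale."""
    if grid <= 0:
        return x
    return np.floor(np.asarray(x, dtype=float) / grid + 0.5) * grid


@dataclass
class Recording:
    """IMU streams of one (subject, rater, angle, repetition)."""

    subject: int
    rater: int
    angle_id: str
    rep: int
    streams: dict[str, IMUStream]
    executed_rom_deg: float
    start_offset_deg: float = 0.0
    mounts: dict[str, np.ndarray] | None = None  # declared sensor→segment mounting


@dataclass
class StudyData:
    """Everything a simulated inter-rater study produces.

    Streams are generated lazily (and deterministically) by
    :meth:`iter_recordings`; the examiner sheet and ground truth are
    materialized eagerly.
    """

    cohort: CohortSpec
    catalog: Catalog
    noise: NoiseModel
    angle_ids: tuple[str, ...]
    ground_truth: pd.DataFrame  # subject, angle_id, true_rom_deg
    examiner_sheet: pd.DataFrame  # subject, rater, angle_id, rep, rating_deg
    executed: pd.DataFrame  # subject, rater, angle_id, rep, executed_rom_deg
    scripts: Mapping[str, MotionScript] = field(default_factory=dict)

    @property
    def n_recordings(self) -> int:
        return (
            self.cohort.n_subjects
            * self.cohort.n_raters
            * len(self.angle_ids)
            * self.cohort.n_repetitions
        )

    def _script_for(self, angle_id: str) -> MotionScript:
        if angle_id in self.scripts:
            return self.scripts[angle_id]
        return MotionScript(angle_id=angle_id, n_repetitions=1)

    def iter_recordings(self) -> Iterator[Recording]:
        c = self.cohort
        seed = c.seed
        ex = self.executed.set_index(["subject", "rater", "angle_id", "rep"])[
            "executed_rom_deg"
        ]
        for s in range(c.n_subjects):
            for r in range(c.n_raters):
                for ai, aid in enumerate(self.angle_ids):
                    exam = self.catalog.lookup(aid)
                    base = self._script_for(aid)
                    for k in range(c.n_repetitions):
                        rng = np.random.default_rng(
                            np.random.SeedSequence([seed, 5, s, r, ai, k])
                        )
                        offset = (
                            rng.normal(0.0, self.noise.start_posture_offset_sd)
                            if self.noise.start_posture_offset_sd > 0
                            else 0.0
                        )
                        peak = float(ex.loc[(s, r, aid, k)])
                        script = MotionScript(
                            angle_id=aid,
                            profile=base.profile,
                            n_repetitions=1,
                            rep_peaks=[peak],
                            start_offset_deg=offset,
                            sampling_rate=base.sampling_rate,
                            lead_in=base.lead_in,
                        )
                        kin = simulate_segment_kinematics(script, exam, self.catalog)
                        streams = {}
                        for site, trace in kin.repetitions[0].items():
                            site_idx = list(self.catalog.sites).index(site)
                            bias_rng = np.random.default_rng(
                                np.random.SeedSequence([seed, 6, r, site_idx])
                            )
                            gb = self.noise.gyro_bias
                            if np.isscalar(gb) and gb:
                                d = bias_rng.normal(size=3)
                                d /= np.linalg.norm(d)
                                bias_vec = float(gb) * d
                            elif np.isscalar(gb):
                                bias_vec = np.zeros(3)
                            else:
                                bias_vec = np.asarray(gb, dtype=float)
                            streams[site] = synthesize_imu(
                                trace,
                                self.noise,
                                site_id=site,
                                rng=rng,
                                gyro_bias_vec=bias_vec,
                            )
                        yield Recording(
                            subject=s,
                            rater=r,
                            angle_id=aid,
                            rep=k,
                            streams=streams,
                            executed_rom_deg=peak,
                            start_offset_deg=offset,
                        )


def simulate_study(
    cohort: CohortSpec,
    catalog: Catalog,
    scripts: Mapping[str, MotionScript] | None = None,
    noise: NoiseModel | None = None,
) -> StudyData:
    """Simulate a full inter-rater examination study.

    Draws the per-subject true RoM, per-session and per-repetition execution
    noise, and the examiner ratings (bias + perception error + anchored
    repetition tracking, rounded to the rating grid).  All draws descend from
    ``cohort.seed``; identical specs give byte-identical sheets and streams.
    """
    noise = NoiseModel() if noise is None else noise
    angle_ids = tuple(cohort.angle_ids) if cohort.angle_ids else tuple(catalog.angle_ids)
    for aid in angle_ids:
        catalog.lookup(aid)
    mean_default, sd_default = default_true_rom(catalog)
    means = dict(mean_default)
    if cohort.true_rom_mean:
        means.update(cohort.true_rom_mean)
    if cohort.true_rom_sd is None:
        sds = dict(sd_default)
    elif isinstance(cohort.true_rom_sd, Mapping):
        sds = dict(sd_default)
        sds.update(cohort.true_rom_sd)
    else:
        sds = {aid: float(cohort.true_rom_sd) for aid in angle_ids}

    seed = cohort.seed
    biases = cohort.biases()
    rater_sds = cohort.rater_sds()

    gt_rows, ex_rows, run_rows = [], [], []
    for s in range(cohort.n_subjects):
        for ai, aid in enumerate(angle_ids):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 1, s, ai]))
            theta = means[aid] + (rng.normal(0.0, sds[aid]) if sds[aid] > 0 else 0.0)
            gt_rows.append((s, aid, theta))
            for r in range(cohort.n_raters):
                rng_sr = np.random.default_rng(np.random.SeedSequence([seed, 2, s, r, ai]))
                session = rng_sr.normal(0.0, cohort.session_sd) if cohort.session_sd > 0 else 0.0
                eta = rng_sr.normal(0.0, rater_sds[r]) if rater_sds[r] > 0 else 0.0
                base_rating = theta + session + biases[r] + eta
                for k in range(cohort.n_repetitions):
                    rng_k = np.random.default_rng(
                        np.random.SeedSequence([seed, 3, s, r, ai, k])
                    )
                    rep_noise = rng_k.normal(0.0, cohort.rep_sd) if cohort.rep_sd > 0 else 0.0
                    executed = theta + session + rep_noise
                    rating = round_to_grid(
                        base_rating + cohort.rater_anchor * rep_noise, cohort.rating_grid
                    )
                    run_rows.append((s, r, aid, k, executed))
                    ex_rows.append((s, r, aid, k, float(rating)))

    ground_truth = pd.DataFrame(gt_rows, columns=["subject", "angle_id", "true_rom_deg"])
    examiner_sheet = pd.DataFrame(
        ex_rows, columns=["subject", "rater", "angle_id", "rep", "rating_deg"]
    )
    executed = pd.DataFrame(
        run_rows, columns=["subject", "rater", "angle_id", "rep", "executed_rom_deg"]
    )
    return StudyData(
        cohort=cohort,
        catalog=catalog,
        noise=noise,
        angle_ids=angle_ids,
        ground_truth=ground_truth,
        examiner_sheet=examiner_sheet,
        executed=executed,
        scripts=dict(scripts) if scripts else {},
    )
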