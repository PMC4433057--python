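# Methods

This note documents the models, conventions and design choices behind
`romexam`: what is computed, under which assumptions, and what the synthetic
studies can and cannot show about real examinations.

## Frames and conventions

* World frame: right-handed, Z up, X anterior, Y to the subject's left.
  Gravity acts along −Z; a resting accelerometer outputs the gravitational
  *reaction*, +9.81 m/s² along its world-up axis.
* Quaternions: Hamilton, scalar-first `[w, x, y, z]`, passive sensor→world
  (`v_world = q v_body q⁻¹`). Traces keep a continuous sign (no antipodal
  flips between consecutive samples).
* Anatomical segment frames at the neutral-zero posture: x = flexion axis
  (mediolateral, +left), y = long axis (vertical), z = sagittal (anterior).
  All catalog sites share this neutral frame; differences in physical sensor
  placement are the *mounting* rotation handled by calibration.
* Angles are degrees everywhere outside the quaternion layer.

## Orientation estimation (magnetometer-free)

Attitude is propagated by the quaternion exponential of the gyro increment,
`q_{k+1} = q_k ⊗ exp(½ ω_k Δt)` — exact for a constant rate over one step,
which is why the constant-rate closed-form oracle is met to machine
precision. Whenever the accelerometer magnitude is within `accel_gate`
(default 0.5 m/s²) of gravity, the estimate is rotated toward
gravity-consistency about the horizontal axis `u × ẑ` (where `u` is the
measured up-direction in world coordinates) by `correction_gain` (default
0.02 per sample at 100 Hz) of the remaining tilt error. The correction axis
is horizontal by construction, so heading is never altered: a constant yaw
error propagates unchanged, which is the defining non-observability of
magnetometer-free fusion. With the default gain, a gyro bias `b` produces a
steady-state tilt error of about `b·Δt/gain` (0.25° for 0.5°/s at 100 Hz)
instead of unbounded drift.

Heading drift *within* a repetition is accepted: examinations last seconds,
and the system re-initializes at the start of every repetition from a 1 s
static window (`init_window`).

## Calibration and the heading prior

The simplified neutral-posture calibration measures sensor inclination from
the averaged gravity vector of the static window and takes heading from the
*expected* sensor orientation — the catalog's neutral segment frame composed
with the declared (placement-protocol) mounting. The sensor→segment rotation
follows as `q_seg_world⁻¹ ⊗ q̂_sensor_world`.

Consequences, inherited deliberately:

* a mounting rotation that is *declared* (any tilt, any yaw) is recovered
  exactly and leaves joint angles unchanged (the mounting-invariance
  property, < 0.2° noise-free);
* a mounting yaw the protocol does not declare is unobservable from gravity
  and leaks into the angles;
* a subject who cannot reach the neutral-zero start shifts the measurement
  by the start offset (a 10° offset shifts the reported RoM by ≈10°); the
  tool cannot detect this, it only reports a `residual_tilt` quality metric
  (the angle between the expected and the measured gravity direction).

A static-window gyro check (0.35 rad/s RMS) rejects calibration during
motion.

## Joint angles and RoM

Joint angles use the Grood–Suntay joint coordinate system: body-fixed
flexion axis e₁ = proximal segment x, body-fixed long axis e₃ = distal
segment y, floating e₂ = their mutual perpendicular; abduction is the
deviation of the e₁–e₃ angle from 90°. Algebraically this equals an
intrinsic X–Z–Y Euler factorization of the relative rotation, implemented in
closed form (`flexion = atan2(R₃₂, R₂₂)`, `abduction = asin(−R₁₂)`,
`rotation = atan2(R₁₃, R₁₁)`) and cross-checked in the tests against scipy's
independent Euler path. Near the gimbal singularity (|abduction| > 80°) the
angles are still returned but flagged, never failed.

Two measurement modes mirror the examination software: joints with sensors
on both segments decompose the proximal-relative orientation of the distal
segment; single-sensor examinations (shoulder rotation, forearm
pronation/supination, hip rotation) decompose the distal sensor's rotation
away from its own starting orientation. "In the corresponding plane of
motion" is realized as *taking the examination's JCS component*, not as a
geometric projection; for the planar motions of these examinations the two
readings coincide.

The reported RoM of a repetition is the unsigned extreme of the JCS
component in the direction the nomenclature names (sign +1 → maximum, −1 →
negated minimum); both extremes are retained so one recording can serve a
paired left/right nomenclature. Pronation/supination is measured at the
distal-forearm sensor: the dorsum-of-hand sensor is known to over-read from
skin motion under the examiner's grip, so the hand sites serve the wrist
examinations only. The trunk examinations pair Th4 (distal) against L5/S1
(proximal), the cervical examinations forehead against Th4 — with three
trunk/head sensors this is the only physically sensible assignment, and the
pairing is configurable in the catalog.

## The synthetic study

The simulator emulates the study design: 20 subjects, 3 raters each using
their own sensor set, 5 repetitions per examination, examiner ratings on a
5° grid. Random effects (degrees, all seeded through one root seed):

| effect | default | why |
|---|---|---|
| between subjects, true RoM mean | catalog reference midpoint | anchors cohorts at published normal values |
| between subjects, SD | clip(0.15·mean, 2, 12) | matches the 2–20° spread of published cohort SDs |
| between sessions (subject × rater) | 2 | sensor re-fitting and day-state differences, seen by both sources |
| between repetitions | 3 | execution variability; reproduces within-repetition SDs of a few degrees |
| rater bias | (−6, 0, +6) | systematic over/under-estimation up to 12° between rater pairs |
| rater perception SD | 8 per (subject, rater, angle) | spreads examiner ICC over ≈0.3–0.95 |
| rating anchor | 0.2 | examiners anchor on their first impression; ratings track only a fraction of repetition-to-repetition variation, keeping examiner within-repetition SDs below ≈1° |
| gyro noise / bias | 0.2 °/s, 0.3 °/s per sensor set | typical consumer MEMS figures |
| accel noise | 0.05 m/s² | idem |
| soft-tissue rotation | 2° sinusoid at 0.25 Hz | skin-mounted sensors rotate on the segment; literature reports up to ≈8° on the shank under vigorous motion, clinical handling is gentler |
| start-posture offset SD | 2° | imperfect neutral-zero postures |

The rater perception error is drawn once per (subject, rater, angle) and
held constant over the five repetitions. This is deliberate: examiners
rating the same subject seconds apart do not re-draw independent errors —
their repeated ratings are nearly constant — and only a non-averaging error
term makes the average-measures reliability converge to the analytic
ICC(3,k) = σ_s²/(σ_s² + σ_e²/k) that the analysis layer is tested against.
Grid rounding is half-up (73.2° on a 5° grid → 75°) for determinism.

The inverse sensor model emits, per sample, the constant body rate that
carries the orientation to the next sample (so noise-free streams
re-integrate to the ground truth within 0.05° over 10 s) and the gravity
reaction rotated into the sensor frame. Translational segment acceleration
is **not** simulated: the examinations are quasi-static, and this keeps the
accelerometer gate testable in isolation.

What the simulator does *not* emulate — and hence what green tests do not
show about real data: non-planar and multi-axis joint kinematics, skin
artifacts correlated with the examiner's grip, magnetic disturbance (there
is no magnetometer at all), anthropometric variation, fatigue or learning
effects, and real examiner psychology beyond bias + anchored noise.

## Statistics

* Within-repetition repeatability: sample SD (n−1) per (subject, rater,
  angle), averaged over subjects, raters and the left/right members of an
  examination family. Note the estimator's sampling distribution: the mean
  of n=5 sample SDs is centred at c₄(5)·σ ≈ 0.94·σ, so recovery tests
  compare against c₄·σ; a bias-corrected value (mean/c₄) is also reported.
* ICC(3,k): two-way mean squares on the subjects × raters matrix of
  repetition means; ICC = (BMS − EMS)/BMS. Negative estimates are reported
  raw (the display layer floors them at 0 with a flag); zero between-subject
  variance yields NaN with an `undefined` flag. Acceptability is ICC ≥ 0.8,
  inclusive. Confidence intervals are out of scope. Subjects with any
  missing rater cell for an angle are dropped for that angle and counted.
* Bland–Altman: per-subject difference (first-listed minus second-listed
  rater) against the pair mean; limits of agreement at MDiff ± 1.96·SD
  (n−1); acceptable systematic difference strictly below 5°. The agreement
  panel orders k examiner-vs-own-measurement comparisons, then all
  measurement pairs, then all examiner pairs.

## Problem sizes in tests and acceptance

The acceptance computations use the design conditions directly: all 40
catalog angles for noise-free recovery; 1000 random triples for the JCS
round trip; 100 random 20×3 matrices plus a 2000-subject cohort for the ICC
oracles; 200 subjects × 2 raters × 5 repetitions through the full pipeline
for repeatability recovery; and the full 20 × 3 × 5 study over the 10 active
angles for the measurement-vs-examiner comparison. These sizes were chosen
so each statistical claim has comfortable resolving power while a complete
run stays in the minutes range on one CPU.

## Known limitations

* Heading errors (undeclared mounting yaw, yaw drift over very long
  repetitions) bias flexion/abduction components multiplicatively
  (≈cos of the yaw error) and are invisible to the quality metric.
* Small-magnitude angles (elbow/knee extension) are dominated by
  start-posture variation — their reliability is intrinsically poor, which
  the simulator reproduces via the small between-subject SD.
* The catalog's single-axis motion model is a simplification; real passive
  examinations include out-of-plane components the JCS decomposition would
  expose but the simulator never generates.
* Equivalence is claimed to the contracts above, not to any particular
  proprietary estimator.
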