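# romexam

**IMU-supported joint range-of-motion examination — simulation, measurement
chain, and inter-rater reliability analysis.**

Occupational-medicine screening examines joint range of motion (RoM) by the
neutral-zero method: the distal segment of a joint is moved from a defined
neutral posture about a defined axis to the end of its range, and the maximum
rotation angle is the result. In practice the examiner estimates this angle
by eye. A body-worn network of inertial measurement units (IMUs) can measure
it instead — without magnetometers, which are unreliable indoors — while the
physician examines as usual.

`romexam` implements that measurement chain and the statistics used to judge
it, for a whole-body catalog of **40 examination angles** (active cervical and
thoraco-lumbar spine; passive shoulder, elbow, wrist, hip, knee) measured by
**13 sensor sites**:

* **catalog** — the validated examination catalog: joints, anatomical
  nomenclature, sensor-site pairing, joint-coordinate-system axis, sign
  conventions and two literature reference ranges per angle;
* **fusion** — magnetometer-free orientation estimation: strapdown
  integration of the angular rate `q ← q ⊗ exp(½ ω Δt)` with a
  complementary-filter tilt correction toward the measured gravity direction
  (heading is initialized from the expected neutral posture and never
  corrected — it is unobservable without a magnetometer);
* **anatomy** — simplified neutral-posture sensor-to-segment calibration
  (gravity for inclination, placement protocol for heading), Grood–Suntay
  joint angles (flexion e₁ / floating e₂ / axial e₃), and min/max RoM
  extraction mapped to the anatomical nomenclature;
* **kinesim** — a seeded synthetic study generator: ground-truth segment
  kinematics, inverse IMU sensor model (gyro noise/bias, accelerometer
  noise, soft-tissue rotation, start-posture offsets), and examiner rating
  sheets with subject, session, repetition and rater random effects;
* **reliability** — the analysis layer: within-repetition SD
  (repeatability), inter-rater ICC(3,k) = (BMS − EMS)/BMS with the
  acceptability rule ICC ≥ 0.8, and Bland–Altman agreement
  (MDiff ± 1.96·SD limits, acceptable when |MDiff| < 5°);
* **cli / io / analysis** — a four-verb command line
  (`simulate`, `process`, `analyze`, `report`) over CSV/YAML/JSON formats,
  byte-reproducible for a fixed seed.

## Worked example

A small noisy study — two subjects, three raters, five repetitions of the
active cervical rotation examination:

```yaml
# config.yaml
output_dir: run
seed: 3
cohort:
  n_subjects: 2
  n_raters: 3
  n_repetitions: 5
  angle_ids: [cervical_rotation_L]
```

```sh
romexam simulate --config config.yaml   # IMU streams + examiner sheet + truth
romexam process  --config config.yaml   # fusion + calibration + RoM per repetition
romexam analyze  --config config.yaml   # ICC, Bland-Altman, repeatability
romexam report   --config config.yaml   # markdown summary
```

The report prints tables like

```
| Examination angle   | ICC (Measurements) | ICC (Examiners) |
|---------------------|--------------------|-----------------|
| cervical_rotation_L | **0.86**           | **0.93**        |
```

where bold marks acceptable reliability (ICC ≥ 0.8). The measurement column
comes from the simulated IMU streams pushed through orientation estimation,
neutral-posture calibration and Grood–Suntay decomposition; the examiner
column from the simulated visual ratings (rater bias + perception error,
rounded to the customary 5° grid). The Bland–Altman section lists each
examiner against their own measurement, all measurement pairs and all
examiner pairs (9 comparisons for 3 raters), with MDiff bold when the
systematic difference is below 5°.

In library form the same chain is three calls:

```python
from romexam import load_catalog
from romexam.kinesim import CohortSpec, simulate_study
from romexam.anatomy import process_study
from romexam.reliability import build_rating_table, icc_3k

catalog = load_catalog()
study = simulate_study(CohortSpec(angle_ids=("cervical_rotation_L",), seed=7), catalog)
results = process_study(study.iter_recordings(), catalog)
print(icc_3k(build_rating_table(results, "cervical_rotation_L",
                                "measurement", "measured_rom_deg")).icc_3k)
```

## Scope

The package deliberately omits magnetometer fusion, functional (movement
based) calibration, distance-based screening items (finger–floor,
chin–jugulum), figure rendering (it emits plot *data*), and any real-time or
GUI layer. See `docs/methods.md` for the model assumptions, simulator
details and known limitations.
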