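# fmakit

Sensor-based automation of upper-limb motor-function assessment.

Standard clinical instruments for post-stroke motor impairment — the
Fugl-Meyer Assessment (FMA) above all — ask a patient to perform a series of
predefined movements while a clinician rates each one on a three-point scale
(0: cannot perform, 1: partial, 2: faultless) and sums the ratings into a
total. Administering the full upper-limb battery takes a clinician on the
order of half an hour per patient. `fmakit` implements the alternative: the
patient is watched by a handful of low-cost sensors — a depth camera
producing a 30 Hz joint-position skeleton, a wrist IMU (3-axis accelerometer
in g, 3-axis gyroscope in deg/s, 100 Hz), a five-channel flexion-sensing
glove, and a grip pressure sensor — and each test movement is scored by a
per-test machine-learning classifier over features extracted from those
streams.

The package is aimed at researchers building or evaluating automated
assessment pipelines. It contains no device drivers: recordings are plain
JSON/CSV containers, and a seeded forward-kinematic movement simulator
generates realistic multi-sensor recordings at all three impairment levels,
so the entire pipeline is testable without hardware.

## The pipeline

1. **Preprocessing** (`fmakit.preprocess`). Movement speed is removed as a
   scoring factor: frames where the wrist moved less than a threshold are
   dropped, and the remainder is resampled to a fixed per-test frame count at
   even intervals. Median filtering (boundary-replicated) smooths IMU, glove
   and pressure channels. Movement end is detected automatically as the first
   sustained quiet period after motion onset.
2. **Feature extraction** (`fmakit.features`). Seven primitives, combined per
   test by a declarative YAML recipe:
   * limb orientation — unit vector **v** = (p_distal − p_proximal)/‖·‖ (3 dims);
   * joint angle — θ = arccos(**S**ᵀ**I**) for adjacent unit limb vectors
     **S**, **I** (1 dim);
   * rotation range — max − min of the median-filtered Z accelerometer, the
     gravity signature of supination/pronation (1 dim, g);
   * smoothness — Σ|raw − filtered| over accelerometer axes (1 dim);
   * movement amount — ∫ max(0, |gyro| − baseline) dt summed over axes
     (1 dim, deg);
   * grip strength — max of the filtered pressure series (1 dim, counts);
   * finger state — the five filtered glove channels at the most
     flexed/extended instant (5 dims, counts).
3. **Classification** (`fmakit.classify`). One classifier per test: pairwise
   linear-kernel SVMs with majority voting (default C, unscaled features), or
   a from-scratch 3-layer backpropagation network (inputs = feature
   dimension, 3 outputs, hidden ≈ halfway between; sigmoid units, full-batch
   gradient descent, seeded). Validation is subject-wise: leave-one-subject-out
   folds, with the default regime of 5 training instances per score per test.
4. **Assessment** (`fmakit.assessment`). A built-in registry of 23 supported
   test movements (5 Shoulder, 4 Elbow, 2 Forearm, 7 Hand, 3 Wrist,
   2 Coordination/Speed); per-test scores are summed into the assessment
   total, and agreement between an automated and a clinician total is
   reported as (1 − |auto − clin|/clin) × 100.

## Worked example

Simulate a 3-subject cohort for three tests, train per-test SVMs, assess one
subject's partial (score-1) performances, and cross-validate:

```
$ fmakit simulate --subjects 3 --seed 7 --tests forearm_supination \
    --tests elbow_flexion --tests hand_grasp_a -o recordings
$ fmakit train -i recordings --classifier svm --instances-per-class 0 -o models
$ mkdir subject && cp recordings/S01_*_s1_*.json subject/
$ fmakit assess -i subject -m models -o report.json
Assessment report for subject S01
  Elbow: Flexion                                1
  Forearm: Supination                           1
  Hand: Grasp a                                 1
  shoulder_abduction                            skipped (no recording; clinician-administered)
  ...
  TOTAL                                         3
$ fmakit crossval -i recordings -o cv.json
mean accuracy 1.0000
```

All three movements recorded at impairment level 1 are scored 1, the total
(3) is the sum of the per-test scores, and registry tests without a recording
are reported as clinician-administered rather than scored 0. Leave-one-
subject-out accuracy on this small low-noise cohort is 1.0.

From Python, the same components compose directly:

```python
>>> import fmakit as fk
>>> fk.score_agreement(29, 30)   # automated vs clinician total
96.67
>>> b = fk.simulate_movement("forearm_supination", 2, fk.SubjectParams(), seed=1)
>>> round(fk.rotation_range(b.imu, 5), 2)   # ~2 g for a 180-degree supination
1.97
```

## Documentation

* `docs/methods.md` — models, parameters, numerical choices, and what the
  simulator does and does not emulate.
* `docs/recording_format.md` — the recording container schema (JSON and
  per-stream CSV).
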