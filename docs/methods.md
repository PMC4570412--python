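# Methods

## Problem setting

Upper-limb motor assessments rate each of a battery of predefined test
movements on a discrete scale — here 0 (the movement cannot be performed),
1 (performed partially), 2 (performed faultlessly) — and sum the ratings
into a total indexing the patient's impairment level. `fmakit` automates the
rating step: multi-sensor recordings of a movement are preprocessed, reduced
to a small per-test feature vector, and classified into {0, 1, 2} by a
per-test model trained on labeled recordings. 23 test movements are
supported by the built-in registry; battery items that need external
actuation (reflexes) or fine-motion sensing are outside the registry and are
reported as clinician-administered, never scored.

The published count of supported tests is internally inconsistent in the
source material (the inventory table lists 23 movements; the surrounding
text says 24 in one place and 25 in another). The registry implements
exactly the 23 tabulated movements and does not attempt to reconcile the
counts.

## Sensor data model

Four streams, all timestamped in seconds from recording start:

| stream   | contents                               | rate    | units        |
|----------|----------------------------------------|---------|--------------|
| skeleton | named 3-D joint positions + status     | 30 Hz   | m (camera frame, +Y up, +Z toward subject) |
| imu      | 3-axis accelerometer, 3-axis gyroscope | 100 Hz  | g, deg/s     |
| glove    | five finger-flexion channels           | 100 Hz  | raw counts, larger = more flexed, default range [0, 1023] |
| pressure | grip force                             | 30 Hz   | raw counts   |

Units and the camera frame are this package's conventions (the hardware
itself fixes none of them); they are validated at construction and preserved
by the JSON/CSV container round trip (`docs/recording_format.md`). Skeleton
joints carry a tracked/inferred/missing status; missing means occluded, and
occluded samples are excluded from every computation.

## Preprocessing

**Speed normalization.** Movement speed is not a rated quality, so skeleton
sequences are normalized in two stages using the wrist (the fastest, most
reliably tracked upper-limb joint) as the reference point. Stage 1 walks the
frames and drops any frame whose wrist moved less than `movement_threshold`
(default 3 mm) from the previously retained frame. Stage 2 resamples the
retained frames to a fixed per-test count `target_frames` (default 45 ≈
1.5 s at 30 Hz) with the even-interval index map

    in_idx(j) = round(j · (n_in − 1) / (n_out − 1)),   j = 0 … n_out − 1,

which deletes or repeats frames at even intervals and always preserves the
first and last retained postures. (A stepped delete-every-k-th rule was
considered and rejected: for deletion counts beyond half the sequence it
removes the endpoints.) A fully stationary sequence collapses to one posture
repeated `target_frames` times.

**Median filtering.** All 1-D channel smoothing uses a centered sliding
median with boundary samples replicated at the edges (delegated to
`scipy.ndimage.median_filter(mode="nearest")` and cross-checked against a
brute-force reference in the tests). `filter_window` defaults to 5 samples.
The filter never widens a channel's range and is the shared smoothing step
of four feature primitives.

**Movement-end segmentation.** Recording stops are detected from the motion
signal — per-frame wrist displacement for skeleton data, gyro magnitude
(threshold `gyro_rest_threshold`, default 5 deg/s) for IMU data, including a
glove's embedded IMU. Movement onset is the first sample at or above the
rest threshold; the cut point is the start of the first quiet run after
onset lasting at least `end_quiet_time` (default 0.5 s). All streams are
trimmed at the cut. A recording with no qualifying quiet run is returned
unchanged; an all-rest recording is trimmed to its initial quiet window.
Ordering onset before quiet-run search keeps the deliberate pre-movement
rest window (used for gyro baselining) intact.

## Features

Seven primitives (dimensions in parentheses); per-test recipes are ordered
lists of primitive calls shipped in `src/fmakit/data/registry.yaml` and
user-overridable:

* **limb orientation (3)** — unit vector from a proximal to a distal joint at
  a recipe-designated frame. Normalization removes limb-length and distance
  variation between subjects.
* **joint angle (1)** — θ = arccos(**S**ᵀ**I**) between the two adjacent unit
  limb vectors at the designated frame (e.g. upper arm and forearm for the
  elbow); the dot product is clamped to [−1, 1] before arccos to absorb
  rounding. Frame selectors: `wrist_highest`, `wrist_lowest`, `first`,
  `last`, with ties broken toward the earliest frame. Selectors consider
  only frames in which every joint the recipe touches is visible.
* **rotation range (1)** — max − min of the median-filtered Z accelerometer.
  A wrist-worn IMU's Z axis picks up gravity as the forearm rotates, so this
  range tracks supination/pronation, circumduction and dorsiflexion extent.
  It is reported in g; mapping g to degrees would need a calibration of
  sensor mounting that is deliberately out of scope.
* **smoothness (1)** — Σ|raw − median-filtered| over the three accelerometer
  axes; zero for constant signals, grows with tremor.
* **movement amount (1)** — the per-axis gyro baseline is the median of
  |gyro| over the first 0.5 s (recordings are expected to begin at rest);
  the feature is the trapezoidal time integral of the excess |gyro| −
  baseline, clipped at zero, summed over axes. Using |gyro| per-axis then
  summing makes the proxy robust to sensor orientation; the units are
  degrees of accumulated excursion.
* **grip strength (1)** — maximum of the median-filtered pressure series.
* **finger state (5)** — each glove channel is median-filtered, the instant
  maximizing (flexion) or minimizing (extension) the summed channels is
  located, and the five filtered values there are returned.

Feature vectors are **not** rescaled before classification. A typical
skeleton recipe (one joint angle plus the two limb orientations) has seven
dimensions.

## Classifiers

Each test owns its own model; the two families are interchangeable.

**Linear SVM.** Soft-margin linear-kernel SVMs at the library default C = 1,
fitted pairwise: one binary machine per pair of scores present in training,
prediction by majority vote, ties broken by summed decision values and then
toward the lower score. The pairwise arrangement is load-bearing, not a
convenience: the partial-execution class lies *between* the no-movement and
faultless classes along every amplitude-monotone feature, so no single
linear discriminant can separate it from the union of the other two — a
one-vs-rest arrangement of linear machines systematically loses the middle
class even on cleanly separated data.

**Backpropagation network (BNN).** A hand-written 3-layer network: input
layer sized to the feature dimension d, three output nodes (one per score;
prediction is the argmax, ties toward the lower score), and a hidden layer
of round_half_up((d + 3)/2) nodes — about halfway between input and output
(7 features → 5 hidden). Sigmoid activations throughout, squared-error
objective, full-batch gradient descent (defaults: 2000 epochs, learning rate
1.0), Xavier-uniform initialization from a caller-supplied seed; training is
bitwise deterministic given the seed. The network standardizes its inputs
internally using training-set mean/sd stored with the weights: raw-count
features (glove, pressure, magnitudes ~10²–10³) would otherwise saturate
the sigmoids and stall gradient descent. This is a property of the network,
not a pipeline preprocessing step — the stored statistics travel with the
model.

Models serialize to versioned JSON (weights/hyperplanes, dimensions,
training metadata).

**Validation.** `crossval_by_subject` implements the subject-wise protocol:
each fold holds out every recording of one subject and trains on the rest
(folds = number of subjects). Folds whose training partition collapses to a
single class are skipped with a warning. The default training regime
subsamples 5 instances per score per test, the size at which held-out
accuracy peaks before overfitting; `training_curve` reproduces that
accuracy-vs-training-size study.

## Assessment aggregation

Per-test scores are summed into the assessment total (0 ≤ total ≤ 2 × tests
scored). Agreement between an automated total *a* and a clinician total *c*
is (1 − |a − c|/c) × 100, reported to two decimals — 100.00 iff the totals
are equal, strictly decreasing in |a − c|. This formula reproduces both
published patient comparisons (29 vs 30 → 96.67%, 30 vs 33 → 90.91%).

## The movement simulator

`fmakit.synth` generates recordings with the structure the pipeline assumes.
Each test has a template of time profiles — shoulder elevation, elbow
flexion, forearm rotation, finger flexion, grip effort — describing the
faultless execution: a raised-cosine ramp (or a full out-and-back cycle for
circumduction) over a nominal 2 s movement, padded with 0.6 s of initial and
0.8 s of final rest. Impairment is amplitude scaling: score 2 uses the full
amplitude, score 1 a factor drawn uniformly from [0.3, 0.7] per recording,
score 0 a residual of at most 5%.

Skeleton frames come from forward kinematics of a neck–shoulder–elbow–wrist
chain with per-subject limb lengths, sampled at 30 Hz, with i.i.d. Gaussian
position noise per joint and occlusion modeled as `missing`-status runs with
geometric (mean 3 frames) lengths. The IMU Z accelerometer is the gravity
projection −cos(ρ(t)) of the forearm rotation angle, so a 180° supination
sweeps −1 g → +1 g; the gyroscope is the numerical derivative of the angle
profiles in deg/s; tremor enters as Gaussian noise on the accelerometer
(amplitude in g) with a proportional gyro component. Glove counts follow the
finger profile with per-finger gains; pressure follows a half-sine grip
effort bump.

Subjects are drawn from documented distributions (limb lengths ~N(0.30,
0.02) m and N(0.26, 0.02) m; speed factor U(0.75, 1.3)); two noise presets
stand in for the healthy-cohort vs patient gap: `low_noise` (tremor 0.01 g,
position sd 2 mm, occlusion 1%) and `clinical_noise` (0.12 g, 15 mm, 10%).
All randomness derives from one root seed via seed-sequence spawning keyed
by (subject, test, score, repetition), making cohorts bit-for-bit
reproducible.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and skeleton-tracking artifacts beyond
i.i.d. noise and dropout runs; compensatory movement strategies (real
patients recruit the trunk and shoulder girdle); fatigue and intra-session
drift; correlated multi-joint tremor; glove fit variability. Scores in the
simulator are amplitude-defined by construction, so classification accuracy
on synthetic cohorts is an upper bound of sorts on clinical performance —
the published experience, where accuracy dropped substantially when models
trained on healthy movements scored patient movements, should be kept in
mind.

## Study conditions used by the test suite

The acceptance-level checks run on a simulated cohort of 8 subjects × 23
registry tests × 3 levels (552 recordings), low-noise preset, 5 training
instances per score, leave-one-subject-out validation — sizes at which the
whole suite completes in well under a minute of classifier work on one CPU.
Reported there and asserted by the tests: mean LOSO accuracy ≥ 0.90 for both
classifier families, ≥ 90% of movements recover their generating score
end-to-end, every per-subject total within 3 points of the generating total,
and a shuffled-label control at chance level (1/3).

## Known limitations

* Angular calibration of rotation range (g → degrees) is out of scope.
* Occlusion handling is deletion-based; no gap filling or re-tracking.
* The registry's per-test recipes are fixed expert choices; recipes are not
  learned from data.
* `score_agreement` is undefined for a clinician total of 0 (it normalizes
  by that total).
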