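"""Seeded simulator of multi-sensor test-movement recordings.

The simulator stands in for live sensors so the whole scoring pipeline can be
exercised at desk scale.  Each supported test movement has a template of
time-parameterized angle profiles (shoulder elevation, elbow flexion, forearm
rotation, finger flexion, grip effort) describing a faultless (score-2)
execution.  A recording at a given impairment level is produced by scaling
the movement amplitude:

* score 2 — full amplitude;
* score 1 — partial execution, amplitude factor drawn uniformly from
  [0.3, 0.7];
* score 0 — the movement is essentially absent, residual amplitude at most
  5% of full.

Skeleton frames come from forward kinematics of a two-segment arm (shoulder →
elbow → wrist → hand) sampled at 30 Hz in the camera frame (+Y up, +Z toward
the subject), with Gaussian position noise and occlusion dropouts (joint
status ``missing`` in geometrically distributed runs).  The IMU (100 Hz)
derives its Z accelerometer from the projection of gravity onto the rotating
forearm — a supination through 180° sweeps the channel from −1 g to +1 g —
and its gyroscope from the angular-velocity profiles, with tremor noise on
both.  Glove (100 Hz) and pressure (30 Hz) channels follow the finger and
grip profiles in raw counts.  Every recording starts with a rest window and
ends with a quiet tail so movement-end segmentation has something to find.

All randomness flows from one root seed: child generators are derived per
(subject, test, score, repetition) via ``numpy``'s SeedSequence spawning
mechanism (``default_rng([root, ...indices])``), so cohorts are bit-for-bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .classify import LabeledDataset
from .errors import ParameterError, ValidationError
from .features import extract_features
from .sensor_io import (
    GloveTrace,
    ImuTrace,
    JointStatus,
    PressureTrace,
    RecordingBundle,
    SkeletonFrame,
    SkeletonSequence,
    side_joint,
)

GRAVITY_G = 1.0  # accelerometer works in units of g

SKELETON_RATE = 30.0
IMU_RATE = 100.0
GLOVE_RATE = 100.0
PRESSURE_RATE = 30.0

SCORE1_AMPLITUDE = (0.3, 0.7)
SCORE0_MAX_AMPLITUDE = 0.05

#: Noise presets: the healthy-cohort ("low_noise") vs stroke-patient
#: ("clinical_noise") analogue.  Values chosen once as study conditions.
PRESETS = {
    "low_noise": {
        "tremor_amplitude": 0.01,
        "position_noise_sd": 0.002,
        "occlusion_rate": 0.01,
    },
    "clinical_noise": {
        "tremor_amplitude": 0.12,
        "position_noise_sd": 0.015,
        "occlusion_rate": 0.10,
    },
}


@dataclass
class SubjectParams:
    """Anthropometry and noise levels for one simulated subject."""

    upper_arm_length: float = 0.30
    forearm_length: float = 0.26
    movement_speed_factor: float = 1.0
    tremor_amplitude: float = 0.01
    position_noise_sd: float = 0.002
    occlusion_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.upper_arm_length <= 0 or self.forearm_length <= 0:
            raise ParameterError("limb lengths must be > 0")
        if self.movement_speed_factor <= 0:
            raise ParameterError("movement_speed_factor must be > 0")
        if not 0 <= self.occlusion_rate < 1:
            raise ParameterError("occlusion_rate must lie in [0, 1)")


@dataclass(frozen=True)
class MovementTemplate:
    """Angle/effort profiles of the faultless execution of one test."""

    test_id: str
    duration: float = 2.0  # seconds of movement at speed factor 1
    rest_pre: float = 0.6
    rest_post: float = 0.8
    plane: str = "xy"  # movement plane: "xy" (lateral) or "yz" (sagittal)
    shoulder_start: float = 0.12  # rad from hanging-down
    shoulder_amp: float = 0.0
    elbow_start: float = 0.15  # rad of elbow flexion (0 = straight)
    elbow_amp: float = 0.0
    rotation_amp: float = 0.0  # rad of forearm rotation (gravity on IMU Z)
    rotation_shape: str = "ramp"  # "ramp" (go and hold) or "cycle" (go and return)
    finger_start: float = 0.1  # fraction of full flexion
    finger_amp: float = 0.0
    grip_amp: float = 0.0  # fraction of full grip effort
    hand_gyro_gain: float = 0.0  # deg/s of wrist gyro per unit finger velocity


def _t(tid: str, **kw) -> MovementTemplate:
    return MovementTemplate(test_id=tid, **kw)


TEMPLATES: Dict[str, MovementTemplate] = {
    t.test_id: t
    for t in [
        _t("shoulder_abduction", plane="xy", shoulder_amp=2.1, elbow_start=0.25),
        _t("shoulder_external_rotation", plane="yz", shoulder_start=0.2,
           shoulder_amp=0.9, elbow_start=1.57),
        _t("shoulder_abduction_0_90", plane="xy", shoulder_start=0.1,
           shoulder_amp=1.47),
        _t("shoulder_flexion_0_90", plane="yz", shoulder_start=0.1,
           shoulder_amp=1.47),
        _t("shoulder_flexion_90_180", plane="yz", shoulder_start=1.57,
           shoulder_amp=1.5),
        _t("elbow_flexion", plane="xy", shoulder_start=0.15, elbow_amp=2.1),
        _t("elbow_extension", plane="xy", shoulder_start=0.15,
           elbow_start=2.25, elbow_amp=-2.0),
        _t("elbow_prosup_0", rotation_amp=math.pi),
        _t("elbow_prosup_90", rotation_amp=math.pi),
        _t("forearm_supination", rotation_amp=2.8),
        _t("forearm_pronation", rotation_amp=-2.8),
        _t("hand_mass_flexion", finger_amp=0.8, hand_gyro_gain=40.0),
        _t("hand_mass_extension", finger_start=0.9, finger_amp=-0.8,
           hand_gyro_gain=40.0),
        _t("hand_grasp_a", finger_start=0.15, finger_amp=0.65, grip_amp=0.85,
           hand_gyro_gain=40.0),
        _t("hand_grasp_b", finger_start=0.15, finger_amp=0.7, grip_amp=0.75,
           hand_gyro_gain=40.0),
        _t("hand_grasp_c", finger_start=0.2, finger_amp=0.6, grip_amp=0.9,
           hand_gyro_gain=40.0),
        _t("hand_grasp_d", finger_start=0.1, finger_amp=0.75, grip_amp=0.6,
           hand_gyro_gain=40.0),
        _t("hand_grasp_e", finger_start=0.15, finger_amp=0.55, grip_amp=0.7,
           hand_gyro_gain=40.0),
        _t("wrist_flexext_elbow_90", rotation_amp=1.3),
        _t("wrist_flexext_elbow_0", rotation_amp=1.1),
        _t("wrist_circumduction", rotation_amp=1.5, rotation_shape="cycle"),
        _t("coord_tremor", rotation_amp=0.9),
        _t("coord_speed", rotation_amp=2.4, duration=1.0),
    ]
}


def _phase(t: np.ndarray, t0: float, dur: float, shape: str) -> np.ndarray:
    tau = np.clip((t - t0) / dur, 0.0, 1.0)
    if shape == "ramp":
        return 0.5 * (1.0 - np.cos(np.pi * tau))
    if shape == "cycle":
        return np.sin(2.0 * np.pi * tau)
    raise ParameterError(f"unknown profile shape {shape!r}")


def _amplitude_factor(score: int, rng: np.random.Generator) -> float:
    if score == 2:
        return 1.0
    if score == 1:
        return float(rng.uniform(*SCORE1_AMPLITUDE))
    if score == 0:
        return float(rng.uniform(0.0, SCORE0_MAX_AMPLITUDE))
    raise ParameterError(f"score must be 0, 1 or 2, got {score!r}")


def _occlusion_mask(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Missing-frame mask with geometrically distributed run lengths (mean 3)."""
    mask = np.zeros(n, dtype=bool)
    if rate <= 0:
        return mask
    p_enter = rate / 3.0
    i = 0
    while i < n:
        if rng.random() < p_enter:
            run = int(rng.geometric(1.0 / 3.0))
            mask[i : i + run] = True
            i += run
        else:
            i += 1
    return mask


def _arm_direction(angle: np.ndarray, plane: str, sx: float) -> np.ndarray:
    """Unit direction of a limb elevated by ``angle`` from hanging-down."""
    if plane == "xy":
        return np.stack(
            [sx * np.sin(angle), -np.cos(angle), np.zeros_like(angle)], axis=1
        )
    if plane == "yz":
        return np.stack(
            [np.zeros_like(angle), -np.cos(angle), -np.sin(angle)], axis=1
        )
    raise ParameterError(f"unknown movement plane {plane!r}")


def simulate_movement(
    test_id: str,
    score: int,
    subject: SubjectParams,
    seed,
    subject_id: str = "sim",
    side: str = "right",
) -> RecordingBundle:
    """Generate one recording of one test at one impairment level.

    Deterministic given ``seed`` (an int or an int sequence).  Only the
    sensor streams the test requires are generated; hand tests carry the
    glove's embedded IMU so movement-end detection has a motion signal.
    """
    from .assessment import registry_by_id

    template = TEMPLATES.get(test_id)
    test = registry_by_id().get(test_id)
    if template is None or test is None:
        raise ValidationError(f"unknown test {test_id!r}")
    rng = np.random.default_rng(seed)
    a = _amplitude_factor(score, rng)
    dur = template.duration / subject.movement_speed_factor
    t_total = template.rest_pre + dur + template.rest_post
    t0 = template.rest_pre

    def shoulder_angle(t):
        return template.shoulder_start + a * template.shoulder_amp * _phase(
            t, t0, dur, "ramp"
        )

    def elbow_angle(t):
        return template.elbow_start + a * template.elbow_amp * _phase(
            t, t0, dur, "ramp"
        )

    def rotation_angle(t):
        return a * template.rotation_amp * _phase(
            t, t0, dur, template.rotation_shape
        )

    def finger_level(t):
        return template.finger_start + a * template.finger_amp * _phase(
            t, t0, dur, "ramp"
        )

    kwargs: dict = {}
    required = test.required_sensors

    if "skeleton" in required:
        kwargs["skeleton"] = _simulate_skeleton(
            template, subject, side, t_total, shoulder_angle, elbow_angle, rng
        )

    imu = None
    if "imu" in required or "glove" in required:
        imu = _simulate_imu(
            subject,
            t_total,
            shoulder_angle,
            elbow_angle,
            rotation_angle,
            finger_level,
            template.hand_gyro_gain,
            rng,
        )
    if "imu" in required:
        kwargs["imu"] = imu

    if "glove" in required:
        t = np.arange(0.0, t_total, 1.0 / GLOVE_RATE)
        level = finger_level(t)
        gains = np.array([1.0, 0.95, 1.05, 0.9, 0.85])
        noise_sd = 3.0 + 40.0 * subject.tremor_amplitude
        counts = 100.0 + 700.0 * level[:, None] * gains[None, :]
        counts = counts + rng.normal(0.0, noise_sd, size=counts.shape)
        kwargs["glove"] = GloveTrace(
            timestamps=t,
            flexion=np.clip(counts, 0, 1023),
            imu=imu if "imu" not in required else None,
            nominal_rate=GLOVE_RATE,
        )

    if "pressure" in required:
        t = np.arange(0.0, t_total, 1.0 / PRESSURE_RATE)
        tau = np.clip((t - t0) / dur, 0.0, 1.0)
        effort = a * _t_grip(template) * np.sin(np.pi * tau)
        noise_sd = 2.0 + 20.0 * subject.tremor_amplitude
        values = 5.0 + 650.0 * effort + rng.normal(0.0, noise_sd, size=t.shape)
        kwargs["pressure"] = PressureTrace(
            timestamps=t, values=np.clip(values, 0, None), nominal_rate=PRESSURE_RATE
        )

    return RecordingBundle(
        test_id=test_id,
        subject_id=subject_id,
        side=side,
        true_score=score,
        **kwargs,
    )


def _t_grip(template: MovementTemplate) -> float:
    return template.grip_amp


def _simulate_skeleton(
    template, subject, side, t_total, shoulder_angle, elbow_angle, rng
) -> SkeletonSequence:
    t = np.arange(0.0, t_total, 1.0 / SKELETON_RATE)
    n = len(t)
    sx = -1.0 if side == "right" else 1.0  # mirrored in the camera frame
    neck = np.array([0.0, 0.55, 2.0])
    shoulder = neck + np.array([0.18 * sx, -0.03, 0.0])
    th_s = shoulder_angle(t)
    th_e = elbow_angle(t)
    u = _arm_direction(th_s, template.plane, sx)
    f = _arm_direction(th_s + th_e, template.plane, sx)
    elbow = shoulder + subject.upper_arm_length * u
    wrist = elbow + subject.forearm_length * f
    hand = wrist + 0.08 * f

    s_wrist = side_joint("wrist", side)
    s_elbow = side_joint("elbow", side)
    occl = {
        s_wrist: _occlusion_mask(n, subject.occlusion_rate, rng),
        s_elbow: _occlusion_mask(n, subject.occlusion_rate, rng),
    }
    # always keep >= 2 wrist frames usable
    if occl[s_wrist].sum() > n - 2:
        occl[s_wrist][:2] = False

    frames: List[SkeletonFrame] = []
    sd = subject.position_noise_sd
    noise = rng.normal(0.0, sd, size=(n, 5, 3)) if sd > 0 else np.zeros((n, 5, 3))
    for i in range(n):
        joints = {
            "neck": neck + noise[i, 0],
            side_joint("shoulder", side): shoulder + noise[i, 1],
            s_elbow: elbow[i] + noise[i, 2],
            s_wrist: wrist[i] + noise[i, 3],
            side_joint("hand", side): hand[i] + noise[i, 4],
        }
        status = {}
        for j, mask in occl.items():
            if mask[i]:
                joints[j] = np.full(3, np.nan)
                status[j] = JointStatus.MISSING
        frames.append(
            SkeletonFrame(timestamp=float(t[i]), joints=joints, confidence=status)
        )
    return SkeletonSequence(frames=frames, nominal_rate=SKELETON_RATE)


def _simulate_imu(
    subject,
    t_total,
    shoulder_angle,
    elbow_angle,
    rotation_angle,
    finger_level,
    hand_gyro_gain,
    rng,
) -> ImuTrace:
    t = np.arange(0.0, t_total, 1.0 / IMU_RATE)
    th_s = shoulder_angle(t)
    th_e = elbow_angle(t)
    rho = rotation_angle(t)
    tremor = subject.tremor_amplitude
    accel = np.stack(
        [
            0.08 * np.sin(th_s + th_e),
            0.05 * np.sin(th_s),
            -GRAVITY_G * np.cos(rho),
        ],
        axis=1,
    )
    accel = accel + rng.normal(0.0, tremor, size=accel.shape)
    deg = 180.0 / math.pi
    gyro = np.stack(
        [
            np.gradient(th_e, t) * deg,
            np.gradient(th_s, t) * deg,
            np.gradient(rho, t) * deg,
        ],
        axis=1,
    )
    if hand_gyro_gain:
        gyro[:, 0] = gyro[:, 0] + hand_gyro_gain * np.gradient(finger_level(t), t)
    gyro_noise = 50.0 * tremor
    gyro = gyro + rng.normal(0.0, gyro_noise, size=gyro.shape)
    return ImuTrace(
        timestamps=t, accel=accel, gyro=gyro, placement="wrist", nominal_rate=IMU_RATE
    )


def draw_subject(rng: np.random.Generator, preset: str) -> SubjectParams:
    """Draw one subject's parameters from the documented distributions."""
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}")
    p = PRESETS[preset]
    return SubjectParams(
        upper_arm_length=float(np.clip(rng.normal(0.30, 0.02), 0.22, 0.38)),
        forearm_length=float(np.clip(rng.normal(0.26, 0.02), 0.18, 0.34)),
        movement_speed_factor=float(rng.uniform(0.75, 1.3)),
        tremor_amplitude=p["tremor_amplitude"] * float(rng.uniform(0.6, 1.4)),
        position_noise_sd=p["position_noise_sd"] * float(rng.uniform(0.6, 1.4)),
        occlusion_rate=p["occlusion_rate"],
    )


@dataclass
class CohortResult:
    """Simulated cohort: raw bundles plus per-test labeled feature datasets."""

    bundles: List[RecordingBundle]
    datasets: Dict[str, LabeledDataset]
    subjects: Dict[str, SubjectParams]


def simulate_cohort(
    n_subjects: int = 8,
    reps_per_score: int = 1,
    preset: str = "low_noise",
    seed: int = 0,
    tests: Optional[Sequence[str]] = None,
    extract: bool = True,
) -> CohortResult:
    """Simulate a cohort over the registry (or a subset of tests).

    Generates ``reps_per_score`` recordings per (subject, test, score) and,
    when ``extract`` is set, assembles one labeled feature dataset per test.
    Deterministic given ``seed``.
    """
    from .assessment import registry

    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if reps_per_score < 1:
        raise ParameterError("reps_per_score must be >= 1")
    tests_list = [t for t in registry() if tests is None or t.test_id in tests]
    if tests is not None and len(tests_list) != len(set(tests)):
        known = {t.test_id for t in registry()}
        raise ValidationError(f"unknown tests: {sorted(set(tests) - known)}")

    subjects: Dict[str, SubjectParams] = {}
    for si in range(n_subjects):
        sid = f"S{si + 1:02d}"
        subjects[sid] = draw_subject(np.random.default_rng([seed, 999_983, si]), preset)

    bundles: List[RecordingBundle] = []
    rows: Dict[str, list] = {t.test_id: [] for t in tests_list}
    for si, (sid, sp) in enumerate(subjects.items()):
        for ti, test in enumerate(tests_list):
            for score in (0, 1, 2):
                for rep in range(reps_per_score):
                    bundle = simulate_movement(
                        test.test_id,
                        score,
                        sp,
                        seed=[seed, si, ti, score, rep],
                        subject_id=sid,
                    )
                    bundles.append(bundle)
                    if extract:
                        fv = extract_features(bundle, test)
                        rows[test.test_id].append((fv, score, sid))
    datasets = {
        tid: LabeledDataset.from_rows(r, tid) for tid, r in rows.items() if r
    }
    return CohortResult(bundles=bundles, datasets=datasets, subjects=subjects)
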