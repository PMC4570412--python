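import numpy as np
import pytest

import fmakit as fk

#: root seed of the simulated study cohort used across the suite
COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """8 subjects x full registry x 3 impairment levels, low-noise preset."""
    return fk.simulate_cohort(
        n_subjects=8, reps_per_score=1, preset="low_noise", seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def registry_by_id():
    return fk.registry_by_id()


def make_sequence(wrist_xyz, side="right", rate=30.0, extra_joints=True):
    """Skeleton sequence from explicit wrist positions (one frame per row)."""
    frames = []
    for i, pos in enumerate(np.atleast_2d(np.asarray(wrist_xyz, dtype=float))):
        joints = {"wrist_r" if side == "right" else "wrist_l": pos}
        if extra_joints:
            joints["neck"] = np.array([0.0, 0.5, 2.0])
            joints[f"shoulder_{side[0]}"] = np.array([-0.18, 0.47, 2.0])
            joints[f"elbow_{side[0]}"] = pos + np.array([0.0, 0.25, 0.0])
        frames.append(fk.SkeletonFrame(timestamp=i / rate, joints=joints))
    return fk.SkeletonSequence(frames=frames, nominal_rate=rate)


def make_imu(timestamps, accel=None, gyro=None):
    t = np.asarray(timestamps, dtype=float)
    zeros = np.zeros((len(t), 3))
    return fk.ImuTrace(
        timestamps=t,
        accel=zeros if accel is None else np.asarray(accel, dtype=float),
        gyro=zeros if gyro is None else np.asarray(gyro, dtype=float),
    )


def separable_dataset(n_per_class=5, sd=0.01, spacing=10.0, dim=3, seed=1,
                      n_subjects=None, test_id="toy"):
    """Three well-separated Gaussian clusters, one per score."""
    rng = np.random.default_rng(seed)
    xs, ys, subjects = [], [], []
    n_subjects = n_subjects or n_per_class
    for c in (0, 1, 2):
        center = np.full(dim, c * spacing)
        for i in range(n_per_class):
            xs.append(center + rng.normal(0.0, sd, size=dim))
            ys.append(c)
            subjects.append(f"P{i % n_subjects}")
    return fk.LabeledDataset(
        X=np.array(xs), y=np.array(ys), subjects=subjects, test_id=test_id
    )
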