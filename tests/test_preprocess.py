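"""Speed normalization, filtering, limb vectors and movement segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmakit as fk
from fmakit.preprocess import PreprocessParams

import oracles
from conftest import make_imu, make_sequence


def _params(**kw):
    defaults = dict(target_frames=30, movement_threshold=0.002,
                    filter_window=3, end_quiet_time=1.0)
    defaults.update(kw)
    return PreprocessParams(**defaults)


class TestNormalizeSpeed:
    def test_stationary_prefix_collapses_and_length_is_exact(self):
        wrist = np.zeros((90, 3))
        wrist[45:, 1] = np.cumsum(np.full(45, 0.005))  # 5 mm per frame
        seq = make_sequence(wrist)
        out = fk.normalize_speed(seq, "right", _params())
        assert len(out) == 30
        ys = [f.position("wrist_r")[1] for f in out.frames]
        # the 45-frame stationary prefix survives as at most one posture
        assert sum(1 for y in ys if y == 0.0) <= 1

    def test_fixed_point_when_all_steps_move(self):
        wrist = np.column_stack([np.zeros(30), np.arange(30) * 0.01, np.zeros(30)])
        seq = make_sequence(wrist)
        out = fk.normalize_speed(seq, "right", _params())
        for fa, fb in zip(seq.frames, out.frames):
            np.testing.assert_array_equal(fa.position("wrist_r"),
                                          fb.position("wrist_r"))

    def test_fully_stationary_sequence_repeats_single_posture(self):
        seq = make_sequence(np.tile([0.1, 0.2, 1.9], (12, 1)))
        out = fk.normalize_speed(seq, "right", _params())
        assert len(out) == 30
        for f in out.frames:
            np.testing.assert_array_equal(f.position("wrist_r"), [0.1, 0.2, 1.9])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_reference_rule_frame_by_frame(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        wrist = rng.normal(0.0, 0.01, size=(n, 3)).cumsum(axis=0)
        target = int(rng.integers(2, 80))
        thr = float(rng.uniform(0.001, 0.02))
        seq = make_sequence(wrist)
        out = fk.normalize_speed(
            seq, "right", _params(target_frames=target, movement_threshold=thr)
        )
        picks = oracles.normalize_speed_ref(
            {i: tuple(w) for i, w in enumerate(wrist)}, list(range(n)), thr, target
        )
        assert len(out) == target
        for frame, k in zip(out.frames, picks):
            np.testing.assert_array_equal(frame.position("wrist_r"), wrist[k])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(n=st.integers(2, 500), target=st.integers(2, 120), seed=st.integers(0, 10**6))
    def test_output_length_always_target(self, n, target, seed):
        rng = np.random.default_rng(seed)
        wrist = rng.normal(0.0, 0.01, size=(n, 3)).cumsum(axis=0)
        out = fk.normalize_speed(
            make_sequence(wrist), "right", _params(target_frames=target)
        )
        assert len(out) == target

    def test_invariant_to_prepending_stationary_frames(self):
        rng = np.random.default_rng(3)
        wrist = rng.normal(0.0, 0.02, size=(60, 3)).cumsum(axis=0)
        padded = np.vstack([np.tile(wrist[0], (25, 1)), wrist])
        out_a = fk.normalize_speed(make_sequence(wrist), "right", _params())
        out_b = fk.normalize_speed(make_sequence(padded), "right", _params())
        pos_a = np.array([f.position("wrist_r") for f in out_a.frames])
        pos_b = np.array([f.position("wrist_r") for f in out_b.frames])
        np.testing.assert_allclose(pos_a, pos_b)

    def test_degenerate_input_rejected(self):
        seq = make_sequence([[0.0, 0.0, 1.9]])
        with pytest.raises(fk.DegenerateInputError):
            fk.normalize_speed(seq, "right", _params())


class TestFindExtremeWristFrame:
    def test_simple_highest(self):
        seq = make_sequence([[0, 0.1, 2], [0, 0.5, 2], [0, 0.3, 2]])
        assert fk.find_extreme_wrist_frame(seq, "right", "highest") == 1

    def test_constant_height_tie_breaks_earliest(self):
        seq = make_sequence(np.tile([0.0, 0.4, 2.0], (5, 1)))
        assert fk.find_extreme_wrist_frame(seq, "right", "highest") == 0
        assert fk.find_extreme_wrist_frame(seq, "right", "lowest") == 0

    @pytest.mark.parametrize("direction", ["highest", "lowest"])
    def test_noisy_sinusoid_matches_exhaustive_scan(self, direction):
        rng = np.random.default_rng(7)
        y = np.sin(np.linspace(0, 6 * np.pi, 200)) + rng.normal(0, 0.05, 200)
        seq = make_sequence(np.column_stack([np.zeros(200), y, np.full(200, 2.0)]))
        expected = oracles.find_extreme_ref(list(enumerate(y)), direction)
        assert fk.find_extreme_wrist_frame(seq, "right", direction) == expected

    def test_occluded_frames_ignored(self):
        frames = []
        for i, y in enumerate([0.1, 9.9, 0.3]):
            status = {"wrist_r": "missing"} if i == 1 else {}
            joints = {"wrist_r": [0, np.nan if i == 1 else y, 2]}
            frames.append(fk.SkeletonFrame(timestamp=float(i), joints=joints,
                                           confidence=status))
        seq = fk.SkeletonSequence(frames=frames)
        assert fk.find_extreme_wrist_frame(seq, "right", "highest") == 2


class TestMedianFilter:
    def test_window_one_is_identity(self):
        x = [3.0, 1.0, 2.0]
        np.testing.assert_array_equal(fk.median_filter(x, 1), x)

    def test_known_example_with_replicated_edges(self):
        np.testing.assert_array_equal(
            fk.median_filter([0, 3, 7, 5, 0], 3), [0, 3, 5, 5, 0]
        )

    def test_even_window_rejected(self):
        with pytest.raises(fk.ParameterError):
            fk.median_filter([1.0, 2.0], 2)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 60),
           window=st.integers(0, 5))
    def test_matches_bruteforce_and_never_widens_range(self, seed, n, window):
        window = 2 * window + 1
        if window > 2 * n + 1:
            window = 1
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        out = fk.median_filter(x, window)
        np.testing.assert_allclose(out, oracles.median_filter_ref(list(x), window),
                                   atol=1e-12)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    def test_idempotent_on_monotone_series(self):
        x = np.array([0.0, 0.5, 1.0, 1.1, 2.0, 3.0])
        once = fk.median_filter(x, 3)
        np.testing.assert_allclose(fk.median_filter(once, 3), once)


class TestLimbVector:
    def test_axis_aligned(self):
        frame = fk.SkeletonFrame(0.0, {"elbow_r": [0, 0, 0], "wrist_r": [0, 2, 0]})
        np.testing.assert_allclose(fk.limb_vector(frame, "elbow_r", "wrist_r"),
                                   [0, 1, 0])

    def test_hand_computed_diagonal(self):
        frame = fk.SkeletonFrame(0.0, {"elbow_r": [1, 1, 1], "wrist_r": [2, 3, 1]})
        np.testing.assert_allclose(
            fk.limb_vector(frame, "elbow_r", "wrist_r"),
            np.array([1, 2, 0]) / np.sqrt(5), rtol=1e-12,
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_unit_norm_translation_invariant_rotation_equivariant(self, seed):
        rng = np.random.default_rng(seed)
        p, d = rng.normal(size=3), rng.normal(size=3)
        if np.linalg.norm(d - p) < 1e-6:
            d = p + np.array([1.0, 0, 0])
        shift = rng.normal(size=3)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(rng=rng).as_matrix()

        def vec(a, b):
            return fk.limb_vector(
                fk.SkeletonFrame(0.0, {"elbow_r": a, "wrist_r": b}),
                "elbow_r", "wrist_r",
            )

        v = vec(p, d)
        assert abs(np.linalg.norm(v) - 1.0) < 1e-9
        np.testing.assert_allclose(vec(p + shift, d + shift), v, atol=1e-9)
        np.testing.assert_allclose(vec(rot @ p, rot @ d), rot @ v, atol=1e-9)

    def test_coincident_joints_rejected(self):
        frame = fk.SkeletonFrame(0.0, {"elbow_r": [1, 1, 1], "wrist_r": [1, 1, 1]})
        with pytest.raises(fk.DegenerateInputError):
            fk.limb_vector(frame, "elbow_r", "wrist_r")


class TestSegmentMovement:
    def _imu_bundle(self, gyro_mag, rate=100.0):
        t = np.arange(len(gyro_mag)) / rate
        gyro = np.column_stack([gyro_mag, np.zeros_like(t), np.zeros_like(t)])
        return fk.RecordingBundle(
            test_id="x", subject_id="s", side="right",
            imu=make_imu(t, gyro=gyro),
        )

    def test_trims_at_movement_end(self):
        # 3 s of motion then 2 s of rest, quiet time 1 s
        mag = np.concatenate([np.full(300, 50.0), np.zeros(200)])
        out = fk.segment_movement(self._imu_bundle(mag), _params())
        assert out.imu.timestamps[-1] == pytest.approx(3.0, abs=0.011)

    def test_continuous_motion_unchanged(self):
        mag = np.full(400, 50.0)
        bundle = self._imu_bundle(mag)
        out = fk.segment_movement(bundle, _params())
        assert len(out.imu) == len(bundle.imu)

    def test_all_rest_trimmed_to_initial_quiet_window(self):
        out = fk.segment_movement(self._imu_bundle(np.zeros(400)), _params())
        assert out.imu.timestamps[-1] == pytest.approx(1.0, abs=0.011)

    def test_cut_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(4)
        mag = np.concatenate([
            np.abs(rng.normal(0, 1, 80)),          # initial rest
            np.abs(rng.normal(40, 5, 250)),        # movement
            np.abs(rng.normal(0, 1, 170)),         # final rest
        ])
        params = _params()
        t = np.arange(len(mag)) / 100.0
        active = mag >= params.gyro_rest_threshold
        onset = int(np.argmax(active))
        expected = None
        for i in range(onset, len(mag)):  # exhaustive scan of quiet-run starts
            if active[i]:
                continue
            j = i
            while j < len(mag) and not active[j]:
                j += 1
            if t[j - 1] - t[i] >= params.end_quiet_time:
                expected = t[i]
                break
        out = fk.segment_movement(self._imu_bundle(mag), params)
        assert expected is not None
        assert out.imu.timestamps[-1] == pytest.approx(expected, abs=1e-9)

    def test_skeleton_and_other_streams_trimmed_together(self):
        bundle = fk.simulate_movement(
            "hand_grasp_a", 2, fk.SubjectParams(tremor_amplitude=0.0), seed=2
        )
        out = fk.segment_movement(bundle, fk.PreprocessParams())
        assert out.glove.timestamps[-1] <= bundle.glove.timestamps[-1]
        assert out.pressure.timestamps[-1] <= out.glove.timestamps[-1] + 1 / 30
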