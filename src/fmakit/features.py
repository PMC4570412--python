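"""Feature extraction from preprocessed sensor streams.

Seven primitives cover the supported movements:

=====================  ====  =======================================================
primitive              dim   meaning
=====================  ====  =======================================================
limb orientation        3    unit vector along a limb segment at a chosen frame
joint angle             1    arccos of the dot product of two adjacent limb vectors
rotation range          1    max − min of the median-filtered Z accelerometer (g);
                             gravity makes this track supination/pronation range
smoothness              1    Σ |raw − median-filtered| over the accelerometer axes;
                             larger for shakier movements
movement amount         1    time integral of gyro magnitude above its resting
                             baseline (deg), an excursion proxy robust to occlusion
grip strength           1    max of the median-filtered pressure series (counts)
finger state            5    filtered glove channels at the most flexed (or most
                             extended) instant (counts)
=====================  ====  =======================================================

Each supported test movement owns a *recipe*: an ordered list of primitive
calls with their joint/frame/mode arguments.  ``extract_features`` runs the
preprocessing chain (movement-end segmentation, then speed normalization when
skeleton data is used) and concatenates the recipe's outputs into one feature
vector.  Features are not rescaled before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, ParameterError, ValidationError
from .preprocess import (
    PreprocessParams,
    find_extreme_wrist_frame,
    limb_vector,
    median_filter,
    normalize_speed,
    segment_movement,
)
from .sensor_io import GloveTrace, ImuTrace, PressureTrace, RecordingBundle, side_joint

#: Seconds of initial rest used to estimate the gyro baseline.
REST_WINDOW_S = 0.5

#: joint name -> (proximal joint, vertex, distal joint) for joint angles
JOINT_TRIPLES = {
    "shoulder": ("neck", "shoulder", "elbow"),
    "elbow": ("shoulder", "elbow", "wrist"),
}

#: limb name -> (proximal joint, distal joint)
LIMBS = {
    "upper_arm": ("shoulder", "elbow"),
    "forearm": ("elbow", "wrist"),
}

#: per-primitive output dimensionality
FEATURE_DIMS = {
    "limb_orientation": 3,
    "joint_angle": 1,
    "rotation_range": 1,
    "smoothness": 1,
    "movement_amount": 1,
    "grip_strength": 1,
    "finger_state": 5,
}


@dataclass
class FeatureVector:
    """Ordered real-valued features for one recording of one test."""

    values: np.ndarray
    names: List[str]
    test_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("feature values must be 1-D")
        if len(self.values) != len(self.names):
            raise ValidationError("feature values and names must align")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# primitives


def joint_angle(superior: Sequence[float], inferior: Sequence[float]) -> float:
    """Angle (radians, in [0, π]) between two adjacent unit limb vectors.

    Computed as arccos(S·I) with the dot product clamped to [−1, 1] to absorb
    rounding.  Both inputs must be unit length to within 1e-6.
    """
    s = np.asarray(superior, dtype=float)
    i = np.asarray(inferior, dtype=float)
    if s.shape != (3,) or i.shape != (3,):
        raise ParameterError("joint_angle expects two 3-vectors")
    for v, name in ((s, "superior"), (i, "inferior")):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ParameterError(f"{name} limb vector is not unit length")
    return float(np.arccos(np.clip(np.dot(s, i), -1.0, 1.0)))


def rotation_range(trace: ImuTrace, window: int) -> float:
    """Range (max − min, g) of the median-filtered Z accelerometer channel.

    With a wrist-worn IMU the Z axis picks up the gravity component, so this
    range tracks the extent of supination/pronation, circumduction and
    dorsiflexion.  Invariant to constant accelerometer offsets.
    """
    if len(trace) == 0:
        raise DegenerateInputError("rotation_range: empty trace")
    z = median_filter(trace.accel[:, 2], window)
    return float(z.max() - z.min())


def smoothness(trace: ImuTrace, window: int) -> float:
    """Shakiness: Σ |raw − median-filtered| over the three accelerometer axes."""
    if len(trace) == 0:
        raise DegenerateInputError("smoothness: empty trace")
    total = 0.0
    for axis in range(3):
        raw = trace.accel[:, axis]
        total += float(np.abs(raw - median_filter(raw, window)).sum())
    return total


def movement_amount(trace: ImuTrace, rest_window: float = REST_WINDOW_S) -> float:
    """Integrated angular excursion proxy (deg) from the gyroscope.

    The resting baseline is the per-axis median of |gyro| over the first
    ``rest_window`` seconds; the feature is the trapezoidal time integral of
    the excess |gyro| − baseline (clipped at zero), summed over the axes.
    """
    if len(trace) < 2:
        raise DegenerateInputError("movement_amount: trace too short")
    t = trace.timestamps
    if t[-1] - t[0] < rest_window:
        raise DegenerateInputError(
            f"movement_amount needs >= {rest_window} s of data for the baseline"
        )
    mag = np.abs(trace.gyro)
    rest = t <= t[0] + rest_window
    baseline = np.median(mag[rest], axis=0)
    excess = np.clip(mag - baseline, 0.0, None)
    return float(np.trapezoid(excess, x=t, axis=0).sum())


def grip_strength(trace: PressureTrace, window: int) -> float:
    """Maximum of the median-filtered grip pressure series (raw counts)."""
    if len(trace) == 0:
        raise DegenerateInputError("grip_strength: empty trace")
    return float(median_filter(trace.values, window).max())


def finger_state(trace: GloveTrace, mode: str, window: int) -> np.ndarray:
    """Filtered glove channel values at the most flexed/extended instant.

    Each of the five channels is median-filtered; the instant maximizing
    (``flexion``) or minimizing (``extension``) the summed filtered channels
    is located (earliest index on ties) and the five filtered values there
    are returned, thumb → little.
    """
    if mode not in ("flexion", "extension"):
        raise ParameterError(f"mode must be 'flexion' or 'extension', got {mode!r}")
    if len(trace) == 0:
        raise DegenerateInputError("finger_state: empty trace")
    filt = np.column_stack(
        [median_filter(trace.flexion[:, c], window) for c in range(5)]
    )
    total = filt.sum(axis=1)
    idx = int(np.argmax(total) if mode == "flexion" else np.argmin(total))
    return filt[idx].copy()


# ---------------------------------------------------------------------------
# recipe evaluation


def _select_frame(skeleton, side: str, selector: str) -> int:
    if selector == "wrist_highest":
        return find_extreme_wrist_frame(skeleton, side, "highest")
    if selector == "wrist_lowest":
        return find_extreme_wrist_frame(skeleton, side, "lowest")
    if selector == "first":
        return 0
    if selector == "last":
        return len(skeleton.frames) - 1
    raise ValidationError(f"unknown frame selector {selector!r}")


def _bundle_imu(bundle: RecordingBundle) -> ImuTrace:
    if bundle.imu is not None:
        return bundle.imu
    if bundle.glove is not None and bundle.glove.imu is not None:
        return bundle.glove.imu
    raise ValidationError(f"test {bundle.test_id!r}: no IMU stream available")


def extract_features(
    bundle: RecordingBundle,
    test,
    params: Optional[PreprocessParams] = None,
) -> FeatureVector:
    """Run preprocessing and evaluate a test's feature recipe.

    ``test`` is a registry entry providing ``test_id``, ``required_sensors``,
    ``recipe`` (list of primitive-call mappings) and default ``preprocess``
    parameters; ``params`` overrides the latter.
    """
    params = params if params is not None else test.preprocess
    bundle.require_streams(test.required_sensors)
    if not test.recipe:
        raise ValidationError(f"test {test.test_id!r}: empty feature recipe")

    bundle = segment_movement(bundle, params)
    skeleton = None
    needs_skeleton = any(
        entry["feature"] in ("joint_angle", "limb_orientation")
        for entry in test.recipe
    )
    if needs_skeleton:
        if bundle.skeleton is None:
            raise ValidationError(
                f"test {test.test_id!r}: recipe needs skeleton data"
            )
        skeleton = normalize_speed(bundle.skeleton, bundle.side, params)
        # frame selectors must only consider frames where every joint the
        # recipe touches is visible (occlusion can hide e.g. the elbow in
        # frames whose wrist is tracked)
        needed = set()
        for entry in test.recipe:
            if entry["feature"] == "joint_angle":
                needed.update(JOINT_TRIPLES.get(entry.get("joint"), ()))
            elif entry["feature"] == "limb_orientation":
                needed.update(LIMBS.get(entry.get("limb"), ()))
        resolved = {side_joint(j, bundle.side) for j in needed}
        visible = [
            f for f in skeleton.frames
            if all(f.is_usable(j) for j in resolved)
        ]
        if not visible:
            raise ValidationError(
                f"test {test.test_id!r}: recipe joints occluded in every frame"
            )
        from .sensor_io import SkeletonSequence

        skeleton = SkeletonSequence(frames=visible,
                                    nominal_rate=skeleton.nominal_rate)

    values: List[float] = []
    names: List[str] = []
    for entry in test.recipe:
        kind = entry["feature"]
        if kind == "joint_angle":
            joint = entry["joint"]
            if joint not in JOINT_TRIPLES:
                raise ValidationError(f"unknown joint {joint!r} in recipe")
            selector = entry.get("frame", "last")
            frame = skeleton.frames[_select_frame(skeleton, bundle.side, selector)]
            prox, vertex, dist = (
                side_joint(j, bundle.side) for j in JOINT_TRIPLES[joint]
            )
            sup = limb_vector(frame, prox, vertex)
            inf = limb_vector(frame, vertex, dist)
            values.append(joint_angle(sup, inf))
            names.append(f"joint_angle[{joint}@{selector}]")
        elif kind == "limb_orientation":
            limb = entry["limb"]
            if limb not in LIMBS:
                raise ValidationError(f"unknown limb {limb!r} in recipe")
            selector = entry.get("frame", "last")
            frame = skeleton.frames[_select_frame(skeleton, bundle.side, selector)]
            prox, dist = (side_joint(j, bundle.side) for j in LIMBS[limb])
            vec = limb_vector(frame, prox, dist)
            values.extend(vec.tolist())
            names.extend(f"limb_orientation[{limb}@{selector}].{ax}" for ax in "xyz")
        elif kind == "rotation_range":
            values.append(rotation_range(_bundle_imu(bundle), params.filter_window))
            names.append("rotation_range")
        elif kind == "smoothness":
            values.append(smoothness(_bundle_imu(bundle), params.filter_window))
            names.append("smoothness")
        elif kind == "movement_amount":
            values.append(movement_amount(_bundle_imu(bundle)))
            names.append("movement_amount")
        elif kind == "grip_strength":
            if bundle.pressure is None:
                raise ValidationError(
                    f"test {test.test_id!r}: recipe needs pressure data"
                )
            values.append(grip_strength(bundle.pressure, params.filter_window))
            names.append("grip_strength")
        elif kind == "finger_state":
            if bundle.glove is None:
                raise ValidationError(
                    f"test {test.test_id!r}: recipe needs glove data"
                )
            mode = entry.get("mode", "flexion")
            vec = finger_state(bundle.glove, mode, params.filter_window)
            values.extend(vec.tolist())
            names.extend(
                f"finger_state[{mode}].{f}"
                for f in ("thumb", "index", "middle", "ring", "little")
            )
        else:
            raise ValidationError(f"unknown feature primitive {kind!r}")
    return FeatureVector(values=np.array(values), names=names, test_id=test.test_id)


def recipe_dimension(recipe) -> int:
    """Total feature dimensionality of a recipe."""
    try:
        return sum(FEATURE_DIMS[e["feature"]] for e in recipe)
    except KeyError as exc:
        raise ValidationError(f"unknown feature primitive {exc}") from exc
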