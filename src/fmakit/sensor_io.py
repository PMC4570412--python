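"""Multi-sensor recording data model and container I/O.

A *recording* is one performance of one test movement by one subject, captured
by any subset of four sensor streams:

* a depth-camera skeleton stream (named 3-D joint positions, nominally 30 Hz),
* a wrist/hand IMU (3-axis accelerometer in g, 3-axis gyroscope in deg/s,
  nominally 100 Hz),
* a data glove (five finger-flexion channels in raw counts),
* a grip pressure sensor (raw counts, nominally 30 Hz).

Recordings are stored either as one JSON document (all streams plus metadata)
or as a directory of per-stream CSV files with a ``meta.json`` sidecar; see
``docs/recording_format.md``.  All timestamps are seconds since recording
start.  Positions are meters in a right-handed camera frame with +Y up and +Z
pointing from the sensor toward the subject.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: Controlled vocabulary of joint names.  Unknown names are rejected.
JOINT_NAMES = (
    "neck",
    "shoulder_l",
    "shoulder_r",
    "elbow_l",
    "elbow_r",
    "wrist_l",
    "wrist_r",
    "hand_l",
    "hand_r",
)

SIDES = ("left", "right")

FORMAT_VERSION = 1


def side_joint(joint: str, side: str) -> str:
    """Resolve a side-agnostic joint name (``wrist``) for a recorded side."""
    if joint == "neck":
        return "neck"
    if side not in SIDES:
        raise ValidationError(f"unknown side {side!r}")
    return f"{joint}_{side[0]}"


class JointStatus(str, Enum):
    TRACKED = "tracked"
    INFERRED = "inferred"
    MISSING = "missing"


@dataclass
class SkeletonFrame:
    """One time sample of estimated 3-D joint positions.

    Positions of joints whose status is ``missing`` are not meaningful (NaN by
    convention); all other positions must be finite.
    """

    timestamp: float
    joints: Dict[str, np.ndarray]
    confidence: Dict[str, JointStatus] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.joints = {k: np.asarray(v, dtype=float) for k, v in self.joints.items()}
        for name, pos in self.joints.items():
            if name not in JOINT_NAMES:
                raise ValidationError(f"unknown joint name {name!r}")
            if pos.shape != (3,):
                raise ValidationError(f"joint {name!r}: position must be a 3-vector")
        self.confidence = {
            k: JointStatus(v) for k, v in self.confidence.items()
        }
        for name in self.confidence:
            if name not in self.joints:
                raise ValidationError(f"confidence for absent joint {name!r}")
        # default: present joints are tracked
        for name in self.joints:
            self.confidence.setdefault(name, JointStatus.TRACKED)
        for name, pos in self.joints.items():
            if self.confidence[name] is not JointStatus.MISSING and not np.all(
                np.isfinite(pos)
            ):
                raise ValidationError(
                    f"joint {name!r}: non-finite position with status "
                    f"{self.confidence[name].value}"
                )

    def is_usable(self, joint: str) -> bool:
        """True when the joint is present and not occluded."""
        return (
            joint in self.joints
            and self.confidence[joint] is not JointStatus.MISSING
        )

    def position(self, joint: str) -> np.ndarray:
        if joint not in self.joints:
            raise ValidationError(f"joint {joint!r} absent from frame")
        return self.joints[joint]


@dataclass
class SkeletonSequence:
    frames: List[SkeletonFrame]
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be > 0")
        ts = [f.timestamp for f in self.frames]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError("skeleton timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)


@dataclass
class ImuTrace:
    """Inertial trace: accelerometer in g, gyroscope in deg/s."""

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    placement: str = "wrist"
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3):
            raise ValidationError("imu: accel must have shape (n, 3)")
        if self.gyro.shape != (n, 3):
            raise ValidationError("imu: gyro must have shape (n, 3)")
        if self.placement not in ("wrist", "hand_dorsum"):
            raise ValidationError(f"imu: unknown placement {self.placement!r}")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValidationError("imu: timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class GloveTrace:
    """Five finger-flexion channels (thumb → little) in raw counts.

    Larger counts mean more flexed; values lie in [0, raw_max].
    """

    timestamps: np.ndarray
    flexion: np.ndarray
    raw_max: int = 1023
    imu: Optional[ImuTrace] = None
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.flexion = np.asarray(self.flexion, dtype=float)
        n = len(self.timestamps)
        if self.flexion.ndim != 2 or self.flexion.shape[1] != 5:
            raise ValidationError(
                "glove: flexion must have 5 channels (thumb..little), got shape "
                f"{self.flexion.shape}"
            )
        if self.flexion.shape[0] != n:
            raise ValidationError("glove: flexion length must match timestamps")
        if np.any(self.flexion < 0) or np.any(self.flexion > self.raw_max):
            raise ValidationError(
                f"glove: flexion values must lie in [0, {self.raw_max}]"
            )
        if np.any(np.diff(self.timestamps) < 0):
            raise ValidationError("glove: timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class PressureTrace:
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.timestamps.shape:
            raise ValidationError("pressure: values length must match timestamps")
        if np.any(self.values < 0):
            raise ValidationError("pressure: values must be >= 0")
        if np.any(np.diff(self.timestamps) < 0):
            raise ValidationError("pressure: timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.timestamps)


STREAM_NAMES = ("skeleton", "imu", "glove", "pressure")


@dataclass
class RecordingBundle:
    """One test-movement performance with its sensor streams and metadata."""

    test_id: str
    subject_id: str
    side: str
    skeleton: Optional[SkeletonSequence] = None
    imu: Optional[ImuTrace] = None
    glove: Optional[GloveTrace] = None
    pressure: Optional[PressureTrace] = None
    true_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.true_score is not None and self.true_score not in (0, 1, 2):
            raise ValidationError("true_score must be 0, 1 or 2")
        if not any(getattr(self, s) is not None for s in STREAM_NAMES):
            raise ValidationError("bundle must contain at least one stream")

    @property
    def streams(self) -> Dict[str, object]:
        return {
            s: getattr(self, s)
            for s in STREAM_NAMES
            if getattr(self, s) is not None
        }

    def require_streams(self, required) -> None:
        """Raise unless every named sensor stream is present."""
        missing = [s for s in sorted(required) if getattr(self, s, None) is None]
        if missing:
            raise ValidationError(
                f"test {self.test_id!r} requires missing sensor(s): "
                + ", ".join(missing)
            )


# ---------------------------------------------------------------------------
# serialization


def _frame_to_obj(frame: SkeletonFrame) -> dict:
    pos = {}
    for name, p in frame.joints.items():
        if frame.confidence[name] is JointStatus.MISSING:
            pos[name] = [None, None, None]
        else:
            pos[name] = [float(x) for x in p]
    return {
        "t": frame.timestamp,
        "pos": pos,
        "status": {k: v.value for k, v in frame.confidence.items()},
    }


def _frame_from_obj(obj: dict) -> SkeletonFrame:
    joints = {
        name: [math.nan if x is None else float(x) for x in p]
        for name, p in obj["pos"].items()
    }
    status = obj.get("status", {})
    return SkeletonFrame(timestamp=float(obj["t"]), joints=joints, confidence=status)


def bundle_to_obj(bundle: RecordingBundle) -> dict:
    """Serialize a bundle to the JSON-ready container object."""
    streams: dict = {}
    if bundle.skeleton is not None:
        streams["skeleton"] = {
            "nominal_rate": bundle.skeleton.nominal_rate,
            "frames": [_frame_to_obj(f) for f in bundle.skeleton.frames],
        }
    if bundle.imu is not None:
        streams["imu"] = _imu_to_obj(bundle.imu)
    if bundle.glove is not None:
        g = bundle.glove
        streams["glove"] = {
            "nominal_rate": g.nominal_rate,
            "raw_max": g.raw_max,
            "samples": np.column_stack([g.timestamps, g.flexion]).tolist(),
        }
        if g.imu is not None:
            streams["glove"]["imu"] = _imu_to_obj(g.imu)
    if bundle.pressure is not None:
        p = bundle.pressure
        streams["pressure"] = {
            "nominal_rate": p.nominal_rate,
            "samples": np.column_stack([p.timestamps, p.values]).tolist(),
        }
    return {
        "format_version": FORMAT_VERSION,
        "test_id": bundle.test_id,
        "subject_id": bundle.subject_id,
        "side": bundle.side,
        "true_score": bundle.true_score,
        "streams": streams,
    }


def _imu_to_obj(imu: ImuTrace) -> dict:
    return {
        "placement": imu.placement,
        "nominal_rate": imu.nominal_rate,
        "samples": np.column_stack([imu.timestamps, imu.accel, imu.gyro]).tolist(),
    }


def _imu_from_obj(obj: dict) -> ImuTrace:
    samples = np.asarray(obj["samples"], dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 7:
        raise ParseError("imu: samples must be rows of [t, ax, ay, az, gx, gy, gz]")
    return ImuTrace(
        timestamps=samples[:, 0],
        accel=samples[:, 1:4],
        gyro=samples[:, 4:7],
        placement=obj.get("placement", "wrist"),
        nominal_rate=float(obj.get("nominal_rate", 100.0)),
    )


def bundle_from_obj(obj: dict) -> RecordingBundle:
    streams = obj.get("streams", {})
    kwargs: dict = {}
    try:
        if "skeleton" in streams:
            sk = streams["skeleton"]
            kwargs["skeleton"] = SkeletonSequence(
                frames=[_frame_from_obj(f) for f in sk["frames"]],
                nominal_rate=float(sk.get("nominal_rate", 30.0)),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"skeleton stream malformed: {exc}") from exc
    try:
        if "imu" in streams:
            kwargs["imu"] = _imu_from_obj(streams["imu"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"imu stream malformed: {exc}") from exc
    try:
        if "glove" in streams:
            g = streams["glove"]
            samples = np.asarray(g["samples"], dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 6:
                raise ValidationError(
                    "glove: samples must be rows of [t, f1..f5] "
                    f"(got {samples.shape[1] - 1} channels)"
                )
            kwargs["glove"] = GloveTrace(
                timestamps=samples[:, 0],
                flexion=samples[:, 1:6],
                raw_max=int(g.get("raw_max", 1023)),
                imu=_imu_from_obj(g["imu"]) if "imu" in g else None,
                nominal_rate=float(g.get("nominal_rate", 100.0)),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"glove stream malformed: {exc}") from exc
    try:
        if "pressure" in streams:
            p = streams["pressure"]
            samples = np.asarray(p["samples"], dtype=float)
            if samples.ndim != 2 or samples.shape[1] != 2:
                raise ValidationError("pressure: samples must be rows of [t, value]")
            kwargs["pressure"] = PressureTrace(
                timestamps=samples[:, 0],
                values=samples[:, 1],
                nominal_rate=float(p.get("nominal_rate", 30.0)),
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"pressure stream malformed: {exc}") from exc
    try:
        bundle = RecordingBundle(
            test_id=obj["test_id"],
            subject_id=obj["subject_id"],
            side=obj["side"],
            true_score=obj.get("true_score"),
            **kwargs,
        )
    except KeyError as exc:
        raise ParseError(f"metadata malformed: missing {exc}") from exc
    _check_registry_requirements(bundle)
    return bundle


def _check_registry_requirements(bundle: RecordingBundle) -> None:
    # lazy import: assessment depends on features which depends on this module
    from .assessment import registry_by_id

    test = registry_by_id().get(bundle.test_id)
    if test is not None:
        bundle.require_streams(test.required_sensors)


# ---------------------------------------------------------------------------
# file round trip

_CSV_FLOAT = "%.12g"  # >= 9 significant digits for lossless-enough round trips


def write_recording(bundle: RecordingBundle, path) -> None:
    """Write a bundle to ``path``.

    ``*.json`` paths get the single-document JSON container; any other path is
    treated as a directory and receives per-stream CSV files plus a
    ``meta.json`` sidecar.
    """
    path = Path(path)
    if path.suffix == ".json":
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(bundle_to_obj(bundle), fh)
        return
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "test_id": bundle.test_id,
        "subject_id": bundle.subject_id,
        "side": bundle.side,
        "true_score": bundle.true_score,
        "rates": {},
    }
    if bundle.skeleton is not None:
        meta["rates"]["skeleton"] = bundle.skeleton.nominal_rate
        joints = sorted({n for f in bundle.skeleton.frames for n in f.joints})
        meta["skeleton_joints"] = joints
        cols: Dict[str, list] = {"timestamp": []}
        for j in joints:
            for ax in "xyz":
                cols[f"{j}_{ax}"] = []
            cols[f"{j}_status"] = []
        for f in bundle.skeleton.frames:
            cols["timestamp"].append(f.timestamp)
            for j in joints:
                if j in f.joints and f.confidence[j] is not JointStatus.MISSING:
                    p = f.joints[j]
                    st = f.confidence[j].value
                else:
                    p = (math.nan,) * 3
                    st = JointStatus.MISSING.value
                for ax, v in zip("xyz", p):
                    cols[f"{j}_{ax}"].append(v)
                cols[f"{j}_status"].append(st)
        pd.DataFrame(cols).to_csv(
            path / "skeleton.csv", index=False, float_format=_CSV_FLOAT
        )
    if bundle.imu is not None:
        meta["rates"]["imu"] = bundle.imu.nominal_rate
        meta["imu_placement"] = bundle.imu.placement
        _write_channels_csv(
            path / "imu.csv",
            bundle.imu.timestamps,
            np.column_stack([bundle.imu.accel, bundle.imu.gyro]),
            ["accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z"],
        )
    if bundle.glove is not None:
        meta["rates"]["glove"] = bundle.glove.nominal_rate
        meta["glove_raw_max"] = bundle.glove.raw_max
        _write_channels_csv(
            path / "glove.csv",
            bundle.glove.timestamps,
            bundle.glove.flexion,
            ["flex_thumb", "flex_index", "flex_middle", "flex_ring", "flex_little"],
        )
        if bundle.glove.imu is not None:
            meta["glove_imu_placement"] = bundle.glove.imu.placement
            _write_channels_csv(
                path / "glove_imu.csv",
                bundle.glove.imu.timestamps,
                np.column_stack([bundle.glove.imu.accel, bundle.glove.imu.gyro]),
                ["accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z"],
            )
    if bundle.pressure is not None:
        meta["rates"]["pressure"] = bundle.pressure.nominal_rate
        _write_channels_csv(
            path / "pressure.csv",
            bundle.pressure.timestamps,
            bundle.pressure.values[:, None],
            ["value"],
        )
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def _write_channels_csv(path, timestamps, channels, names) -> None:
    df = pd.DataFrame(np.column_stack([timestamps, channels]), columns=["timestamp"] + names)
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def read_recording(path) -> RecordingBundle:
    """Read a recording container (JSON file or CSV directory)."""
    path = Path(path)
    if path.is_dir():
        return _read_csv_dir(path)
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    return bundle_from_obj(obj)


def _read_csv_dir(path: Path) -> RecordingBundle:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ParseError(f"{path}: missing meta.json sidecar")
    with open(meta_path) as fh:
        meta = json.load(fh)
    rates = meta.get("rates", {})
    kwargs: dict = {}
    skel_path = path / "skeleton.csv"
    if skel_path.exists():
        try:
            df = pd.read_csv(skel_path)
            joints = meta.get(
                "skeleton_joints",
                sorted({c[:-2] for c in df.columns if c.endswith("_x")}),
            )
            frames = []
            for _, row in df.iterrows():
                jpos = {}
                status = {}
                for j in joints:
                    status[j] = row[f"{j}_status"]
                    jpos[j] = [row[f"{j}_x"], row[f"{j}_y"], row[f"{j}_z"]]
                frames.append(
                    SkeletonFrame(
                        timestamp=row["timestamp"], joints=jpos, confidence=status
                    )
                )
            kwargs["skeleton"] = SkeletonSequence(
                frames=frames, nominal_rate=float(rates.get("skeleton", 30.0))
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"skeleton.csv malformed: {exc}") from exc
    imu_path = path / "imu.csv"
    if imu_path.exists():
        kwargs["imu"] = _read_imu_csv(
            imu_path,
            meta.get("imu_placement", "wrist"),
            float(rates.get("imu", 100.0)),
        )
    glove_path = path / "glove.csv"
    if glove_path.exists():
        try:
            df = pd.read_csv(glove_path)
            glove_imu = None
            if (path / "glove_imu.csv").exists():
                glove_imu = _read_imu_csv(
                    path / "glove_imu.csv",
                    meta.get("glove_imu_placement", "hand_dorsum"),
                    100.0,
                )
            kwargs["glove"] = GloveTrace(
                timestamps=df["timestamp"].to_numpy(),
                flexion=df.iloc[:, 1:].to_numpy()
                if glove_imu is None
                else df.iloc[:, 1:6].to_numpy(),
                raw_max=int(meta.get("glove_raw_max", 1023)),
                imu=glove_imu,
                nominal_rate=float(rates.get("glove", 100.0)),
            )
        except KeyError as exc:
            raise ParseError(f"glove.csv malformed: {exc}") from exc
    pressure_path = path / "pressure.csv"
    if pressure_path.exists():
        try:
            df = pd.read_csv(pressure_path)
            kwargs["pressure"] = PressureTrace(
                timestamps=df["timestamp"].to_numpy(),
                values=df["value"].to_numpy(),
                nominal_rate=float(rates.get("pressure", 30.0)),
            )
        except KeyError as exc:
            raise ParseError(f"pressure.csv malformed: {exc}") from exc
    bundle = RecordingBundle(
        test_id=meta["test_id"],
        subject_id=meta["subject_id"],
        side=meta["side"],
        true_score=meta.get("true_score"),
        **kwargs,
    )
    _check_registry_requirements(bundle)
    return bundle


def trim_bundle(bundle: RecordingBundle, t_cut: float) -> RecordingBundle:
    """Return a copy with every stream trimmed to timestamps <= ``t_cut``.

    Each stream keeps at least its first sample so the result stays valid.
    """
    eps = 1e-9
    kwargs: dict = {}
    if bundle.skeleton is not None:
        frames = [f for f in bundle.skeleton.frames if f.timestamp <= t_cut + eps]
        if not frames:
            frames = bundle.skeleton.frames[:1]
        kwargs["skeleton"] = SkeletonSequence(
            frames=frames, nominal_rate=bundle.skeleton.nominal_rate
        )
    if bundle.imu is not None:
        kwargs["imu"] = _trim_imu(bundle.imu, t_cut)
    if bundle.glove is not None:
        g = bundle.glove
        mask = g.timestamps <= t_cut + eps
        if not mask.any():
            mask[0] = True
        kwargs["glove"] = GloveTrace(
            timestamps=g.timestamps[mask],
            flexion=g.flexion[mask],
            raw_max=g.raw_max,
            imu=_trim_imu(g.imu, t_cut) if g.imu is not None else None,
            nominal_rate=g.nominal_rate,
        )
    if bundle.pressure is not None:
        p = bundle.pressure
        mask = p.timestamps <= t_cut + eps
        if not mask.any():
            mask[0] = True
        kwargs["pressure"] = PressureTrace(
            timestamps=p.timestamps[mask],
            values=p.values[mask],
            nominal_rate=p.nominal_rate,
        )
    return replace(bundle, **kwargs)


def _trim_imu(imu: ImuTrace, t_cut: float) -> ImuTrace:
    mask = imu.timestamps <= t_cut + 1e-9
    if not mask.any():
        mask[0] = True
    return ImuTrace(
        timestamps=imu.timestamps[mask],
        accel=imu.accel[mask],
        gyro=imu.gyro[mask],
        placement=imu.placement,
        nominal_rate=imu.nominal_rate,
    )


def _read_imu_csv(path, placement: str, rate: float) -> ImuTrace:
    try:
        df = pd.read_csv(path)
        return ImuTrace(
            timestamps=df["timestamp"].to_numpy(),
            accel=df[["accel_x", "accel_y", "accel_z"]].to_numpy(),
            gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(),
            placement=placement,
            nominal_rate=rate,
        )
    except KeyError as exc:
        raise ParseError(f"{path.name} malformed: missing column {exc}") from exc
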