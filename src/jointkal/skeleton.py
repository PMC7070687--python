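"""Skeleton data model and file I/O.

A skeleton sequence holds per-frame 3-D positions (camera space, meters) for a
set of named joints, sampled at a fixed frame rate (30 Hz for Kinect v2), with
an optional per-frame sound-source bearing channel.  Coordinates follow the
sensor's right-handed convention: origin at the IR camera, X along the sensor
bar, Y up, Z along the illumination direction.

Missing joint positions are represented by a NaN triple; downstream
classification treats such frames as erroneous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import EstimationError, ParseError, ValidationError

__all__ = [
    "SkeletonTopology",
    "SkeletonSequence",
    "KINECT_V2_JOINTS",
    "default_kinect_topology",
    "read_sequence",
    "write_sequence",
    "read_topology",
    "write_topology",
    "read_labels",
    "write_labels",
    "estimate_bone_length",
]


# Kinect v2 joint names (snake_case) and parent links.  The skeleton root is
# the spine base; each entry maps child -> parent.
KINECT_V2_PARENTS: dict[str, str] = {
    "spine_base": "spine_base",
    "spine_mid": "spine_base",
    "spine_shoulder": "spine_mid",
    "neck": "spine_shoulder",
    "head": "neck",
    "shoulder_left": "spine_shoulder",
    "elbow_left": "shoulder_left",
    "wrist_left": "elbow_left",
    "hand_left": "wrist_left",
    "hand_tip_left": "hand_left",
    "thumb_left": "wrist_left",
    "shoulder_right": "spine_shoulder",
    "elbow_right": "shoulder_right",
    "wrist_right": "elbow_right",
    "hand_right": "wrist_right",
    "hand_tip_right": "hand_right",
    "thumb_right": "wrist_right",
    "hip_left": "spine_base",
    "knee_left": "hip_left",
    "ankle_left": "knee_left",
    "foot_left": "ankle_left",
    "hip_right": "spine_base",
    "knee_right": "hip_right",
    "ankle_right": "knee_right",
    "foot_right": "ankle_right",
}

KINECT_V2_JOINTS: tuple[str, ...] = tuple(KINECT_V2_PARENTS)


@dataclass(frozen=True)
class SkeletonTopology:
    """Parent-child joint links and bone lengths of a kinematic tree.

    Parameters
    ----------
    joints
        Joint names; unique and non-empty.
    parent
        Maps each joint to its parent; the single root maps to itself.
    bone_length
        Maps a child joint to the (constant) length in meters of the bone
        connecting it to its parent.  May be empty; lengths can be estimated
        from data with :func:`estimate_bone_length`.
    """

    joints: tuple[str, ...]
    parent: Mapping[str, str]
    bone_length: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.joints:
            raise ValidationError("topology must contain at least one joint")
        if len(set(self.joints)) != len(self.joints):
            raise ValidationError("joint names must be unique")
        if any(not j for j in self.joints):
            raise ValidationError("joint names must be non-empty")
        joint_set = set(self.joints)
        if set(self.parent) != joint_set:
            raise ValidationError("parent map must cover exactly the joint set")
        for child, par in self.parent.items():
            if par not in joint_set:
                raise ValidationError(f"unknown parent {par!r} for joint {child!r}")
        roots = [j for j in self.joints if self.parent[j] == j]
        if len(roots) != 1:
            raise ValidationError(f"topology must have exactly one root, found {roots}")
        # walk each joint to the root; a cycle never reaches it
        for j in self.joints:
            seen = {j}
            cur = j
            while self.parent[cur] != cur:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValidationError(f"parent map contains a cycle through {cur!r}")
                seen.add(cur)
        for child, length in self.bone_length.items():
            if child not in joint_set:
                raise ValidationError(f"bone length given for unknown joint {child!r}")
            if not length > 0:
                raise ValidationError(f"bone length for {child!r} must be > 0")

    @property
    def root(self) -> str:
        return next(j for j in self.joints if self.parent[j] == j)

    def topological_order(self) -> list[str]:
        """Joints ordered root first, every parent before its children."""
        depth: dict[str, int] = {}

        def _depth(j: str) -> int:
            if j not in depth:
                depth[j] = 0 if self.parent[j] == j else 1 + _depth(self.parent[j])
            return depth[j]

        return sorted(self.joints, key=lambda j: (_depth(j), self.joints.index(j)))

    def with_bone_lengths(self, lengths: Mapping[str, float]) -> "SkeletonTopology":
        merged = dict(self.bone_length)
        merged.update(lengths)
        return SkeletonTopology(self.joints, dict(self.parent), merged)


def default_kinect_topology() -> SkeletonTopology:
    """The 25-joint Kinect v2 skeleton (spine base root, no bone lengths)."""
    return SkeletonTopology(KINECT_V2_JOINTS, dict(KINECT_V2_PARENTS))


@dataclass
class SkeletonSequence:
    """Per-frame 3-D joint positions, optionally with a sound-source bearing.

    ``positions`` has shape ``(n_frames, n_joints, 3)`` in meters; a NaN
    triple marks a missing joint observation.  ``sound_angle`` (radians) is
    the subject bearing arctan(x/z) reported by the sensor's microphone
    array, used as a fourth measurement channel by the extended Kalman
    filter.
    """

    joints: tuple[str, ...]
    positions: np.ndarray
    frame_rate: float = 30.0
    sound_angle: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.joints = tuple(self.joints)
        self.positions = np.asarray(self.positions, dtype=float)
        if not self.joints:
            raise ValidationError("sequence must contain at least one joint")
        if len(set(self.joints)) != len(self.joints):
            raise ValidationError("joint names must be unique")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.joints), 3):
            raise ValidationError(
                f"positions must have shape (n_frames, {len(self.joints)}, 3), "
                f"got {self.positions.shape}"
            )
        if self.positions.shape[0] < 1:
            raise ValidationError("sequence must contain at least one frame")
        if not self.frame_rate > 0:
            raise ValidationError("frame_rate must be > 0")
        if self.sound_angle is not None:
            self.sound_angle = np.asarray(self.sound_angle, dtype=float)
            if self.sound_angle.shape != (self.positions.shape[0],):
                raise ValidationError("sound_angle must have one value per frame")

    @property
    def frame_count(self) -> int:
        return int(self.positions.shape[0])

    def joint(self, name: str) -> np.ndarray:
        """The ``(n_frames, 3)`` trajectory of one joint."""
        try:
            idx = self.joints.index(name)
        except ValueError:
            raise KeyError(f"unknown joint {name!r}") from None
        return self.positions[:, idx, :]

    def with_positions(self, positions: np.ndarray) -> "SkeletonSequence":
        return SkeletonSequence(self.joints, positions, self.frame_rate,
                                None if self.sound_angle is None else self.sound_angle.copy())

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns frame, joint, x, y, z[, sound_angle]."""
        n, j = self.frame_count, len(self.joints)
        frame = np.repeat(np.arange(n), j)
        joint = np.tile(np.array(self.joints, dtype=object), n)
        xyz = self.positions.reshape(n * j, 3)
        df = pd.DataFrame({"frame": frame, "joint": joint,
                           "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2]})
        if self.sound_angle is not None:
            df["sound_angle"] = np.repeat(self.sound_angle, j)
        return df


def _sequence_from_records(records: pd.DataFrame, frame_rate: float,
                           source: str) -> SkeletonSequence:
    if records.duplicated(subset=["frame", "joint"]).any():
        dup = records[records.duplicated(subset=["frame", "joint"])].iloc[0]
        raise ValidationError(
            f"{source}: duplicate entry for frame {int(dup['frame'])}, joint {dup['joint']!r}")
    frames = np.sort(records["frame"].unique())
    if frames[0] != 0 or not np.array_equal(frames, np.arange(len(frames))):
        raise ValidationError(
            f"{source}: frame indices must be 0-based and contiguous, got gaps in {frames[:10]}")
    joints = tuple(pd.unique(records["joint"]))
    n = len(frames)
    positions = np.full((n, len(joints), 3), np.nan)
    jindex = {j: k for k, j in enumerate(joints)}
    fi = records["frame"].to_numpy(dtype=int)
    ji = records["joint"].map(jindex).to_numpy(dtype=int)
    positions[fi, ji, 0] = records["x"].to_numpy(dtype=float)
    positions[fi, ji, 1] = records["y"].to_numpy(dtype=float)
    positions[fi, ji, 2] = records["z"].to_numpy(dtype=float)
    sound = None
    if "sound_angle" in records.columns:
        sound = np.full(n, np.nan)
        sound[fi] = records["sound_angle"].to_numpy(dtype=float)
    return SkeletonSequence(joints, positions, frame_rate, sound)


def read_sequence(path: str | Path, format: str | None = None,
                  frame_rate: float = 30.0) -> SkeletonSequence:
    """Read a skeleton sequence from CSV or JSONL.

    CSV schema: header ``frame,joint,x,y,z[,sound_angle]``, UTF-8, '.' decimal
    separator, units meters.  JSONL: one frame object per line with keys
    ``frame``, ``joints`` (name -> [x, y, z]) and optional ``sound_angle``.
    """
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        required = {"frame", "joint", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        for col in ("frame", "x", "y", "z"):
            try:
                pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                line = int(bad.index[0]) + 2 if len(bad) else "?"
                raise ParseError(f"{path}, line {line}: non-numeric value in column {col!r}") from exc
        return _sequence_from_records(df, frame_rate, str(path))
    elif fmt == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ParseError(f"{path}, line {lineno}: {exc}") from exc
                try:
                    for joint, xyz in obj["joints"].items():
                        rows.append({"frame": obj["frame"], "joint": joint,
                                     "x": xyz[0], "y": xyz[1], "z": xyz[2],
                                     **({"sound_angle": obj["sound_angle"]}
                                        if obj.get("sound_angle") is not None else {})})
                except (KeyError, TypeError, IndexError) as exc:
                    raise ParseError(f"{path}, line {lineno}: malformed frame object") from exc
        if not rows:
            raise ParseError(f"{path}: empty sequence file")
        df = pd.DataFrame(rows)
        return _sequence_from_records(df, frame_rate, str(path))
    raise ValueError(f"unknown format {fmt!r}")


def write_sequence(seq: SkeletonSequence, path: str | Path,
                   format: str | None = None) -> None:
    """Write a sequence as CSV or JSONL, readable back by :func:`read_sequence`."""
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    if fmt == "csv":
        seq.to_dataframe().to_csv(path, index=False, float_format="%.12g")
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for f in range(seq.frame_count):
                obj: dict = {"frame": f, "joints": {
                    j: [float(v) for v in seq.positions[f, k]]
                    for k, j in enumerate(seq.joints)}}
                if seq.sound_angle is not None:
                    a = seq.sound_angle[f]
                    obj["sound_angle"] = None if math.isnan(a) else float(a)
                fh.write(json.dumps(obj) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_topology(path: str | Path) -> SkeletonTopology:
    """Read a topology from a YAML mapping of joint -> {parent, bone_length}."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: topology file must be a mapping")
    joints = tuple(raw)
    parent = {}
    bone_length = {}
    for joint, entry in raw.items():
        entry = entry or {}
        parent[joint] = entry.get("parent", joint)
        if entry.get("bone_length") is not None:
            bone_length[joint] = float(entry["bone_length"])
    return SkeletonTopology(joints, parent, bone_length)


def write_topology(topo: SkeletonTopology, path: str | Path) -> None:
    out = {}
    for j in topo.joints:
        entry: dict = {"parent": topo.parent[j]}
        if j in topo.bone_length:
            entry["bone_length"] = float(topo.bone_length[j])
        out[j] = entry
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def read_labels(path: str | Path) -> np.ndarray:
    """Read manual per-frame error labels from CSV ``frame,erroneous`` (0/1)."""
    df = pd.read_csv(path)
    if not {"frame", "erroneous"}.issubset(df.columns):
        raise ParseError(f"{path}: label file needs columns frame, erroneous")
    frames = df["frame"].to_numpy(dtype=int)
    if not np.array_equal(np.sort(frames), np.arange(len(frames))):
        raise ValidationError(f"{path}: label frames must be 0-based and contiguous")
    out = np.zeros(len(frames), dtype=bool)
    out[frames] = df["erroneous"].to_numpy(dtype=int).astype(bool)
    return out


def write_labels(labels: Iterable[bool], path: str | Path) -> None:
    labels = np.asarray(list(labels), dtype=bool)
    pd.DataFrame({"frame": np.arange(len(labels)),
                  "erroneous": labels.astype(int)}).to_csv(path, index=False)


def estimate_bone_length(parent_traj: np.ndarray, child_traj: np.ndarray,
                         erroneous: Sequence[bool] | np.ndarray | None = None) -> float:
    """Robust (median) bone length between two joint trajectories.

    Only frames where both joints are finite — and, if ``erroneous`` labels
    are supplied, not flagged — contribute.  Human limb segments are rigid,
    so the median inter-joint distance over trusted frames is a stable
    estimate of the constant bone length.
    """
    parent_traj = np.asarray(parent_traj, dtype=float)
    child_traj = np.asarray(child_traj, dtype=float)
    if parent_traj.shape != child_traj.shape or parent_traj.ndim != 2:
        raise ValidationError("parent and child trajectories must share shape (n, 3)")
    ok = np.isfinite(parent_traj).all(axis=1) & np.isfinite(child_traj).all(axis=1)
    if erroneous is not None:
        erroneous = np.asarray(erroneous, dtype=bool)
        if erroneous.shape[0] != parent_traj.shape[0]:
            raise ValidationError("labels must have one entry per frame")
        ok &= ~erroneous
    if not ok.any():
        raise EstimationError("no admissible frames to estimate bone length from")
    dist = np.linalg.norm(child_traj[ok] - parent_traj[ok], axis=1)
    length = float(np.median(dist))
    if not length > 0:
        raise EstimationError("estimated bone length is not positive")
    return length
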