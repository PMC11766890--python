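"""Skeleton data structures: 25 named body joints, frames, and traces.

The sensor tracks the 25-joint body model (four spine/head joints plus a
ten-joint chain per arm and a four-joint chain per leg).  Positions are in
meters in a body-centred frame with x pointing to the subject's left,
y up, and z from the subject toward the sensor (the subject faces the
camera, so +z is the subject's forward direction).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

#: The 25 canonical joint labels.
JOINT_NAMES: tuple[str, ...] = (
    "spine-base",
    "spine-mid",
    "spine-shoulder",
    "neck",
    "head",
    "shoulder-left",
    "elbow-left",
    "wrist-left",
    "hand-left",
    "hand-tip-left",
    "thumb-left",
    "shoulder-right",
    "elbow-right",
    "wrist-right",
    "hand-right",
    "hand-tip-right",
    "thumb-right",
    "hip-left",
    "knee-left",
    "ankle-left",
    "foot-left",
    "hip-right",
    "knee-right",
    "ankle-right",
    "foot-right",
)

JOINT_SET = frozenset(JOINT_NAMES)

#: Joint tracking states. "missing" joints carry no usable position.
VALID_STATES = ("tracked", "inferred", "missing")


class MissingJointError(KeyError):
    """A joint needed for an angle computation is missing from a frame."""

    def __init__(self, joint: str, frame_index: int | None = None):
        self.joint = joint
        self.frame_index = frame_index
        where = f" in frame {frame_index}" if frame_index is not None else ""
        super().__init__(f"joint {joint!r} is missing{where}")


def flip_side(joint: str) -> str:
    """Mirror a joint label left<->right; axial joints map to themselves."""
    if joint.endswith("-left"):
        return joint[: -len("-left")] + "-right"
    if joint.endswith("-right"):
        return joint[: -len("-right")] + "-left"
    return joint


@dataclass
class SkeletonFrame:
    """One time-stamped snapshot of all 25 joint positions.

    Parameters
    ----------
    timestamp
        Seconds from the start of the capture, non-negative.
    positions
        Mapping of all 25 joint names to 3-vectors (meters).
    validity
        Per-joint tracking state; defaults to "tracked" everywhere.
        Missing joints must be flagged explicitly -- they are never
        silently zero.
    """

    timestamp: float
    positions: dict[str, np.ndarray]
    validity: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError("timestamp must be non-negative")
        keys = set(self.positions)
        if keys != JOINT_SET:
            missing = JOINT_SET - keys
            extra = keys - JOINT_SET
            raise ValueError(
                f"frame must contain all 25 joints; missing={sorted(missing)}, "
                f"unknown={sorted(extra)}"
            )
        self.positions = {j: np.asarray(p, dtype=float) for j, p in self.positions.items()}
        for j, p in self.positions.items():
            if p.shape != (3,):
                raise ValueError(f"position of {j!r} must be a 3-vector")
        full = {j: "tracked" for j in JOINT_NAMES}
        full.update(self.validity)
        for j, v in full.items():
            if v not in VALID_STATES:
                raise ValueError(f"invalid tracking state {v!r} for joint {j!r}")
        self.validity = full

    def position(self, joint: str) -> np.ndarray:
        """Return the joint position, raising :class:`MissingJointError` if absent."""
        if self.validity[joint] == "missing":
            raise MissingJointError(joint)
        return self.positions[joint]

    def is_missing(self, joint: str) -> bool:
        return self.validity[joint] == "missing"

    def mirrored(self) -> "SkeletonFrame":
        """Left-right mirror: swap sided joints and negate the x coordinate."""
        pos = {}
        val = {}
        for j in JOINT_NAMES:
            src = flip_side(j)
            p = self.positions[src].copy()
            p[0] = -p[0]
            pos[j] = p
            val[j] = self.validity[src]
        return SkeletonFrame(self.timestamp, pos, val)


@dataclass
class SkeletonTrace:
    """A time-ordered sequence of skeleton frames."""

    frames: list[SkeletonFrame]

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a trace needs at least 2 frames")
        ts = np.array([f.timestamp for f in self.frames])
        if not np.all(np.diff(ts) > 0):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def mirrored(self) -> "SkeletonTrace":
        return SkeletonTrace([f.mirrored() for f in self.frames])

    # ---- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "frames": [
                {
                    "t": f.timestamp,
                    "joints": {j: f.positions[j].tolist() for j in JOINT_NAMES},
                    "validity": {
                        j: f.validity[j] for j in JOINT_NAMES if f.validity[j] != "tracked"
                    },
                }
                for f in self.frames
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SkeletonTrace":
        with open(path) as fh:
            payload = json.load(fh)
        frames = []
        for rec in payload["frames"]:
            frames.append(
                SkeletonFrame(
                    timestamp=float(rec["t"]),
                    positions={j: np.asarray(v, dtype=float) for j, v in rec["joints"].items()},
                    validity=dict(rec.get("validity", {})),
                )
            )
        return cls(frames)

    def to_csv(self, path) -> None:
        """Wide CSV: t plus <joint>_x/_y/_z for all 25 joints (NaN = missing)."""
        header = ["t"]
        for j in JOINT_NAMES:
            header += [f"{j}_x", f"{j}_y", f"{j}_z"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for f in self.frames:
                row: list[object] = [f.timestamp]
                for j in JOINT_NAMES:
                    if f.is_missing(j):
                        row += ["nan", "nan", "nan"]
                    else:
                        row += list(f.positions[j])
                w.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "SkeletonTrace":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            cols = set(reader.fieldnames or [])
            needed = {"t"} | {f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"}
            if not needed <= cols:
                raise ValueError(
                    f"skeleton CSV is missing columns: {sorted(needed - cols)[:6]} ..."
                )
            frames = []
            for rec in reader:
                pos = {}
                val = {}
                for j in JOINT_NAMES:
                    p = np.array([float(rec[f"{j}_{ax}"]) for ax in "xyz"])
                    if np.isnan(p).any():
                        p = np.zeros(3)
                        val[j] = "missing"
                    pos[j] = p
                frames.append(SkeletonFrame(float(rec["t"]), pos, val))
        return cls(frames)
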