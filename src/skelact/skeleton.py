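"""Canonical 15-joint skeleton data model and joint-ordering registry.

The depth-sensor SDK reports up to 19 body joints; the recognition
pipeline keeps 15 of them (head, neck, spine, and the shoulder/elbow/wrist
and hip/knee/ankle triples of both sides), numbered 1-15.  Hand and any
other extra joints are discarded because their tracking is unreliable.

Joint *orderings* are permutations of the 15 indices that control the row
order of the encoded action image.  The B-family permutes whole limb
groups (B1 = left arm, right arm, torso, left leg, right leg is the
control); the C-family are fixed fully-random orders used to probe whether
row adjacency of anatomically adjacent joints matters to the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "JOINT_NAMES",
    "JOINT_GROUPS",
    "JointOrdering",
    "SkeletonFrame",
    "SkeletonSequence",
    "select_joints",
    "get_ordering",
    "register_ordering",
    "registered_orderings",
    "validate_sequence",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_skeleton_jsonl",
    "write_skeleton_jsonl",
    "read_kard_file",
]

#: Canonical joint numbering (1-based), matching the color-coded scheme
#: used throughout the image representation.
JOINT_NAMES: dict[int, str] = {
    1: "head",
    2: "neck",
    3: "spine",
    4: "left_shoulder",
    5: "left_elbow",
    6: "left_wrist",
    7: "right_shoulder",
    8: "right_elbow",
    9: "right_wrist",
    10: "left_hip",
    11: "left_knee",
    12: "left_ankle",
    13: "right_hip",
    14: "right_knee",
    15: "right_ankle",
}

NAME_TO_INDEX: dict[str, int] = {v: k for k, v in JOINT_NAMES.items()}

#: Limb/trunk groups: P1 left arm, P2 right arm, P3 torso, P4 left leg,
#: P5 right leg.  The five triples partition {1..15}.
JOINT_GROUPS: dict[str, tuple[int, int, int]] = {
    "P1": (4, 5, 6),
    "P2": (7, 8, 9),
    "P3": (1, 2, 3),
    "P4": (10, 11, 12),
    "P5": (13, 14, 15),
}

N_JOINTS = 15


@dataclass(frozen=True)
class JointOrdering:
    """A named permutation of the 15 joint indices (image row order)."""

    id: str
    sequence: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.sequence) != list(range(1, N_JOINTS + 1)):
            raise ValueError(
                f"ordering {self.id!r} is not a permutation of 1..15: "
                f"{self.sequence}"
            )

    def row_of_joint(self, joint_index: int) -> int:
        """Image row (0-based, top of image) occupied by a joint."""
        return self.sequence.index(joint_index)

    def as_zero_based(self) -> np.ndarray:
        return np.asarray(self.sequence, dtype=np.intp) - 1


def _groups_concat(*group_ids: str) -> tuple[int, ...]:
    seq: list[int] = []
    for g in group_ids:
        seq.extend(JOINT_GROUPS[g])
    return tuple(seq)


# B-configurations: whole-group permutations (B1 is the control).
_B_GROUP_ORDERS = {
    "B1": ("P1", "P2", "P3", "P4", "P5"),
    "B2": ("P1", "P3", "P2", "P4", "P5"),
    "B3": ("P1", "P4", "P3", "P2", "P5"),
    "B4": ("P5", "P2", "P4", "P3", "P1"),
    "B5": ("P3", "P1", "P2", "P4", "P5"),
    "B6": ("P5", "P4", "P3", "P2", "P1"),
}

# C-configurations: fixed fully-random joint orders.
_C_SEQUENCES = {
    "C2": (5, 13, 11, 8, 3, 6, 2, 9, 15, 10, 7, 12, 1, 4, 14),
    "C3": (2, 9, 14, 12, 5, 11, 8, 6, 3, 7, 13, 4, 15, 1, 10),
    "C4": (15, 7, 6, 13, 4, 12, 3, 1, 2, 11, 8, 14, 5, 10, 9),
    "C5": (11, 10, 1, 12, 15, 2, 5, 6, 14, 3, 9, 4, 13, 8, 7),
}

_REGISTRY: dict[str, JointOrdering] = {}
for _id, _gs in _B_GROUP_ORDERS.items():
    _REGISTRY[_id] = JointOrdering(_id, _groups_concat(*_gs))
for _id, _seq in _C_SEQUENCES.items():
    _REGISTRY[_id] = JointOrdering(_id, _seq)


def get_ordering(id: str) -> JointOrdering:
    """Look up a registered joint ordering by label (e.g. ``"B1"``)."""
    try:
        return _REGISTRY[id]
    except KeyError:
        raise KeyError(
            f"unknown ordering {id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def register_ordering(ordering: JointOrdering, *, overwrite: bool = False) -> None:
    """Register a user-defined ordering for use by the encoder and CLI."""
    if ordering.id in _REGISTRY and not overwrite:
        raise ValueError(f"ordering {ordering.id!r} already registered")
    _REGISTRY[ordering.id] = ordering


def registered_orderings() -> list[str]:
    return sorted(_REGISTRY)


@dataclass(frozen=True)
class SkeletonFrame:
    """One frame: 3D position of each of the 15 joints, meters.

    ``coords`` is a (15, 3) float array; row ``i`` is joint index ``i+1``
    in the canonical numbering, columns are x, y, z in the sensor camera
    frame.  Storage order is always canonical; orderings are applied only
    at encoding time.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.coords, dtype=np.float64)
        if arr.shape != (N_JOINTS, 3):
            raise ValueError(f"expected (15, 3) coordinates, got {arr.shape}")
        object.__setattr__(self, "coords", arr)

    def joint(self, index: int) -> np.ndarray:
        """Coordinates of a joint by canonical 1-based index."""
        return self.coords[index - 1]

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.coords).all())


@dataclass
class SkeletonSequence:
    """An ordered sequence of skeleton frames with sample metadata."""

    frames: list[SkeletonFrame]
    sample_id: str = ""
    subject_id: int | None = None
    label: str | None = None
    viewpoint: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack frames into an (N, 15, 3) array."""
        return np.stack([f.coords for f in self.frames])

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        *,
        sample_id: str = "",
        subject_id: int | None = None,
        label: str | None = None,
        viewpoint: str | None = None,
    ) -> "SkeletonSequence":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"expected (N, 15, 3), got {arr.shape}")
        return cls(
            [SkeletonFrame(a) for a in arr],
            sample_id=sample_id,
            subject_id=subject_id,
            label=label,
            viewpoint=viewpoint,
        )

    def window(self, start: int, length: int) -> "SkeletonSequence":
        if start < 0 or start + length > self.n_frames:
            raise ValueError(
                f"window [{start}, {start + length}) out of range for "
                f"{self.n_frames} frames"
            )
        return SkeletonSequence(
            self.frames[start : start + length],
            sample_id=self.sample_id,
            subject_id=self.subject_id,
            label=self.label,
            viewpoint=self.viewpoint,
        )

    def central_window(self, length: int) -> "SkeletonSequence":
        """The centered ``length``-frame window (the encoder's default)."""
        if self.n_frames < length:
            raise ValueError(
                f"sequence has {self.n_frames} frames, need ≥ {length}"
            )
        start = (self.n_frames - length) // 2
        return self.window(start, length)

    def __iter__(self) -> Iterator[SkeletonFrame]:
        return iter(self.frames)


def select_joints(raw: Mapping[str, Sequence[float]]) -> SkeletonFrame:
    """Extract the 15 canonical joints from a (possibly larger) SDK frame.

    ``raw`` maps joint names to (x, y, z).  Any joint whose name is not in
    the canonical keep-list (e.g. the hand joints) is silently discarded;
    a missing required joint or a non-finite coordinate raises.
    """
    coords = np.empty((N_JOINTS, 3), dtype=np.float64)
    for idx in range(1, N_JOINTS + 1):
        name = JOINT_NAMES[idx]
        if name not in raw:
            raise KeyError(f"missing joint {name!r} (index {idx})")
        xyz = np.asarray(raw[name], dtype=np.float64)
        if xyz.shape != (3,):
            raise ValueError(f"joint {name!r}: expected 3 coordinates")
        if not np.isfinite(xyz).all():
            raise ValueError(f"joint {name!r}: non-finite coordinate {xyz}")
        coords[idx - 1] = xyz
    return SkeletonFrame(coords)


def validate_sequence(seq: SkeletonSequence) -> SkeletonSequence:
    """Check frame invariants; return ``seq`` unchanged if valid.

    Raises with the index of the first offending frame.
    """
    if seq.n_frames < 1:
        raise ValueError("N must be ≥ 1 (empty sequence)")
    for i, frame in enumerate(seq.frames):
        if frame.coords.shape != (N_JOINTS, 3):
            raise ValueError(
                f"frame {i}: inconsistent schema {frame.coords.shape}"
            )
        if not frame.is_finite():
            bad = np.argwhere(~np.isfinite(frame.coords))
            j, c = bad[0]
            raise ValueError(
                f"frame {i}: non-finite coordinate at joint "
                f"{JOINT_NAMES[int(j) + 1]!r} axis {'xyz'[int(c)]}"
            )
    return seq


# ---------------------------------------------------------------------------
# On-disk formats (documented in docs/skeleton_formats.md)
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["sample_id", "frame", "joint_index", "joint_name", "x", "y", "z"]


def write_skeleton_csv(
    sequences: Iterable[SkeletonSequence], path: str | Path
) -> None:
    """Write sequences as long-format CSV, one row per frame per joint."""
    rows = []
    for seq in sequences:
        for f, frame in enumerate(seq.frames):
            for j in range(N_JOINTS):
                x, y, z = frame.coords[j]
                rows.append(
                    (seq.sample_id, f, j + 1, JOINT_NAMES[j + 1], x, y, z)
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_skeleton_csv(path: str | Path) -> list[SkeletonSequence]:
    """Read long-format skeleton CSV; sequences ordered by first appearance."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"skeleton CSV missing columns {sorted(missing)}")
    out: list[SkeletonSequence] = []
    for sample_id, g in df.groupby("sample_id", sort=False):
        n = int(g["frame"].max()) + 1
        arr = np.full((n, N_JOINTS, 3), np.nan)
        arr[g["frame"].to_numpy(), g["joint_index"].to_numpy() - 1] = g[
            ["x", "y", "z"]
        ].to_numpy()
        seq = SkeletonSequence.from_array(arr, sample_id=str(sample_id))
        out.append(validate_sequence(seq))
    return out


def write_skeleton_jsonl(
    sequences: Iterable[SkeletonSequence], path: str | Path
) -> None:
    """One JSON object per line: a frame with its sample id and index."""
    with open(path, "w") as fh:
        for seq in sequences:
            for f, frame in enumerate(seq.frames):
                obj = {
                    "sample_id": seq.sample_id,
                    "frame": f,
                    "joints": {
                        JOINT_NAMES[j + 1]: [float(v) for v in frame.coords[j]]
                        for j in range(N_JOINTS)
                    },
                }
                fh.write(json.dumps(obj) + "\n")


def read_skeleton_jsonl(path: str | Path) -> list[SkeletonSequence]:
    frames_by_sample: dict[str, list[tuple[int, SkeletonFrame]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            frame = select_joints(obj["joints"])
            frames_by_sample.setdefault(str(obj["sample_id"]), []).append(
                (int(obj["frame"]), frame)
            )
    out = []
    for sample_id, items in frames_by_sample.items():
        items.sort(key=lambda t: t[0])
        seq = SkeletonSequence(
            [f for _, f in items], sample_id=sample_id
        )
        out.append(validate_sequence(seq))
    return out


#: Joint order used by KARD per-sample real-world coordinate files; hands
#: and feet map onto the canonical wrist and ankle slots.
KARD_JOINT_ORDER: tuple[int, ...] = (
    1,   # head
    2,   # neck
    3,   # torso -> spine
    7,   # right shoulder
    8,   # right elbow
    9,   # right hand -> right wrist
    4,   # left shoulder
    5,   # left elbow
    6,   # left hand -> left wrist
    13,  # right hip
    14,  # right knee
    15,  # right foot -> right ankle
    10,  # left hip
    11,  # left knee
    12,  # left foot -> left ankle
)


def read_kard_file(path: str | Path, *, sample_id: str | None = None) -> SkeletonSequence:
    """Parse one KARD real-world coordinate text file.

    Each frame is 15 whitespace-separated ``x y z`` lines in the KARD
    joint order; the reader maps them onto the canonical 1-15 numbering.
    """
    values = np.loadtxt(path, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != 3 or values.shape[0] % N_JOINTS:
        raise ValueError(
            f"{path}: expected rows of x y z in multiples of 15 joints"
        )
    n = values.shape[0] // N_JOINTS
    raw = values.reshape(n, N_JOINTS, 3)
    arr = np.empty_like(raw)
    for kard_pos, canon_idx in enumerate(KARD_JOINT_ORDER):
        arr[:, canon_idx - 1] = raw[:, kard_pos]
    sid = sample_id if sample_id is not None else Path(path).stem
    return validate_sequence(SkeletonSequence.from_array(arr, sample_id=sid))
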