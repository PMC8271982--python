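"""Kinematic simulator of seated typical and stereotypical behaviors.

Emulates the collection protocol of a clinical skeleton dataset: 32
child-sized subjects, 9 action classes (6 typical actions plus the
stereotypies hand wave/flapping, covering the ears, and body rocking),
each recorded seated from a frontal and two side viewpoints, 3 frontal +
2 side repetitions per class.

Motion is generated on a fixed seated base posture by class-specific
rigid sub-rotations (arms about the shoulder/elbow, trunk about the hip
line, whole upper body about the vertical axis) so that limb segment
lengths are exactly constant within a noiseless sequence.  Trajectories
are hand-designed sinusoids and ramps: the goal is the statistical
structure of the behaviors (periodic limb oscillation, held postures,
whole-body rotation, inter-subject variation), not photorealism.

Determinism: one master seed fans out to per-sample seeds through
``numpy.random.SeedSequence(master, subject, class, repetition)``, so any
individual sample can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .dataset import LabeledDataset
from .skeleton import N_JOINTS, SkeletonSequence, validate_sequence

__all__ = [
    "ActionClass",
    "SubjectParams",
    "CollectionProtocol",
    "VIEWPOINTS",
    "BASE_POSE",
    "sample_subject",
    "generate_action",
    "generate_dataset",
]


class ActionClass(str, Enum):
    """The nine behavior classes (six typical, three stereotypical)."""

    IDLE = "IDLE"
    STANDING = "STANDING"
    CLAP = "CLAP"
    HAND_WAVE = "HAND_WAVE"
    HAND_RAISE = "HAND_RAISE"
    POINTING = "POINTING"
    COVER_EARS = "COVER_EARS"
    TURN = "TURN"
    ROCKING = "ROCKING"


CLASS_NAMES: tuple[str, ...] = tuple(c.value for c in ActionClass)

VIEWPOINTS: tuple[str, ...] = ("front", "left", "right")

#: Nominal sensor frame rate assumed by the trajectory phase (frames/s).
FPS = 30.0

#: Seated base posture, meters, canonical joint order 1..15.  Subject
#: faces +z; +x is the subject's left; +y up; mid-hip at the origin.
BASE_POSE = np.array(
    [
        [0.00, 0.72, 0.00],   # 1 head
        [0.00, 0.58, 0.00],   # 2 neck
        [0.00, 0.38, 0.00],   # 3 spine
        [0.18, 0.54, 0.00],   # 4 left shoulder
        [0.22, 0.30, 0.03],   # 5 left elbow
        [0.24, 0.10, 0.08],   # 6 left wrist
        [-0.18, 0.54, 0.00],  # 7 right shoulder
        [-0.22, 0.30, 0.03],  # 8 right elbow
        [-0.24, 0.10, 0.08],  # 9 right wrist
        [0.10, 0.00, 0.00],   # 10 left hip
        [0.11, -0.04, 0.34],  # 11 left knee
        [0.12, -0.42, 0.38],  # 12 left ankle
        [-0.10, 0.00, 0.00],  # 13 right hip
        [-0.11, -0.04, 0.34], # 14 right knee
        [-0.12, -0.42, 0.38], # 15 right ankle
    ]
)

_UPPER_BODY = np.arange(0, 9)          # joints 1..9 (0-based rows)
_L_ARM, _R_ARM = np.array([4, 5]), np.array([7, 8])  # elbow+wrist rows
_L_WRIST, _R_WRIST = 5, 8
_L_SHOULDER, _R_SHOULDER = 3, 6
_L_ELBOW, _R_ELBOW = 4, 7
_HIP_ROWS = np.array([9, 12])


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject body and motion-style parameters.

    ``scale`` multiplies all bone lengths (child-sized bodies, 0.7-1.1);
    ``posture_offsets`` are constant per-joint 3D offsets (meters) that
    individualize the base pose; ``amplitude``/``frequency`` multiply the
    class trajectory amplitudes and frequencies; ``sigma`` is the
    per-coordinate Gaussian sensor-noise s.d. in meters (≤ 0.02).
    """

    subject_id: int
    scale: float
    posture_offsets: np.ndarray  # (15, 3)
    amplitude: float
    frequency: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.7 <= self.scale <= 1.1):
            raise ValueError(f"scale {self.scale} outside child-sized [0.7, 1.1]")
        if not (0.0 <= self.sigma <= 0.02):
            raise ValueError(f"sigma {self.sigma} outside [0, 0.02] m")


@dataclass(frozen=True)
class CollectionProtocol:
    """The recording protocol: who is recorded, how often, from where."""

    n_subjects: int = 32
    n_frontal: int = 3
    n_side: int = 2  # one left + one right
    n_frames: int = 64
    master_seed: int = 0
    sigma: float = 0.01

    def __post_init__(self) -> None:
        if self.n_frames < 32:
            raise ValueError("samples must span at least one 32-frame window")
        if self.n_side != 2:
            raise ValueError("protocol records exactly one left + one right sample")

    @property
    def samples_per_subject_class(self) -> int:
        return self.n_frontal + self.n_side

    @property
    def total_samples(self) -> int:
        return self.n_subjects * len(CLASS_NAMES) * self.samples_per_subject_class


def _seed_for(master_seed: int, *counters: int) -> np.random.Generator:
    """Counter-based seed fan-out; each (subject, class, rep) is independent."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, *counters)))


def sample_subject(
    subject_id: int, rng_seed: int, *, sigma: float = 0.01
) -> SubjectParams:
    """Draw one subject's parameters, deterministic in (subject_id, seed)."""
    rng = _seed_for(rng_seed, subject_id)
    return SubjectParams(
        subject_id=subject_id,
        scale=float(rng.uniform(0.80, 1.05)),
        posture_offsets=rng.normal(0.0, 0.008, size=(N_JOINTS, 3)),
        amplitude=float(rng.uniform(0.85, 1.15)),
        frequency=float(rng.uniform(0.85, 1.15)),
        sigma=sigma,
    )


# --------------------------------------------------------------------------
# rigid-motion helpers
# --------------------------------------------------------------------------

def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _rotate_about(pose: np.ndarray, rows: np.ndarray | int, pivot: np.ndarray,
                  R: np.ndarray) -> None:
    pose[rows] = (pose[rows] - pivot) @ R.T + pivot


def _ramp(t: float, rise_frames: float) -> float:
    """0→1 smoothstep ramp over ``rise_frames`` frames, then held."""
    u = min(max(t / rise_frames, 0.0), 1.0)
    return u * u * (3.0 - 2.0 * u)


def _nlerp(d0: np.ndarray, d1: np.ndarray, u: float) -> np.ndarray:
    d = (1.0 - u) * d0 + u * d1
    return d / np.linalg.norm(d)


# --------------------------------------------------------------------------
# class trajectories
# --------------------------------------------------------------------------

def _pose_at_frame(
    cls: ActionClass,
    base: np.ndarray,
    t: int,
    amp: float,
    freq: float,
    phase0: float,
) -> np.ndarray:
    """Noiseless pose at frame ``t`` for one action class.

    All motions are rigid sub-rotations (or, for STANDING, constant-length
    limb re-orientation), so within-limb bone lengths are preserved.
    """
    pose = base.copy()
    w = 2.0 * math.pi / FPS  # rad per (Hz · frame)
    mid_hip = 0.5 * (base[9] + base[12])

    if cls is ActionClass.IDLE:
        # slow postural sway of the trunk about the hip line
        theta = 0.02 * amp * math.sin(w * 0.25 * freq * t + phase0)
        _rotate_about(pose, _UPPER_BODY, mid_hip, _rot_x(theta))

    elif cls is ActionClass.ROCKING:
        # stereotypical forward-back rocking of the whole trunk
        theta = 0.30 * amp * math.sin(w * 0.8 * freq * t + phase0)
        _rotate_about(pose, _UPPER_BODY, mid_hip, _rot_x(theta))

    elif cls is ActionClass.TURN:
        # yaw of the upper body about the vertical axis
        theta = 0.80 * amp * math.sin(w * 0.4 * freq * t + phase0)
        _rotate_about(pose, _UPPER_BODY, mid_hip, _rot_y(theta))

    elif cls is ActionClass.HAND_WAVE:
        # hand flapping: raised left arm oscillating laterally, 3-5 Hz
        sh = base[_L_SHOULDER]
        _rotate_about(pose, _L_ARM, sh, _rot_x(1.9 * amp))
        theta = 0.45 * amp * math.sin(w * 4.0 * freq * t + phase0)
        _rotate_about(pose, _L_ARM, sh, _rot_z(theta))
        _rotate_about(pose, _L_WRIST, pose[_L_ELBOW], _rot_z(0.6 * theta))

    elif cls is ActionClass.CLAP:
        # arms raised forward, wrists converging anti-phase at the chest
        osc = abs(math.sin(w * 2.0 * freq * t + phase0))
        for rows, sh_row, sign in (
            (_L_ARM, _L_SHOULDER, +1.0),
            (_R_ARM, _R_SHOULDER, -1.0),
        ):
            sh = base[sh_row]
            _rotate_about(pose, rows, sh, _rot_x(1.5 * amp))
            _rotate_about(pose, rows, sh, _rot_y(sign * 0.55 * amp * osc))

    elif cls is ActionClass.COVER_EARS:
        # both wrists brought to head height and held
        u = _ramp(t, 12.0)
        for rows, wrist, elbow, sh_row, sign in (
            (_L_ARM, _L_WRIST, _L_ELBOW, _L_SHOULDER, +1.0),
            (_R_ARM, _R_WRIST, _R_ELBOW, _R_SHOULDER, -1.0),
        ):
            sh = base[sh_row]
            _rotate_about(pose, rows, sh, _rot_z(sign * 2.3 * amp * u))
            _rotate_about(pose, wrist, pose[elbow], _rot_z(-sign * 1.5 * amp * u))

    elif cls is ActionClass.HAND_RAISE:
        # left arm raised overhead through the front and held
        u = _ramp(t, 12.0)
        sh = base[_L_SHOULDER]
        _rotate_about(pose, _L_ARM, sh, _rot_x(2.8 * amp * u))
        _rotate_about(pose, _L_WRIST, pose[_L_ELBOW], _rot_x(0.4 * amp * u))

    elif cls is ActionClass.POINTING:
        # left arm extended horizontally forward and held
        u = _ramp(t, 12.0)
        sh = base[_L_SHOULDER]
        _rotate_about(pose, _L_ARM, sh, _rot_x(1.5 * amp * u))
        _rotate_about(pose, _L_WRIST, pose[_L_ELBOW], _rot_x(-0.5 * amp * u))

    elif cls is ActionClass.STANDING:
        # seated → upright: hips and trunk rise while legs extend,
        # limb directions re-oriented at constant segment length
        u = _ramp(t, 24.0)
        rise = np.array([0.0, 0.30 * u, 0.0])
        pose[_UPPER_BODY] += rise
        for hip_row, knee_row, ankle_row in ((9, 10, 11), (12, 13, 14)):
            hip0, knee0, ankle0 = base[hip_row], base[knee_row], base[ankle_row]
            lt = np.linalg.norm(knee0 - hip0)
            ls = np.linalg.norm(ankle0 - knee0)
            thigh0 = (knee0 - hip0) / lt
            shank0 = (ankle0 - knee0) / ls
            down = np.array([0.0, -1.0, 0.05])
            down /= np.linalg.norm(down)
            hip = hip0 + rise
            knee = hip + lt * _nlerp(thigh0, down, u)
            ankle = knee + ls * _nlerp(shank0, down, u)
            pose[hip_row], pose[knee_row], pose[ankle_row] = hip, knee, ankle

    else:
        raise ValueError(f"unknown action class {cls!r}")

    return pose


_VIEW_YAW = {"front": 0.0, "left": math.pi / 2.0, "right": -math.pi / 2.0}


def generate_action(
    cls: ActionClass | str,
    subject: SubjectParams,
    viewpoint: str = "front",
    n_frames: int = 64,
    rng_seed: int = 0,
    *,
    sample_id: str = "",
) -> SkeletonSequence:
    """Generate one labeled skeleton sequence for a subject and viewpoint.

    The subject's scaled, offset base pose is animated by the class
    trajectory, rotated to the camera viewpoint (yaw 0/+90/−90° about the
    vertical axis), and Gaussian sensor noise of s.d. ``subject.sigma``
    is added per coordinate.
    """
    cls = ActionClass(cls)
    if n_frames < 32:
        raise ValueError("n_frames must be ≥ 32 (one encoder window)")
    if viewpoint not in _VIEW_YAW:
        raise ValueError(f"viewpoint must be one of {sorted(_VIEW_YAW)}")
    rng = _seed_for(rng_seed)
    phase0 = float(rng.uniform(0.0, 2.0 * math.pi))
    base = subject.scale * BASE_POSE + subject.posture_offsets
    yaw = _rot_y(_VIEW_YAW[viewpoint])
    frames = np.empty((n_frames, N_JOINTS, 3))
    for t in range(n_frames):
        pose = _pose_at_frame(
            cls, base, t, subject.amplitude, subject.frequency, phase0
        )
        frames[t] = pose @ yaw.T
    if subject.sigma > 0:
        frames += rng.normal(0.0, subject.sigma, size=frames.shape)
    seq = SkeletonSequence.from_array(
        frames,
        sample_id=sample_id or f"s{subject.subject_id:02d}_{cls.value}_{viewpoint}",
        subject_id=subject.subject_id,
        label=cls.value,
        viewpoint=viewpoint,
    )
    return validate_sequence(seq)


def generate_dataset(protocol: CollectionProtocol | None = None) -> LabeledDataset:
    """Generate the full protocol: one sample per (subject, class, repetition).

    The default protocol (32 subjects × 9 classes × (3 frontal + 2 side))
    yields 1440 samples, 160 per class.  Deterministic in the master seed.
    """
    protocol = protocol or CollectionProtocol()
    reps: list[tuple[str, int]] = [
        ("front", r) for r in range(protocol.n_frontal)
    ] + [("left", 0), ("right", 0)]
    samples: list[SkeletonSequence] = []
    for sid in range(1, protocol.n_subjects + 1):
        subject = sample_subject(
            sid, protocol.master_seed, sigma=protocol.sigma
        )
        for ci, cls in enumerate(ActionClass):
            for ri, (view, rep) in enumerate(reps):
                seed_rng = np.random.SeedSequence(
                    (protocol.master_seed, sid, ci, ri)
                )
                sample_seed = int(seed_rng.generate_state(1)[0] % (2**31))
                samples.append(
                    generate_action(
                        cls,
                        subject,
                        viewpoint=view,
                        n_frames=protocol.n_frames,
                        rng_seed=sample_seed,
                        sample_id=(
                            f"s{sid:02d}_{cls.value}_{view}{rep}"
                        ),
                    )
                )
    return LabeledDataset(samples, CLASS_NAMES)
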