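"""Joint-coordinate → RGB action-image encoding.

A 32-frame skeleton sequence is mapped to a 15 (joints) × 32 (frames) × 3
(x→R, y→G, z→B) 8-bit image.  Each axis c ∈ {x, y, z} is min-max
normalized to 0-255 over all joints and frames of the sequence:

    k' = 255 · (k − min_c) / (max_c − min_c)

Per-axis pooling makes the encoding invariant to translating the whole
skeleton and to positively rescaling any axis, so a model trained on one
body size and sensor placement transfers to another.  Values are rounded
half-up to integers so encodings are bit-reproducible and exportable as
lossless PNG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from PIL import Image

from .skeleton import JointOrdering, SkeletonSequence, validate_sequence

__all__ = [
    "WINDOW_LENGTH",
    "ActionImage",
    "NormalizationStats",
    "normalize_coordinate",
    "encode_sequence",
    "sliding_windows",
]

logger = logging.getLogger(__name__)

#: Frames per encoded image — one to two seconds of movement at the
#: sensor's frame rate.
WINDOW_LENGTH = 32


@dataclass(frozen=True)
class NormalizationStats:
    """Per-axis min/max pooled over all joints and frames of one sequence."""

    cmin: np.ndarray  # (3,) per-axis minimum
    cmax: np.ndarray  # (3,) per-axis maximum

    @classmethod
    def from_sequence(cls, seq: SkeletonSequence) -> "NormalizationStats":
        arr = seq.as_array()  # (N, 15, 3)
        return cls(arr.min(axis=(0, 1)), arr.max(axis=(0, 1)))


@dataclass
class ActionImage:
    """Encoded action image: (15, 32, 3) uint8, rows ordered by ``ordering_id``.

    Row 0 is the first joint of the applied ordering (top of the image),
    column 0 the earliest frame (left edge); channels are R←x, G←y, B←z.
    """

    pixels: np.ndarray
    ordering_id: str
    sample_id: str = ""
    label: str | None = None
    subject_id: int | None = None
    viewpoint: str | None = None
    window_start: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {arr.dtype}")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def to_float(self) -> np.ndarray:
        """Network-boundary scaling: uint8 image / 255."""
        return self.pixels.astype(np.float32) / 255.0

    # -- PNG + JSON sidecar -------------------------------------------------

    def save_png(self, path: str | Path) -> None:
        """Write a lossless 8-bit RGB PNG plus a ``.json`` sidecar."""
        path = Path(path)
        Image.fromarray(self.pixels, mode="RGB").save(path, format="PNG")
        sidecar = {
            "ordering_id": self.ordering_id,
            "sample_id": self.sample_id,
            "label": self.label,
            "subject_id": self.subject_id,
            "viewpoint": self.viewpoint,
            "window_start": self.window_start,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load_png(cls, path: str | Path) -> "ActionImage":
        path = Path(path)
        pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = {}
        if sidecar_path.exists():
            meta = json.loads(sidecar_path.read_text())
        return cls(
            pixels=pixels,
            ordering_id=meta.get("ordering_id", "unknown"),
            sample_id=meta.get("sample_id", ""),
            label=meta.get("label"),
            subject_id=meta.get("subject_id"),
            viewpoint=meta.get("viewpoint"),
            window_start=meta.get("window_start", 0),
        )


def normalize_coordinate(k: float, cmin: float, cmax: float) -> float:
    """Min-max normalize one coordinate into [0, 255] (continuous).

    Degenerate range (``cmax == cmin``) maps to 0 so constant-depth
    streams keep flowing rather than failing.
    """
    if not (np.isfinite(k) and np.isfinite(cmin) and np.isfinite(cmax)):
        raise ValueError("non-finite input to normalization")
    if cmax < cmin:
        raise ValueError(f"cmax {cmax} < cmin {cmin}")
    if cmax == cmin:
        return 0.0
    return 255.0 * (k - cmin) / (cmax - cmin)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; the image quantization contract is
    # half-up so e.g. 127.5 -> 128.
    return np.floor(x + 0.5)


def encode_sequence(
    seq: SkeletonSequence,
    ordering: JointOrdering,
    *,
    _expected_frames: int | None = WINDOW_LENGTH,
) -> ActionImage:
    """Encode a 32-frame sequence into an action image under ``ordering``.

    ``_expected_frames`` exists so tests can exercise toy sizes; callers
    with longer streams should cut windows with :func:`sliding_windows`
    or ``SkeletonSequence.central_window`` first.
    """
    validate_sequence(seq)
    if _expected_frames is not None and seq.n_frames != _expected_frames:
        raise ValueError(
            f"sequence has {seq.n_frames} frames, encoder expects "
            f"{_expected_frames}; cut windows with sliding_windows() or "
            "central_window() first"
        )
    arr = seq.as_array()  # (N, J, 3)
    cmin = arr.min(axis=(0, 1))
    cmax = arr.max(axis=(0, 1))
    span = cmax - cmin
    degenerate = span == 0
    if degenerate.any():
        axes = "".join(a for a, d in zip("xyz", degenerate) if d)
        logger.warning(
            "degenerate coordinate range on axis %s; channel set to 0", axes
        )
    safe_span = np.where(degenerate, 1.0, span)
    norm = 255.0 * (arr - cmin) / safe_span
    norm[:, :, degenerate] = 0.0
    # rows = joints in ordering sequence, cols = frames
    order = ordering.as_zero_based()
    pixels = _round_half_up(norm).astype(np.uint8)[:, order, :]
    pixels = pixels.transpose(1, 0, 2)  # (J, N, 3)
    return ActionImage(
        pixels=pixels,
        ordering_id=ordering.id,
        sample_id=seq.sample_id,
        label=seq.label,
        subject_id=seq.subject_id,
        viewpoint=seq.viewpoint,
    )


def sliding_windows(
    stream: SkeletonSequence, length: int = WINDOW_LENGTH, stride: int = 1
) -> list[SkeletonSequence]:
    """Cut a stream into fixed-length windows at a fixed stride.

    Windows start at frames 0, stride, 2·stride, …; a stream shorter than
    ``length`` yields an empty list (logged, not an error), which is the
    natural behavior for a live feed that has just started.
    """
    if length < 1:
        raise ValueError("length must be ≥ 1")
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    n = stream.n_frames
    if n < length:
        logger.info(
            "stream of %d frames shorter than window %d; no windows", n, length
        )
        return []
    return [stream.window(s, length) for s in range(0, n - length + 1, stride)]
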