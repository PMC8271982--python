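"""Labeled sample collections shared by the generator, encoder and trainer."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .encoding import WINDOW_LENGTH, ActionImage, encode_sequence
from .skeleton import JointOrdering, SkeletonSequence, write_skeleton_csv

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """Skeleton sequences (or pre-encoded images) with labels and subjects.

    Every sample carries a class label, a subject id and a viewpoint so
    the collection supports leak-free cross-subject splitting.
    """

    samples: list[SkeletonSequence | ActionImage]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        vocab = set(self.classes)
        for s in self.samples:
            if s.label not in vocab:
                raise ValueError(
                    f"sample {s.sample_id!r} has label {s.label!r} "
                    f"outside vocabulary {sorted(vocab)}"
                )
            if s.subject_id is None:
                raise ValueError(f"sample {s.sample_id!r} has no subject id")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SkeletonSequence | ActionImage]:
        return iter(self.samples)

    @property
    def subjects(self) -> list[int]:
        """Distinct subject ids, sorted."""
        return sorted({s.subject_id for s in self.samples})

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(s.label for s in self.samples))

    def subset_by_subjects(self, subjects: Iterable[int]) -> "LabeledDataset":
        keep = set(subjects)
        return LabeledDataset(
            [s for s in self.samples if s.subject_id in keep], self.classes
        )

    def encode(
        self,
        ordering: JointOrdering,
        *,
        window: str = "center",
    ) -> "LabeledDataset":
        """Encode every sequence into an action image under ``ordering``.

        ``window="center"`` takes the central 32-frame window of each
        sequence (samples are recorded longer than one window so the
        action core is mid-recording); sequences of exactly 32 frames are
        encoded as-is.
        """
        if window != "center":
            raise ValueError("only the central window policy is implemented")
        images: list[ActionImage] = []
        for s in self.samples:
            if isinstance(s, ActionImage):
                images.append(s)
                continue
            images.append(encode_sequence(s.central_window(WINDOW_LENGTH), ordering))
        return LabeledDataset(images, self.classes)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack encoded images into (n, 15, 32, 3) uint8 X and int label y."""
        if not all(isinstance(s, ActionImage) for s in self.samples):
            raise TypeError("dataset holds raw sequences; call encode() first")
        X = np.stack([s.pixels for s in self.samples])
        label_to_idx = {c: i for i, c in enumerate(self.classes)}
        y = np.array([label_to_idx[s.label] for s in self.samples], dtype=np.int64)
        return X, y

    @property
    def ordering_id(self) -> str | None:
        ids = {s.ordering_id for s in self.samples if isinstance(s, ActionImage)}
        if len(ids) > 1:
            raise ValueError(f"mixed ordering ids in dataset: {sorted(ids)}")
        return next(iter(ids)) if ids else None

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "subject": [s.subject_id for s in self.samples],
                "class": [s.label for s in self.samples],
                "viewpoint": [s.viewpoint for s in self.samples],
            }
        )

    def save(self, directory: str | Path) -> None:
        """Write skeleton CSV + manifest CSV under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        seqs = [s for s in self.samples if isinstance(s, SkeletonSequence)]
        write_skeleton_csv(seqs, directory / "skeletons.csv")
        self.manifest().to_csv(directory / "manifest.csv", index=False)
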