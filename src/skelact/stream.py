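"""Simulated real-time classification of a skeleton stream.

A long sequence is cut into fixed-length sliding windows; each window is
encoded with the model's own joint ordering and classified, emitting one
decision per window in temporal order.  Per-window latency can be logged
for information, but no throughput figure is asserted anywhere — timing
is hardware-dependent.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .encoding import WINDOW_LENGTH, encode_sequence, sliding_windows
from .skeleton import SkeletonSequence, get_ordering

__all__ = ["StreamDecision", "classify_stream"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StreamDecision:
    """One classification decision for one stream window."""

    window_start: int
    label: str
    score: float
    probabilities: np.ndarray


def classify_stream(
    stream: SkeletonSequence,
    results,
    window: int = WINDOW_LENGTH,
    stride: int = 1,
    *,
    log_latency: bool = False,
) -> list[StreamDecision]:
    """Classify every sliding window of ``stream`` with a fitted model.

    Returns an empty list (logged) for streams shorter than one window.
    """
    ordering = get_ordering(results.ordering_id)
    decisions: list[StreamDecision] = []
    for i, win in enumerate(sliding_windows(stream, window, stride)):
        t0 = time.perf_counter()
        image = encode_sequence(win, ordering)
        probs, label, score = results.predict(image)
        if log_latency:
            logger.info(
                "window %d: %s (%.2f) in %.1f ms",
                i * stride, label, score, 1e3 * (time.perf_counter() - t0),
            )
        decisions.append(
            StreamDecision(
                window_start=i * stride,
                label=label,
                score=score,
                probabilities=probs,
            )
        )
    if not decisions:
        logger.info(
            "stream of %d frames yields no %d-frame windows",
            stream.n_frames, window,
        )
    return decisions
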