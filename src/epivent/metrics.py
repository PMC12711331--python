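"""Detector validation against a programmed ground truth.

Point events (breaths, apneas, sighs, R-peaks) are matched greedily one-to-one
within a time tolerance; interval events (seizures) are matched by temporal
intersection-over-union.  Sensitivity = matched true events / true events;
precision = matched detections / detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Interval

__all__ = ["Recovery", "match_point_events", "interval_iou", "match_intervals"]


@dataclass
class Recovery:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")


def match_point_events(
    true_times: Sequence[float], detected_times: Sequence[float], tol_s: float
) -> Recovery:
    """Greedy one-to-one nearest matching within ``tol_s``."""
    true_left = sorted(true_times)
    matched = 0
    for d in sorted(detected_times):
        if not true_left:
            break
        diffs = [abs(d - t) for t in true_left]
        k = int(np.argmin(diffs))
        if diffs[k] <= tol_s:
            true_left.pop(k)
            matched += 1
    return Recovery(len(true_times), len(detected_times), matched)


def interval_iou(a: Interval, b: Interval) -> float:
    inter = max(0.0, min(a.end, b.end) - max(a.start, b.start))
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union if union > 0 else 0.0


def match_intervals(
    true_iv: Sequence[Interval], detected_iv: Sequence[Interval], min_iou: float = 0.8
) -> Recovery:
    """Greedy one-to-one interval matching at ``iou >= min_iou``."""
    true_left = list(true_iv)
    matched = 0
    for d in detected_iv:
        if not true_left:
            break
        ious = [interval_iou(d, t) for t in true_left]
        k = int(np.argmax(ious))
        if ious[k] >= min_iou:
            true_left.pop(k)
            matched += 1
    return Recovery(len(true_iv), len(detected_iv), matched)
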