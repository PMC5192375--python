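"""Scoring detections against reference annotations.

Detections and references are matched one-to-one within a time tolerance;
the match counts give sensitivity SE = TP/(TP+FN), positive predictivity
+P = TP/(TP+FP) and the overall accuracy J = (SE + +P)/2.  A zero
denominator yields NaN for that statistic, the convention used to flag a
detector that produced no blocks of interest at all ("non-coupling").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AnnotationSet", "EvalResult", "match_events", "score"]

#: Default matching tolerance in milliseconds.  The tolerance is not part
#: of the method itself and must be recorded with every result; ±75 ms is
#: the long-standing beat-detection convention for QRS-scale events.
DEFAULT_TOLERANCE_MS = 75.0


@dataclass(frozen=True)
class AnnotationSet:
    """Reference event locations for one record."""

    events: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        events = np.asarray(self.events, dtype=int)
        if events.size and (np.any(np.diff(events) <= 0) or events[0] < 0):
            raise ValueError("annotation events must be strictly increasing and non-negative")
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return self.events.size


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    se: float
    pp: float
    j: float
    tolerance_ms: float


def match_events(
    detected: np.ndarray,
    reference: AnnotationSet,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to reference events.

    References are walked in increasing time; each is matched to the
    nearest unmatched detection within ``±tolerance_ms``, ties breaking to
    the earlier detection.  Unmatched detections count as false positives,
    unmatched references as false negatives, so ``tp + fn == len(reference)``
    and ``tp + fp == len(detected)`` always hold.

    Returns ``(tp, fp, fn, pairs)`` where ``pairs`` lists matched
    ``(detected_index, reference_index)`` sample pairs.
    """
    if not (tolerance_ms > 0):
        raise ValueError(f"tolerance_ms must be > 0, got {tolerance_ms}")
    detected = np.asarray(detected, dtype=int)
    if detected.size and np.any(np.diff(detected) < 0):
        raise ValueError("detected indices must be sorted")
    tol_samples = tolerance_ms * reference.fs / 1000.0

    taken = np.zeros(detected.size, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for ref in reference.events:
        best = -1
        best_dist = tol_samples
        for i in np.flatnonzero(~taken):
            dist = abs(int(detected[i]) - int(ref))
            if dist < best_dist or (dist == best_dist and best == -1):
                best, best_dist = i, dist
        if best >= 0:
            taken[best] = True
            pairs.append((int(detected[best]), int(ref)))
    tp = len(pairs)
    fp = detected.size - tp
    fn = len(reference) - tp
    return tp, fp, fn, pairs


def score(
    detected: np.ndarray,
    reference: AnnotationSet,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> EvalResult:
    """Match and compute SE, +P and J for one record."""
    tp, fp, fn, _ = match_events(detected, reference, tolerance_ms)
    return result_from_counts(tp, fp, fn, tolerance_ms)


def result_from_counts(tp: int, fp: int, fn: int, tolerance_ms: float) -> EvalResult:
    """Build an EvalResult from pooled TP/FP/FN counts."""
    se = tp / (tp + fn) if tp + fn > 0 else math.nan
    pp = tp / (tp + fp) if tp + fp > 0 else math.nan
    j = (se + pp) / 2.0
    return EvalResult(tp=tp, fp=fp, fn=fn, se=se, pp=pp, j=j, tolerance_ms=tolerance_ms)
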