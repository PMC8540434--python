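"""Detection scoring against ground-truth beat positions.

A truth beat counts as detected (true positive) when the detector placed
a peak within a tolerance window around the annotated first-peak index —
±3 samples by default, about 0.6 ms at 5 kHz.  Matching is greedy and
one-to-one, so a single detection can never satisfy two truth beats.
Sensitivity and accuracy coincide under this protocol (only TP and FN
are defined, TB = TP + FN) and percentages are *truncated* to one
decimal, not rounded: 186/187 = 99.465% reports as 99.4.  Detections
matching no truth beat are counted separately as false positives and do
not enter Se/Ac.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "DetectionScore",
    "match_events",
    "score",
    "count_false_positives",
    "truncate_percent",
]

DEFAULT_TOLERANCE_SAMPLES = 3


@dataclass(frozen=True)
class DetectionScore:
    """Per-class beat-detection counts and rates."""

    TB: int
    TP: int
    FN: int
    Se: float
    Ac: float

    def __post_init__(self) -> None:
        if self.TB != self.TP + self.FN:
            raise ValueError("TB must equal TP + FN")


def truncate_percent(tp: int, tb: int) -> float:
    """``TP/TB`` as a percentage truncated (not rounded) to one decimal."""
    if tb <= 0:
        return float("nan")
    return (tp * 1000 // tb) / 10.0


def match_events(
    truth: Sequence[int],
    detected: Sequence[int],
    tol: int = DEFAULT_TOLERANCE_SAMPLES,
) -> List[bool]:
    """Greedy one-to-one matching of truth peaks to detections.

    Both sequences must be sorted.  Each truth peak, in index order,
    claims the earliest unused detection within ``±tol`` samples; the
    returned flags align with ``truth``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    truth = np.asarray(truth)
    detected = np.asarray(detected)
    used = np.zeros(detected.size, dtype=bool)
    flags: List[bool] = []
    start = 0
    for t in truth:
        hit = False
        # skip detections that are permanently too early
        while start < detected.size and (
            used[start] or detected[start] < t - tol
        ):
            start += 1
        j = start
        while j < detected.size and detected[j] <= t + tol:
            if not used[j]:
                used[j] = True
                hit = True
                break
            j += 1
        flags.append(hit)
    return flags


def count_false_positives(
    truth: Sequence[int],
    detected: Sequence[int],
    tol: int = DEFAULT_TOLERANCE_SAMPLES,
) -> int:
    """Detections left unmatched by the greedy one-to-one rule."""
    flags = match_events(truth, detected, tol)
    return len(detected) - sum(flags)


def score(
    matches: Sequence[bool], labels: Sequence[str]
) -> Tuple[DetectionScore, DetectionScore]:
    """Split match flags by beat class into (normal, ectopic) scores."""
    if len(matches) != len(labels):
        raise ValueError(
            f"matches ({len(matches)}) and labels ({len(labels)}) misaligned"
        )
    out = []
    for cls in ("normal", "ectopic"):
        tp = sum(1 for m, lab in zip(matches, labels) if lab == cls and m)
        fn = sum(1 for m, lab in zip(matches, labels) if lab == cls and not m)
        pct = truncate_percent(tp, tp + fn)
        out.append(DetectionScore(TB=tp + fn, TP=tp, FN=fn, Se=pct, Ac=pct))
    return out[0], out[1]
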