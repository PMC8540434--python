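"""Inter-beat-interval analysis, ectopic flagging, and dual-channel
pairing into transit times.

An ectopic beat (PAC or PVC) perturbs the beat-to-beat timing: a
premature beat terminates an abnormally short interval, and is usually
followed by a compensatory pause.  Flagging therefore compares every
interval against a reference — the median by default, since the median
is robust to the very intervals being flagged; ``reference="mean"``
reproduces the plain-average reading.  The beat that *terminates* an
out-of-band interval is the one labelled ectopic.

Two sensors a known distance apart see the same pulse with a phase
shift; pairing each proximal first peak with the next distal first peak
gives the pulse transit time (PTT), and the sensor distance divided by
the PTT the pulse wave velocity (PWV).  PTT resolution is one sample
(0.2 ms at 5 kHz) — peaks are integer sample indices and no sub-sample
interpolation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

__all__ = [
    "BeatPair",
    "EctopicPolicy",
    "intervals_from_peaks",
    "flag_ectopic",
    "pair_peaks",
    "pwv_from_ptt",
    "default_max_lag_s",
]

DEFAULT_SENSOR_DISTANCE_M = 0.025  # 2.5 cm sensor spacing


@dataclass(frozen=True)
class BeatPair:
    """Matched proximal/distal first peaks of one pulse wave."""

    proximal_peak: int
    distal_peak: int
    ptt_s: float
    pwv_m_s: float

    def __post_init__(self) -> None:
        if self.distal_peak <= self.proximal_peak:
            raise ValueError("distal peak must come after the proximal peak")
        if not self.ptt_s > 0:
            raise ValueError("ptt_s must be > 0")


@dataclass(frozen=True)
class EctopicPolicy:
    """Interval-based ectopic flagging rule.

    A beat is ectopic when its terminating interval deviates from the
    reference by more than ``relative_tolerance`` (fractional).
    """

    relative_tolerance: float = 0.25
    reference: str = "median"

    def __post_init__(self) -> None:
        if not 0 < self.relative_tolerance < 1:
            raise ValueError("relative_tolerance must be in (0, 1)")
        if self.reference not in ("median", "mean"):
            raise ValueError(f"unknown reference {self.reference!r}")


def intervals_from_peaks(
    peaks: Sequence[int], rate: float
) -> np.ndarray:
    """Successive peak-to-peak time differences in seconds."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak indices must be strictly increasing")
    return np.diff(peaks) / rate


def flag_ectopic(
    intervals: Sequence[float], policy: EctopicPolicy = EctopicPolicy()
) -> List[str]:
    """Label each beat normal/ectopic from its terminating interval.

    For ``n`` intervals there are ``n + 1`` beats.  Beat ``i`` (``i >= 1``)
    is tested against interval ``i - 1``; the first beat, which terminates
    no interval, inherits the test of the interval that follows it.
    Labels are invariant under rescaling all intervals, since the rule is
    relative.
    """
    intervals = np.asarray(intervals, dtype=np.float64)
    if intervals.size < 3:
        raise ValueError("need at least 3 intervals to flag ectopic beats")
    ref = (
        float(np.median(intervals))
        if policy.reference == "median"
        else float(np.mean(intervals))
    )
    tol = policy.relative_tolerance
    out_of_band = (intervals < (1 - tol) * ref) | (intervals > (1 + tol) * ref)
    labels = ["ectopic" if bad else "normal" for bad in out_of_band]
    return [labels[0]] + labels


def default_max_lag_s(proximal_peaks: Sequence[int], rate: float) -> float:
    """Default pairing lag: half the median inter-beat interval."""
    return 0.5 * float(np.median(intervals_from_peaks(proximal_peaks, rate)))


def pair_peaks(
    proximal: Sequence[int],
    distal: Sequence[int],
    rate: float,
    max_lag_s: float,
    sensor_distance_m: float = DEFAULT_SENSOR_DISTANCE_M,
) -> List[BeatPair]:
    """Greedy forward matching of proximal to distal peaks.

    Each proximal peak pairs with the earliest unused distal peak strictly
    after it and within ``max_lag_s``; unmatched peaks on either side are
    dropped.  Empty inputs yield an empty list.
    """
    if not max_lag_s > 0:
        raise ValueError("max_lag_s must be > 0")
    prox = np.asarray(proximal)
    dist = np.asarray(distal)
    max_lag = max_lag_s * rate
    pairs: List[BeatPair] = []
    j = 0
    for p in prox:
        while j < dist.size and dist[j] <= p:
            j += 1
        if j == dist.size:
            break
        if dist[j] - p <= max_lag:
            ptt = (int(dist[j]) - int(p)) / rate
            pairs.append(
                BeatPair(
                    proximal_peak=int(p),
                    distal_peak=int(dist[j]),
                    ptt_s=ptt,
                    pwv_m_s=pwv_from_ptt(ptt, sensor_distance_m),
                )
            )
            j += 1
    return pairs


def pwv_from_ptt(ptt_s: float, distance_m: float) -> float:
    """Pulse wave velocity: sensor distance over transit time (m/s)."""
    if not ptt_s > 0:
        raise ValueError("ptt_s must be > 0 (non-positive PTT signals mis-pairing)")
    if not distance_m > 0:
        raise ValueError("distance_m must be > 0")
    return distance_m / ptt_s
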