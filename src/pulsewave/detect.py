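"""Dynamic-threshold computation and hysteresis peak/trough detection.

The detector tracks a running local maximum while the signal rises and a
running local minimum while it falls.  A peak is only confirmed once the
signal has dropped a threshold (the *gradient*) below the local maximum;
a trough once it has risen the gradient above the local minimum.  The
gradient adapts to the signal: over a trailing window it is

    gradient = RMS * CV / 100 * gain

where CV is the population variance of the window (the printed formula;
units mV^2 — see ``ThresholdParams.cv_mode``), RMS its root mean square,
and ``gain`` a user dial (default 1).  The division by 100 absorbs the
amplitude scale.  Because the threshold follows signal strength, the same
settings work across subjects with different pulse amplitudes, and a beat
whose first peak is attenuated (e.g. a PVC) is still confirmed provided
its excursion exceeds the current gradient.

The window defaults to half the sampling rate (0.5 s), recomputed every
sample over the trailing window; during warm-up (the first window) the
window simply grows from the first sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .trace import DetectionEvent, SignalTrace

__all__ = [
    "ThresholdParams",
    "window_mean",
    "window_cv",
    "window_rms",
    "dynamic_gradient",
    "gradient_series",
    "detect_events",
    "peak_indices",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Dynamic-threshold settings.

    Parameters
    ----------
    window_samples
        Trailing window length; ``None`` means half the sampling rate.
    gain
        Linear scale on the gradient.
    cv_mode
        ``"variance"`` uses the population variance exactly as printed;
        ``"std"`` uses its square root (coefficient-of-variation reading).
    update
        ``"sliding"`` recomputes the gradient each sample; ``"block"``
        recomputes once per window and holds it constant.
    """

    window_samples: Optional[int] = None
    gain: float = 1.0
    cv_mode: str = "variance"
    update: str = "sliding"

    def __post_init__(self) -> None:
        if self.window_samples is not None and self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if not self.gain > 0:
            raise ValueError("gain must be > 0")
        if self.cv_mode not in ("variance", "std"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")
        if self.update not in ("sliding", "block"):
            raise ValueError(f"unknown update {self.update!r}")

    def resolve_window(self, sample_rate_hz: float) -> int:
        if self.window_samples is not None:
            return self.window_samples
        return max(2, int(round(sample_rate_hz / 2)))


def window_mean(values: Sequence[float]) -> float:
    """Arithmetic mean of a window."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("window is empty")
    return float(values.mean())


def window_cv(values: Sequence[float]) -> float:
    """Amplitude variability of a window: ``sum((x - mean)^2)/N``.

    This is the population variance (units mV^2), implemented literally.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("window is empty")
    return float(np.mean((values - values.mean()) ** 2))


def window_rms(values: Sequence[float]) -> float:
    """Root mean square ``sqrt(sum(x^2)/N)`` of a window."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("window is empty")
    return float(np.sqrt(np.mean(values**2)))


def dynamic_gradient(values: Sequence[float], params: ThresholdParams) -> float:
    """Threshold ``RMS * CV / 100 * gain`` over one window (mV)."""
    cv = window_cv(values)
    if params.cv_mode == "std":
        cv = float(np.sqrt(cv))
    return window_rms(values) * cv / 100.0 * params.gain


def gradient_series(trace: SignalTrace, params: ThresholdParams) -> np.ndarray:
    """Per-sample gradient over the trailing window.

    Computed with cumulative sums so a full record is O(n); agrees with
    :func:`dynamic_gradient` applied window-by-window to rounding error.
    During warm-up (the first window) the window grows from sample 0.
    """
    x = trace.samples
    w = params.resolve_window(trace.sample_rate_hz)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(x.size)
    lo = np.maximum(0, i - w + 1)
    n = (i - lo + 1).astype(np.float64)
    s1 = c1[i + 1] - c1[lo]
    s2 = c2[i + 1] - c2[lo]
    mean = s1 / n
    cv = np.maximum(s2 / n - mean * mean, 0.0)  # clamp float cancellation
    rms = np.sqrt(s2 / n)
    if params.cv_mode == "std":
        cv = np.sqrt(cv)
    g = rms * cv / 100.0 * params.gain
    if params.update == "block":
        # hold the value computed at each window boundary
        edges = np.arange(w - 1, x.size, w)
        held = np.empty_like(g)
        held[: w - 1] = g[: w - 1]  # growing-window warm-up
        for k, e in enumerate(edges):
            stop = edges[k + 1] if k + 1 < len(edges) else x.size
            held[e:stop] = g[e]
        g = held
    return g


def detect_events(
    trace: SignalTrace, params: ThresholdParams
) -> List[DetectionEvent]:
    """Run the hysteresis state machine over a trace.

    Emits, in index order: ``rise_onset`` (signal has climbed the gradient
    above the local minimum), ``peak`` (at the preceding local maximum,
    emitted once the signal falls the gradient below it), ``fall_onset``
    (the sample that confirmed the peak), and ``trough`` (at the preceding
    local minimum).  Ties on plateaus resolve to the first sample.

    The machine starts undecided, tracking both extrema from sample 0;
    whichever hysteresis condition triggers first decides the initial
    phase, and the corresponding onset is back-filled at index 0 so that
    every peak is preceded by a rise onset and every trough by a fall
    onset.
    """
    x = trace.samples
    w = params.resolve_window(trace.sample_rate_hz)
    if x.size < w:
        raise ValueError(
            f"trace length {x.size} shorter than threshold window {w}"
        )
    g = gradient_series(trace, params)
    events: List[DetectionEvent] = []
    mode = 0  # 0 undecided, +1 rising, -1 falling
    mx = mi = x[0]
    mxi = mii = 0
    for i in range(1, x.size):
        v = x[i]
        if mode >= 0 and v > mx:
            mx = v
            mxi = i
        if mode <= 0 and v < mi:
            mi = v
            mii = i
        if mode >= 0 and v < mx - g[i]:
            if mode == 0:
                events.append(DetectionEvent("rise_onset", 0, x[0]))
            events.append(DetectionEvent("peak", mxi, mx))
            events.append(DetectionEvent("fall_onset", i, v))
            mode = -1
            mi, mii = v, i
        elif mode <= 0 and v > mi + g[i]:
            if mode == 0:
                events.append(DetectionEvent("fall_onset", 0, x[0]))
            events.append(DetectionEvent("trough", mii, mi))
            events.append(DetectionEvent("rise_onset", i, v))
            mode = 1
            mx, mxi = v, i
    return events


def peak_indices(events: Sequence[DetectionEvent]) -> np.ndarray:
    """Sample indices of ``peak`` events, in order."""
    return np.array([e.index for e in events if e.kind == "peak"], dtype=np.int64)
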