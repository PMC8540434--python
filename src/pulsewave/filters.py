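"""Kaiser-window FIR band-pass design and application.

The band-pass is built the classical way: an ideal (sinc) band-pass
impulse response truncated to ``N + 1`` taps and shaped by a Kaiser
window, whose parameter ``beta`` trades main-lobe width against side-lobe
level.  The zeroth-order modified Bessel function of the first kind that
defines the window is implemented here as its power series — it is part
of the design chain, and is cross-checked against library evaluations in
the test suite.

Digital cut-offs are normalized as ``omega = 2*pi*f_c / sample_rate_hz``
(radians per sample), the only reading under which the requested corner
frequencies land where stated.

A note on sizing: the transition bandwidth of a Kaiser design is roughly
``(beta + pi) * sample_rate_hz / (pi * N)``.  At 5 kHz a 128-tap filter
therefore has an ~80 Hz transition band and cannot resolve a 0.7–9.5 Hz
passband — its response is a shallow wide-band low-pass with ~0.22 gain.
:func:`minimum_taps` gives the tap count at which the requested band is
actually realized; the analysis pipeline defaults to a resolved design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .trace import SignalTrace

__all__ = [
    "FirSpec",
    "bessel_i0",
    "kaiser_window",
    "ideal_bandpass",
    "design_fir",
    "apply_fir",
    "frequency_response",
    "minimum_taps",
]


@dataclass(frozen=True)
class FirSpec:
    """Band-pass design parameters.

    Defaults are the acquisition-chain values: 0.7–9.5 Hz band, 128-tap
    window, 5 kHz sampling.  ``beta = 6`` (~ -63 dB side lobes) is a
    common design point; the band properties are insensitive to it over
    beta in [4, 9].
    """

    f_c1: float = 0.7
    f_c2: float = 9.5
    N: int = 128
    beta: float = 6.0
    sample_rate_hz: float = 5000.0

    def __post_init__(self) -> None:
        if not 0 < self.f_c1 < self.f_c2 < self.sample_rate_hz / 2:
            raise ValueError(
                "cut-offs must satisfy 0 < f_c1 < f_c2 < sample_rate_hz/2"
            )
        if self.N < 2 or self.N % 2 != 0:
            raise ValueError("N must be even and >= 2")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def group_delay_samples(self) -> int:
        """Delay of the linear-phase filter: N/2 samples."""
        return self.N // 2


def bessel_i0(x: float) -> float:
    """Zeroth-order modified Bessel function of the first kind, I0(x).

    Power series ``sum_i ((x/2)^i / i!)^2``, truncated once a term falls
    below 1e-16 of the running sum.
    """
    if x < 0:
        raise ValueError("bessel_i0 requires x >= 0")
    total = 1.0  # i = 0 term
    term = 1.0
    half = x / 2.0
    i = 1
    while True:
        term *= (half / i) ** 2
        total += term
        if term < 1e-16 * total:
            return total
        i += 1


def kaiser_window(N: int, beta: float) -> np.ndarray:
    """Kaiser window of ``N + 1`` symmetric weights.

    ``w[n] = I0(beta*sqrt(1 - (2n/N - 1)^2)) / I0(beta)``; the center
    weight is 1 and the endpoints are ``1/I0(beta)``.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    denom = bessel_i0(beta)
    # evaluate one half and mirror so the symmetry is exact in floats
    n = np.arange(N // 2 + 1)
    arg = beta * np.sqrt(np.clip(1.0 - (2.0 * n / N - 1.0) ** 2, 0.0, None))
    half = np.array([bessel_i0(a) for a in arg]) / denom
    return np.concatenate([half, half[-2 + (N % 2) :: -1]])


def ideal_bandpass(N: int, spec: FirSpec) -> np.ndarray:
    """Truncated ideal band-pass impulse response, ``N + 1`` coefficients.

    ``h_d[n] = sin(w2*(n - N/2))/(pi*(n - N/2)) - sin(w1*...)/...`` with
    the center coefficient ``(w2 - w1)/pi``; symmetric about ``N/2``.
    """
    w1 = 2.0 * math.pi * spec.f_c1 / spec.sample_rate_hz
    w2 = 2.0 * math.pi * spec.f_c2 / spec.sample_rate_hz
    # left half (m < 0) plus center, mirrored for exact symmetry
    m = np.arange(N // 2 + 1) - N / 2.0
    safe = np.where(m == 0, 1.0, m)
    half = (np.sin(w2 * safe) - np.sin(w1 * safe)) / (np.pi * safe)
    half[m == 0] = (w2 - w1) / np.pi
    return np.concatenate([half, half[-2 + (N % 2) :: -1]])


def design_fir(spec: FirSpec) -> np.ndarray:
    """Band-pass taps: elementwise product of the Kaiser window and the
    ideal response.  Symmetric, hence exactly linear-phase."""
    return kaiser_window(spec.N, spec.beta) * ideal_bandpass(spec.N, spec)


def apply_fir(trace: SignalTrace, taps: np.ndarray) -> SignalTrace:
    """Causal convolution ``y[n] = sum_k b[k] x[n-k]`` with zero-padded
    history.

    Output length equals input length; a symmetric ``N + 1``-tap filter
    delays the signal by ``N/2`` samples, and the first ``N`` output
    samples are start-up transient.
    """
    taps = np.asarray(taps, dtype=np.float64)
    x = trace.samples
    if x.size < taps.size:
        raise ValueError(
            f"trace length {x.size} shorter than filter length {taps.size}"
        )
    y = scipy.signal.convolve(x, taps, mode="full", method="auto")[: x.size]
    return SignalTrace(y, trace.sample_rate_hz, trace.channel_id)


def frequency_response(taps: np.ndarray, f: float, sample_rate_hz: float) -> float:
    """Magnitude of the taps' frequency response at ``f`` Hz."""
    n = np.arange(len(taps))
    return float(abs(np.sum(taps * np.exp(-2j * np.pi * f * n / sample_rate_hz))))


def minimum_taps(
    transition_hz: float, sample_rate_hz: float, beta: float = 6.0
) -> int:
    """Even tap count N whose Kaiser main lobe fits in ``transition_hz``.

    Uses the main-lobe half-width ``sqrt(beta^2 + pi^2)/(pi*N/2)`` cycles
    per sample of the Kaiser window spectrum.
    """
    if not transition_hz > 0:
        raise ValueError("transition_hz must be > 0")
    n = math.sqrt(beta**2 + math.pi**2) * sample_rate_hz / (
        math.pi * transition_hz
    )
    N = int(math.ceil(n))
    return N + (N % 2)
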