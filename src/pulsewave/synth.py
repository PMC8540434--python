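"""Seeded synthetic dual-channel pulse-wave generator with ground truth.

Emulates what the dual piezoelectric sensor + AFE + 12-bit ADC chain
delivers: two voltage traces of the same arterial pulse observed 2.5 cm
apart, the distal channel delayed by an integer number of samples, with
baseline wander, mains interference, white sensor noise and ADC
quantization layered on top.  Each beat is a two-Gaussian composite —
a dominant first (percussion) peak and a smaller, broader dicrotic peak
whose tail decays through diastole — placed at jittered inter-beat
intervals.

Two ectopic morphotypes are modelled after their clinical signatures:

* **PAC** — a timing anomaly: the beat arrives prematurely (at a fraction
  of the current interval) with normal morphology, followed by a
  compensatory pause that restores the underlying rhythm.
* **PVC** — a morphology anomaly: the beat keeps normal timing but its
  first peak is attenuated until it is close to the dicrotic peak's
  absolute height.

The generator records, per channel, the pre-noise first-peak sample
indices and per-beat labels, plus the true transit delay — the ground
truth every downstream stage is scored against.  Output is bit-identical
for a given seed.

Quantization is a mid-tread (rounding) uniform quantizer clipped to the
ADC range: it preserves zero, is idempotent, and its error never exceeds
half a code step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .trace import SignalTrace

__all__ = [
    "SubjectConfig",
    "GroundTruth",
    "beat_template",
    "generate_subject",
    "quantize",
]

# Beat-template geometry, as fractions of the beat width.  The first peak
# is a sharp systolic upstroke; the dicrotic hump is broad so the wave
# decays continuously through diastole instead of going flat (real pulse
# records are never silent between beats, and the trailing-window dynamic
# threshold relies on that).
FIRST_PEAK_POS = 0.20
FIRST_PEAK_SIGMA = 0.04
SECOND_PEAK_DELAY = 0.28
SECOND_PEAK_SIGMA = 0.12


@dataclass(frozen=True)
class SubjectConfig:
    """Simulation settings for one synthetic subject.

    ``beat_width_s = None`` scales the template to 95% of the mean
    inter-beat interval.  ``sensor_distance_m`` only enters the recorded
    ground-truth PWV.
    """

    duration_s: float = 60.0
    sample_rate_hz: float = 5000.0
    heart_rate_bpm: float = 60.0
    hr_jitter: float = 0.02
    first_peak_mv: float = 100.0
    second_peak_ratio: float = 0.45
    pvc_first_peak_ratio: float = 0.5
    pac_prematurity: float = 0.6
    ectopic_rate: float = 0.05
    ectopic_type: str = "pac"
    transit_delay_samples: int = 20
    noise_mv: float = 1.0
    drift_mv: float = 5.0
    drift_hz: float = 0.3
    mains_mv: float = 2.0
    mains_hz: float = 60.0
    adc_bits: int = 12
    adc_fullscale_mv: float = 400.0
    sensor_distance_m: float = 0.025
    beat_width_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ectopic_rate < 0.5):
            raise ValueError("ectopic_rate must be in [0, 0.5)")
        if self.transit_delay_samples < 1:
            raise ValueError("transit_delay_samples must be >= 1")
        if not 0 < self.pac_prematurity < 1:
            raise ValueError("pac_prematurity must be in (0, 1)")
        if self.ectopic_type not in ("pac", "pvc"):
            raise ValueError(f"unknown ectopic_type {self.ectopic_type!r}")
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("duration_s and sample_rate_hz must be > 0")
        if not 0 < self.second_peak_ratio < 1:
            raise ValueError("second_peak_ratio must be in (0, 1)")
        if not 0 < self.pvc_first_peak_ratio < 1:
            raise ValueError("pvc_first_peak_ratio must be in (0, 1)")
        if not self.pvc_first_peak_ratio > self.second_peak_ratio:
            raise ValueError(
                "pvc_first_peak_ratio must exceed second_peak_ratio so the "
                "attenuated first peak stays (just) dominant"
            )
        if self.adc_bits < 2:
            raise ValueError("adc_bits must be >= 2")

    @property
    def mean_interval_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def resolved_beat_width_s(self) -> float:
        if self.beat_width_s is not None:
            return self.beat_width_s
        return 0.95 * self.mean_interval_s


@dataclass(frozen=True)
class GroundTruth:
    """Generator bookkeeping used to score the analysis chain."""

    peak_indices_ch1: np.ndarray
    peak_indices_ch2: np.ndarray
    labels: List[str]
    true_ptt_samples: int
    true_pwv_m_s: float


def beat_template(
    first_mv: float,
    ratio: float,
    width_s: float,
    rate: float,
    *,
    first_peak_width_s: float | None = None,
) -> np.ndarray:
    """Render one beat: two Gaussian bumps over ``width_s`` seconds.

    The first bump (amplitude ``first_mv``) peaks at 20% of the width;
    the second at ``ratio * first_mv``, delayed a further 28% of the
    width and three times broader.  For ``ratio < 1`` the global maximum
    is the first peak; ``ratio = 0`` degenerates to a single bump.

    ``first_peak_width_s`` pins the systolic (first-peak) geometry to a
    different reference width: the generator uses it to stretch only the
    dicrotic portion with the instantaneous cycle length — diastole
    absorbs cycle-length variation while systolic timing stays fixed —
    so the ground-truth first-peak offset does not move.
    """
    if not 0 <= ratio < 1:
        raise ValueError("ratio must be in [0, 1) for a dominant first peak")
    n = int(round(width_s * rate))
    if n < 2:
        raise ValueError("beat width shorter than two samples")
    w1 = first_peak_width_s if first_peak_width_s is not None else width_s
    t = np.arange(n) / rate
    c1 = FIRST_PEAK_POS * w1
    s1 = FIRST_PEAK_SIGMA * w1
    c2 = c1 + SECOND_PEAK_DELAY * width_s
    s2 = SECOND_PEAK_SIGMA * width_s
    y = first_mv * np.exp(-0.5 * ((t - c1) / s1) ** 2)
    if ratio > 0:
        y = y + first_mv * ratio * np.exp(-0.5 * ((t - c2) / s2) ** 2)
    return y


def quantize(trace: SignalTrace, bits: int, fullscale_mv: float) -> SignalTrace:
    """Uniform mid-tread quantization over ``±fullscale_mv/2``.

    Codes are ``round(x/step)`` clipped to the two's-complement range,
    so zero maps to zero, requantizing is a no-op, and the in-range
    error is at most ``step/2 = fullscale / 2^bits / 2``.
    """
    if bits < 2:
        raise ValueError("bits must be >= 2")
    if not fullscale_mv > 0:
        raise ValueError("fullscale_mv must be > 0")
    step = fullscale_mv / 2**bits
    half = 2 ** (bits - 1)
    codes = np.clip(np.round(trace.samples / step), -half, half - 1)
    return SignalTrace(codes * step, trace.sample_rate_hz, trace.channel_id)


def generate_subject(cfg: SubjectConfig) -> Tuple[SignalTrace, SignalTrace, GroundTruth]:
    """Simulate one dual-channel recording plus its ground truth.

    Beats are laid down at jittered intervals; each beat after the first
    two is independently ectopic with probability ``ectopic_rate``.  The
    distal channel is the proximal one delayed by
    ``transit_delay_samples`` (applied before noise, so the two channels
    carry independent sensor noise).  Disturbances are added per channel
    and both channels pass through the ADC quantizer.
    """
    rate = cfg.sample_rate_hz
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * rate))
    width = cfg.resolved_beat_width_s()
    delay = cfg.transit_delay_samples

    # PVC: first peak attenuated toward the (unchanged) dicrotic height.
    pvc_first = cfg.first_peak_mv * cfg.pvc_first_peak_ratio
    pvc_ratio = cfg.second_peak_ratio * cfg.first_peak_mv / pvc_first

    T = cfg.mean_interval_s
    # Schedule beats first: (onset_s, label, use_pvc_template).  A PAC
    # arrives at pac_prematurity of the drawn interval; the following
    # normal beat lands two mean intervals after the beat preceding the
    # PAC, so the premature beat plus its compensatory pause restore the
    # underlying rhythm.
    schedule: List[tuple] = [(0.3, "normal", False)]
    while schedule[-1][0] <= cfg.duration_s:
        prev_t = schedule[-1][0]
        interval = max(
            T * (1.0 + cfg.hr_jitter * rng.standard_normal()), 0.2 * T
        )
        if len(schedule) >= 2 and rng.random() < cfg.ectopic_rate:
            if cfg.ectopic_type == "pac":
                schedule.append(
                    (prev_t + cfg.pac_prematurity * interval, "ectopic", False)
                )
                schedule.append((prev_t + 2.0 * T, "normal", False))
            else:
                schedule.append((prev_t + interval, "ectopic", True))
        else:
            schedule.append((prev_t + interval, "normal", False))

    # Diastole absorbs cycle-length variation: each beat's dicrotic
    # portion is stretched to its own gap to the next beat (within
    # bounds), while the systolic first peak keeps the nominal geometry.
    # A compensatory pause after a premature beat is therefore filled by
    # a decaying tail, as in real recordings, not by silence.
    clean = np.zeros(n + int(2.0 * width * rate) + delay + 1)
    peaks: List[int] = []
    labels: List[str] = []
    for i, (t0, label, is_pvc) in enumerate(schedule):
        gap = (
            schedule[i + 1][0] - t0 if i + 1 < len(schedule) else T
        )
        # stretch only: an early next beat truncates this one by
        # superposition, it does not reshape it
        w_i = float(np.clip(0.95 * gap, width, 1.6 * width))
        if is_pvc:
            tpl = beat_template(pvc_first, pvc_ratio, w_i, rate,
                                first_peak_width_s=width)
        else:
            tpl = beat_template(cfg.first_peak_mv, cfg.second_peak_ratio,
                                w_i, rate, first_peak_width_s=width)
        off = int(np.argmax(tpl))
        start = int(round(t0 * rate))
        if t0 > cfg.duration_s or start + len(tpl) >= len(clean):
            break
        clean[start : start + len(tpl)] += tpl
        peaks.append(start + off)
        labels.append(label)
    clean = clean[:n]
    delayed = np.concatenate([np.zeros(delay), clean[:-delay]])

    t = np.arange(n) / rate
    mains_phase = rng.uniform(0, 2 * np.pi)

    def disturb(sig: np.ndarray) -> np.ndarray:
        out = sig.copy()
        if cfg.drift_mv > 0:
            out += cfg.drift_mv * np.sin(
                2 * np.pi * cfg.drift_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if cfg.mains_mv > 0:
            out += cfg.mains_mv * np.sin(2 * np.pi * cfg.mains_hz * t + mains_phase)
        if cfg.noise_mv > 0:
            out += cfg.noise_mv * rng.standard_normal(n)
        return out

    ch1 = quantize(
        SignalTrace(disturb(clean), rate, "ch1"), cfg.adc_bits, cfg.adc_fullscale_mv
    )
    ch2 = quantize(
        SignalTrace(disturb(delayed), rate, "ch2"), cfg.adc_bits, cfg.adc_fullscale_mv
    )

    p1 = np.array(peaks, dtype=np.int64)
    keep = p1 < n
    p1 = p1[keep]
    labels = [lab for lab, k in zip(labels, keep) if k]
    p2 = p1 + delay
    in2 = p2 < n
    truth = GroundTruth(
        peak_indices_ch1=p1,
        peak_indices_ch2=p2[in2],
        labels=labels,
        true_ptt_samples=delay,
        true_pwv_m_s=cfg.sensor_distance_m / (delay / rate),
    )
    return ch1, ch2, truth
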