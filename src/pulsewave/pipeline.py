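"""End-to-end analysis: filter -> detect -> pair -> flag -> estimate.

``run_analyze`` takes a proximal/distal trace pair and produces a
per-beat table (peak index, inter-beat interval, normal/ectopic label,
PTT, PWV, MAP) plus summary statistics: mean PWV and mean MAP over all
beats and with ectopic beats excluded, and — when a cuff reference MAP
is supplied — the mean differences against both.

Peaks are reported in raw-trace sample coordinates: the band-pass FIR is
linear-phase, so detections are shifted back by the known group delay
(N/2 samples).  Beats whose first peak falls inside the filter's warm-up
(threshold window + group delay at the start of the record) or inside
the group-delay tail at the end are excluded — the causal filter has not
produced settled output there.

The pipeline's default FIR is sized so the 0.7–9.5 Hz band is actually
resolved at the trace's sample rate (about 16k taps at 5 kHz); see
``filters.minimum_taps``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import detect as detect_mod
from . import filters as filters_mod
from . import hemodynamics as hemo_mod
from .beats import BeatPair, EctopicPolicy
from .detect import ThresholdParams
from .filters import FirSpec
from .hemodynamics import ArteryModel
from .trace import SignalTrace

__all__ = ["RunConfig", "AnalysisReport", "InsufficientDataError", "run_analyze",
           "default_fir_spec"]


class InsufficientDataError(ValueError):
    """Fewer usable beats than the analysis requires."""


def default_fir_spec(sample_rate_hz: float, f_c1: float = 0.7,
                     f_c2: float = 9.5, beta: float = 6.0) -> FirSpec:
    """Band-pass spec whose tap count resolves the band at this rate."""
    n = filters_mod.minimum_taps(f_c1, sample_rate_hz, beta)
    return FirSpec(f_c1=f_c1, f_c2=f_c2, N=n, beta=beta,
                   sample_rate_hz=sample_rate_hz)


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of one analysis run.

    ``filter=None`` resolves to :func:`default_fir_spec` at the traces'
    sample rate.  ``artery=None`` skips pressure estimation;
    ``reference_map_mmhg=None`` skips the mean-difference comparison.
    """

    sensor_distance_m: float = 0.025
    filter: Optional[FirSpec] = None
    threshold: ThresholdParams = field(default_factory=ThresholdParams)
    ectopic: EctopicPolicy = field(default_factory=EctopicPolicy)
    artery: Optional[ArteryModel] = None
    reference_map_mmhg: Optional[float] = None
    seed: int = 0


@dataclass
class AnalysisReport:
    """Per-beat table plus flat summary of one run."""

    beats: pd.DataFrame
    summary: dict
    config: RunConfig

    def summary_text(self) -> str:
        """Flat ``key=value`` block, deterministic ordering."""
        buf = io.StringIO()
        for k in sorted(self.summary):
            v = self.summary[k]
            if isinstance(v, float):
                buf.write(f"{k}={v:.6f}\n")
            else:
                buf.write(f"{k}={v}\n")
        return buf.getvalue()

    def to_csv(self, path) -> None:
        self.beats.to_csv(path, index=False)


def _detected_peaks(trace: SignalTrace, taps: np.ndarray,
                    params: ThresholdParams) -> np.ndarray:
    """Filter, detect, undo group delay, drop warm-up and tail peaks."""
    filtered = filters_mod.apply_fir(trace, taps)
    events = detect_mod.detect_events(filtered, params)
    peaks = detect_mod.peak_indices(events)
    gd = (len(taps) - 1) // 2
    w = params.resolve_window(trace.sample_rate_hz)
    peaks = peaks[peaks >= w + gd] - gd
    return peaks[peaks < len(trace) - gd]


def run_analyze(proximal: SignalTrace, distal: SignalTrace,
                cfg: RunConfig = RunConfig()) -> AnalysisReport:
    """Run the full chain on one dual-channel recording."""
    if proximal.sample_rate_hz != distal.sample_rate_hz:
        raise ValueError("channels must share a sample rate")
    rate = proximal.sample_rate_hz
    spec = cfg.filter if cfg.filter is not None else default_fir_spec(rate)
    taps = filters_mod.design_fir(spec)

    prox = _detected_peaks(proximal, taps, cfg.threshold)
    dist = _detected_peaks(distal, taps, cfg.threshold)
    if prox.size < 4:
        raise InsufficientDataError(
            f"only {prox.size} usable proximal beats; need >= 4 "
            "(3 inter-beat intervals) to flag ectopic beats"
        )

    intervals = beats_mod.intervals_from_peaks(prox, rate)
    labels = beats_mod.flag_ectopic(intervals, cfg.ectopic)
    max_lag = beats_mod.default_max_lag_s(prox, rate)
    pairs = beats_mod.pair_peaks(prox, dist, rate, max_lag,
                                 cfg.sensor_distance_m)
    ptt_by_prox = {p.proximal_peak: p for p in pairs}

    rows = []
    for i, p in enumerate(prox):
        pair: Optional[BeatPair] = ptt_by_prox.get(int(p))
        pwv = pair.pwv_m_s if pair else np.nan
        row = {
            "peak_index": int(p),
            "time_s": p / rate,
            "interval_prev_s": intervals[i - 1] if i > 0 else np.nan,
            "label": labels[i],
            "ptt_s": pair.ptt_s if pair else np.nan,
            "pwv_m_s": pwv,
        }
        if cfg.artery is not None:
            # A grossly mis-paired beat can put the modulus below E0;
            # mark that beat's estimate NaN instead of aborting the run.
            try:
                row["map_mmhg"] = (
                    hemo_mod.pressure_from_pwv(pwv, cfg.artery)
                    if np.isfinite(pwv)
                    else np.nan
                )
            except ValueError:
                row["map_mmhg"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    normal = table["label"] == "normal"
    pwv_all = table["pwv_m_s"].dropna()
    pwv_norm = table.loc[normal, "pwv_m_s"].dropna()
    summary = {
        "n_beats": len(table),
        "n_ectopic": int((~normal).sum()),
        "n_paired": int(pwv_all.size),
        "mean_pwv_all_m_s": float(pwv_all.mean()) if pwv_all.size else np.nan,
        "mean_pwv_normal_m_s": float(pwv_norm.mean()) if pwv_norm.size else np.nan,
        "sensor_distance_m": cfg.sensor_distance_m,
        "fir_taps": spec.N + 1,
        "threshold_window": cfg.threshold.resolve_window(rate),
    }
    if cfg.artery is not None:
        map_all = table["map_mmhg"].dropna()
        map_norm = table.loc[normal, "map_mmhg"].dropna()
        summary["mean_map_all_mmhg"] = (
            float(map_all.mean()) if map_all.size else np.nan
        )
        summary["mean_map_normal_mmhg"] = (
            float(map_norm.mean()) if map_norm.size else np.nan
        )
        if cfg.reference_map_mmhg is not None and map_all.size and map_norm.size:
            summary["md_reference_all_mmhg"] = hemo_mod.mean_difference(
                cfg.reference_map_mmhg, map_all.to_numpy()
            )
            summary["md_reference_normal_mmhg"] = hemo_mod.mean_difference(
                cfg.reference_map_mmhg, map_norm.to_numpy()
            )
    return AnalysisReport(beats=table, summary=summary, config=cfg)
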