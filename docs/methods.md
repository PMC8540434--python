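# Methods

This note documents the models, numerical choices and limitations
behind `pulsewave`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Signal chain and conventions

A dual piezoelectric sensor on the radial artery feeds an analog front
end and a 12-bit ADC sampling at 5 kHz.  Throughout the package sample
indices are 0-based, time is `index / sample_rate_hz` seconds, and
amplitudes are in mV.  Traces are uniformly sampled and gap-free; a
missing cell in an input CSV is a parse error, not a NaN, because the
detector state machine assumes contiguity.

## Front-end calculators (`afe`)

Pure formulas, not a circuit simulator: the load resistor
`R = 1/(2π f C_p)` forming the first-order high-pass with the sensor's
parasitic capacitance; the gain `R2/R3`; the Sallen–Key corner
`1/(2π √(R_a C_a R_b C_b))` and second-order transfer-function
magnitudes (equal-component stages have Q = 1/2, so |H| at the corner
is 0.5); and the sensor cavity treated as a Helmholtz spring,
`a(x) = −(γ S P_A / ρ_air V L) · x`, whose natural frequency for
plausible geometry lands in the tens of kHz — far above the pulse
band, which is why the sensor's in-band response is treated as flat.
Air density defaults to 1.2 kg/m³ (room conditions) and γ to 1.4.

## FIR band-pass (`filters`)

The band-pass is the classical windowed-sinc design: ideal band-pass
impulse response `h_d` (corner frequencies normalized as
`ω = 2π f_c / f_s` — the only reading under which the corners land at
the stated 0.7 and 9.5 Hz), truncated to `N+1` taps and multiplied by
a Kaiser window.  The order-0 modified Bessel function is summed as
its power series starting at the `i = 0` term (the series must start
at 1, otherwise the window normalization divides by zero), truncated
when a term falls below 1e-16 of the running sum, and is cross-checked
in the tests against `scipy.special.i0` and `numpy.kaiser`.  Window
and sinc are evaluated on one half and mirrored, so tap symmetry —
hence exactly linear phase and an integer `N/2`-sample group delay —
holds bit-for-bit.

`beta` defaults to 6.0 (≈ −63 dB side lobes); the band properties are
insensitive to it over roughly [4, 9].

**Filter sizing.**  A Kaiser design's transition band is about
`√(β² + π²) · f_s / (π · N/2)` Hz wide.  At 5 kHz a 128-tap filter
therefore has an ~80 Hz transition band: it cannot realize a
0.7–9.5 Hz passband, and its actual response is a shallow wide-band
low-pass with ≈ 0.22 gain (`examples/02_filter_design.py` prints both
responses).  The 128-tap configuration is kept available as
`FirSpec()`'s default for the acquisition-chain fidelity it
represents, but the analysis pipeline defaults to
`minimum_taps(f_c1, f_s)` ≈ 15 400 taps, at which the band is actually
resolved: mid-band gain 1.000 at 5 Hz, |Σb| < 0.02 (DC rejection), and
< 1e-4 response at 25 and 60 Hz.  The cost is a 1.54 s group delay,
which the pipeline removes exactly (linear phase) before any timing
measurement.

Convolution is causal with zero-padded history; output length equals
input length.  The first `N` output samples are start-up transient,
and the last `N/2` raw-domain samples never receive settled output, so
the pipeline excludes beats in both regions from pairing and scoring.

## Adaptive threshold and beat detection (`detect`)

Over a trailing window (default half the sampling rate, i.e. 0.5 s)
the dynamic threshold is

    gradient = RMS · CV / 100 · gain

with `CV` the population variance of the window (mV²), `RMS` its root
mean square (mV), and `gain` defaulting to 1.  The variance form is
implemented literally; a `cv_mode="std"` variant (making the bracket a
coefficient-of-variation-like quantity) is provided but is not the
default.  The constant 100 absorbs the amplitude scale.  The series is
recomputed every sample via cumulative sums (O(n), clamped at zero
against float cancellation); a block-wise mode recomputing once per
window is available.  During warm-up the window grows from sample 0.

The detector is a two-state hysteresis machine: while rising it tracks
the running maximum and confirms a **peak** (at the maximum's index)
once the signal drops `gradient` below it; while falling it tracks the
running minimum and confirms a **trough** once the signal climbs
`gradient` above it.  Rise/fall onsets are emitted at the confirming
samples.  Start-up is undecided, tracking both extrema from sample 0;
whichever condition triggers first decides the phase, and the matching
onset is back-filled at index 0 so peaks and troughs are always
bracketed by onsets.  Plateau ties resolve to the first sample
(strictly-greater updates).  The streaming implementation is checked
for exact peak-set equality against an independently structured
offline jump-search oracle on randomized signals.

Because the threshold follows signal strength with a ~0.5 s lag, a
beat is confirmed only once the wave has decayed well below its first
peak; the dicrotic hump is never confirmed as a separate beat as long
as its local rise stays below the gradient — which the `/100` scaling
arranges for pulse amplitudes on the order of 100 mV.

## Intervals, ectopic flagging, pairing (`beats`)

Beat-to-beat intervals come from successive detected first peaks.  A
beat is flagged ectopic when the interval *terminating* it deviates
from a reference by more than `relative_tolerance` (default 0.25; the
threshold for "much larger or smaller" is not prescribed anywhere, so
it is exposed in the policy).  The reference defaults to the
**median** — robust to the very intervals being flagged — with a
`"mean"` mode available.  The first beat inherits the test of the
interval that follows it.  Note that with this rule a premature beat's
compensatory pause also flags the *following* normal beat; recall on
the premature beats themselves is what the recovery tests measure.

Proximal and distal peak trains are paired greedily: each proximal
peak takes the earliest unused distal peak strictly after it within
`max_lag` (default half the median inter-beat interval, which prevents
cross-beat mis-pairing).  PTT resolution is one sample — 0.2 ms at
5 kHz, i.e. ~5 % of a 4 ms transit time — and no sub-sample
interpolation is attempted, since the measurement is defined on
detected peak indices.  `PWV = sensor_distance / PTT` with a 2.5 cm
default spacing.

## Pressure estimation (`hemodynamics`)

`E_inc = PWV² D ρ / h` is computed in SI (Pa) and multiplied by a
stored calibration factor `unit_scale = 0.1` before inversion
`P = ln(E_inc/E₀)/ξ`.  The published coefficients `E₀ = 1428.7`,
`ξ = 0.031 /mmHg` carry no stated units for `E₀`; solving
`E₀ e^{ξP}` against the two reference subjects' printed mean MAP and
geometry gives a consistent SI-to-calibrated factor of 0.1 for both,
so the factor is stored explicitly on `ArteryModel` and documented as
an inherited unit convention rather than physics.  With it, the two
anchor round trips reproduce (6.34 m/s, D = 1.75 mm, h = 0.39 mm →
83.70 mmHg; 7.14 m/s, D = 2.35 mm, h = 0.47 mm → 94.86 mmHg).

Mean MAP over a record is the mean of per-beat pressures (pressure is
concave in PWV, so this is systematically at or below the pressure of
the mean PWV — asserted as a property test).  The cuff reference is
`MAP = (SBP + 2·DBP)/3`.  In the pipeline, a beat whose mis-paired PWV
puts the modulus below `E₀` gets a NaN estimate instead of aborting
the run; the standalone function raises.

## Scoring (`metrics`)

A truth beat is a true positive when an unused detection lies within
±3 samples (0.6 ms at 5 kHz); matching is greedy and one-to-one.  Only
TP and FN are defined (TB = TP + FN), so sensitivity and accuracy
coincide; percentages are **truncated** to one decimal with integer
arithmetic (`TP·1000 // TB / 10`) — 186/187 reports as 99.4 and 17/19
as 89.4, which rounding cannot produce.  Detections matching no truth
beat are counted separately as false positives and never enter Se/Ac.

## Synthetic generator (`synth`)

The generator emulates what the sensor chain delivers, not arterial
physics.  Each beat is a two-Gaussian composite: a sharp systolic
first peak (center 0.20, σ 0.04 of the beat width) and a broad
dicrotic hump (delay 0.28, σ 0.12), with the beat width defaulting to
95 % of the mean cycle (0.95 s at 60 bpm).  Two features matter for
faithfulness to real recordings:

- **Diastole absorbs cycle-length variation.**  Each beat's dicrotic
  portion is stretched to its own gap to the next beat (clipped to
  [1.0, 1.6]× the nominal width; stretch only — an early next beat
  truncates its predecessor by superposition rather than reshaping
  it), while the systolic geometry stays fixed in absolute time so the
  ground-truth first-peak index does not move.  Without this, a
  compensatory pause leaves > 0.5 s of silence, the trailing-window
  threshold collapses to the noise floor, and noise wiggles are
  systematically detected as beats — an artifact of template silence,
  not of the detector.
- **Ectopic morphotypes.**  A PAC is a timing anomaly: it arrives at
  `pac_prematurity` (default 0.6) of the drawn interval with normal
  morphology, and the following beat lands two mean cycles after the
  beat preceding the PAC (fully compensatory pause).  A PVC is a
  morphology anomaly: normal timing, but its first peak is attenuated
  (default to 50 mV) toward the unchanged dicrotic height (45 mV), so
  the first peak stays only just dominant.

Beats are scheduled at intervals `T(1 + jitter·ε)`, ε standard normal
(jitter 0.02); each beat after the first two is independently ectopic
with probability `ectopic_rate`.  The distal channel is the proximal
one delayed by an integer `transit_delay_samples` (default 20 ⇒ 6.25
m/s at 2.5 cm) *before* disturbances, so the channels carry
independent sensor noise; disturbances are white noise (default SD
1 mV on a 100 mV first peak), 0.3 Hz baseline wander (5 mV), 60 Hz
mains (2 mV, common phase across channels), then mid-tread 12-bit
quantization over ±200 mV (zero-preserving, idempotent, error ≤ half a
code step).  Everything is driven by one `numpy` generator seeded from
the config, so output is bit-identical per seed.

What the generator does **not** emulate: beat-to-beat hemodynamic
variation of the transit delay itself (every beat shares one integer
delay), realistic pulse morphology beyond two bumps, respiratory
modulation, sensor motion artifacts, or ectopic-specific hemodynamics.
Consequently, passing the recovery tests shows that the *computation
chain* is correct and noise-robust — it does not certify clinical
accuracy on real arteries, where the PWV of an ectopic beat genuinely
differs.

## Evaluation protocol and problem sizes

Recovery tests run the full chain on 30 s subjects (≈ 29 beats each):
transit-time recovery on 20 seeds at 2 mV noise (2 % of the first
peak) requiring ≥ 95 % of paired beats within one sample of the true
PTT, exact recovery on a disturbance-free subject, and ≥ 90 % recall
of PAC labels on 20 seeds at `ectopic_rate = 0.08`.  Beats whose first
peak falls in the filter warm-up (threshold window + group delay) or
in the group-delay tail are excluded from pairing and scoring on both
channels.  Detector/oracle equivalence uses 100 randomized
1000-sample signals.  These sizes keep the default suite fast while
leaving the statistics comfortably clear of their thresholds.

## Known limitations

- The printed 128-tap filter configuration is retained but documented
  as unresolved at 5 kHz; analyses use the resolved design by default.
- Greedy pairing can still attach a wrong distal peak near a missed
  detection; such beats surface as NaN or outlier PWVs in the per-beat
  table rather than being silently dropped.
- The ectopic rule is interval-only; a PVC with normal timing is
  invisible to it (morphology-based flagging is out of scope).
- `E₀`, `ξ` and `unit_scale` are a calibration inherited from aortic
  pressure–volume data; no claim is made about their validity beyond
  reproducing the reference arithmetic.
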