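"""Dynamic threshold and the hysteresis peak/trough state machine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsewave.detect import (
    ThresholdParams,
    detect_events,
    dynamic_gradient,
    gradient_series,
    peak_indices,
    window_cv,
    window_mean,
    window_rms,
)
from pulsewave.trace import SignalTrace


class TestWindowStatistics:
    def test_mean_examples(self):
        assert window_mean([1, 3]) == 2.0
        assert window_mean([7.5] * 10) == 7.5
        assert window_mean([0, 1, 2, 3]) == 1.5

    def test_cv_is_population_variance(self):
        assert window_cv([5, 5, 5]) == 0.0
        assert window_cv([1, 3]) == 1.0  # ((1-2)^2 + (3-2)^2)/2

    def test_cv_translation_invariant(self, rng):
        x = rng.standard_normal(50)
        assert window_cv(x + 100.0) == pytest.approx(window_cv(x), abs=1e-9)

    def test_rms_examples_and_scaling(self, rng):
        assert window_rms([1, 3]) == pytest.approx(np.sqrt(5))
        assert window_rms(np.zeros(5)) == 0.0
        x = rng.standard_normal(20)
        assert window_rms(-3 * x) == pytest.approx(3 * window_rms(x))

    def test_empty_window_rejected(self):
        for fn in (window_mean, window_cv, window_rms):
            with pytest.raises(ValueError):
                fn([])


class TestDynamicGradient:
    def test_constant_window_gives_zero(self):
        assert dynamic_gradient([4.2] * 10, ThresholdParams()) == pytest.approx(0.0, abs=1e-15)

    def test_composition_of_printed_formulas(self):
        # RMS([1,3]) * CV([1,3]) / 100 = sqrt(5) * 1 / 100
        g = dynamic_gradient([1, 3] * 50, ThresholdParams())
        assert g == pytest.approx(np.sqrt(5) / 100, rel=1e-12)

    def test_linear_in_gain(self):
        vals = [0, 2, 5, 1]
        g1 = dynamic_gradient(vals, ThresholdParams(gain=1.0))
        g2 = dynamic_gradient(vals, ThresholdParams(gain=2.0))
        assert g2 == pytest.approx(2 * g1)

    def test_std_mode_takes_square_root(self):
        vals = [1, 3] * 8
        g_var = dynamic_gradient(vals, ThresholdParams(cv_mode="variance"))
        g_std = dynamic_gradient(vals, ThresholdParams(cv_mode="std"))
        assert g_std == pytest.approx(g_var)  # CV=1 here
        vals4 = [1, 5] * 8  # CV=4, sqrt -> 2
        g_var = dynamic_gradient(vals4, ThresholdParams(cv_mode="variance"))
        g_std = dynamic_gradient(vals4, ThresholdParams(cv_mode="std"))
        assert g_var == pytest.approx(2 * g_std)

    def test_series_matches_per_window_recomputation(self, rng):
        x = rng.standard_normal(400) * 30
        tr = SignalTrace(x, 100.0)
        params = ThresholdParams(window_samples=50)
        g = gradient_series(tr, params)
        for i in (0, 10, 49, 50, 123, 399):
            lo = max(0, i - 49)
            assert g[i] == pytest.approx(
                dynamic_gradient(x[lo : i + 1], params), rel=1e-9, abs=1e-12
            )

    def test_block_update_holds_between_boundaries(self, rng):
        x = rng.standard_normal(300)
        tr = SignalTrace(x, 100.0)
        g = gradient_series(tr, ThresholdParams(window_samples=50, update="block"))
        assert np.all(g[49:99] == g[49])
        assert np.all(g[99:149] == g[99])

    @given(gain=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_gradient_nonnegative(self, gain):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200) * 50
        g = gradient_series(
            SignalTrace(x, 100.0), ThresholdParams(window_samples=20, gain=gain)
        )
        assert np.all(g >= 0)


class TestStateMachine:
    def test_hand_traced_double_triangle(self):
        # x = [0,5,10,5,0,5,10,5,0], window 2: gradient over (a,b) is
        # sqrt((a^2+b^2)/2) * ((a-b)/2)^2 / 100, i.e. 0.221 / 0.494 here —
        # small against the swings, so every extremum is confirmed.
        x = np.array([0, 5, 10, 5, 0, 5, 10, 5, 0], dtype=float)
        ev = detect_events(SignalTrace(x, 4.0), ThresholdParams(window_samples=2))
        got = [(e.kind, e.index) for e in ev]
        assert got == [
            ("fall_onset", 0),
            ("trough", 0),
            ("rise_onset", 1),
            ("peak", 2),
            ("fall_onset", 3),
            ("trough", 4),
            ("rise_onset", 5),
            ("peak", 6),
            ("fall_onset", 7),
        ]

    def test_monotone_trace_emits_no_peak(self):
        x = np.linspace(0, 10, 100)
        ev = detect_events(SignalTrace(x, 100.0), ThresholdParams(window_samples=10))
        assert all(e.kind != "peak" for e in ev)

    def test_plateau_peak_resolves_to_first_sample(self):
        x = np.array([0, 1, 5, 5, 5, 1, 0, 0, 0, 0], dtype=float)
        ev = detect_events(SignalTrace(x, 4.0), ThresholdParams(window_samples=2))
        peaks = [e.index for e in ev if e.kind == "peak"]
        assert peaks == [2]

    def test_two_bumps_deep_trough(self):
        # two identical bumps separated by a deep trough: 2 peaks, 1
        # interior trough (ignoring the start-up trough at index 0)
        t = np.linspace(0, 1, 200)
        x = np.exp(-0.5 * ((t - 0.25) / 0.05) ** 2) + np.exp(
            -0.5 * ((t - 0.75) / 0.05) ** 2
        )
        ev = detect_events(
            SignalTrace(100 * x, 200.0), ThresholdParams(window_samples=20)
        )
        peaks = [e.index for e in ev if e.kind == "peak"]
        troughs = [e.index for e in ev if e.kind == "trough" and e.index > 0]
        assert len(peaks) == 2
        assert len(troughs) == 1
        assert peaks[0] < troughs[0] < peaks[1]
        # apex positions recovered
        assert abs(peaks[0] - 50) <= 1 and abs(peaks[1] - 149) <= 1

    def test_events_alternate_and_are_ordered(self, rng):
        x = np.cumsum(rng.standard_normal(2000))
        ev = detect_events(SignalTrace(x, 500.0), ThresholdParams(window_samples=50))
        idx = [e.index for e in ev]
        assert idx == sorted(idx)
        pt = [e.kind for e in ev if e.kind in ("peak", "trough")]
        for a, b in zip(pt, pt[1:]):
            assert a != b  # peaks and troughs alternate

    def test_every_peak_bracketed_by_onsets(self, rng):
        x = np.cumsum(rng.standard_normal(3000))
        ev = detect_events(SignalTrace(x, 500.0), ThresholdParams(window_samples=100))
        for i, e in enumerate(ev):
            if e.kind == "peak":
                assert ev[i - 1].kind == "rise_onset" or i == 1
                assert ev[i + 1].kind == "fall_onset"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detect_events(SignalTrace(np.zeros(10), 100.0),
                          ThresholdParams(window_samples=50))


def offline_oracle_peaks(x: np.ndarray, g: np.ndarray) -> list:
    """Independent offline reference: vectorized jump-search over the
    same per-sample gradient sequence."""
    n = len(x)
    peaks = []
    mode = 0
    mx = mi = x[0]
    mxi = mii = 0
    i = 1
    while i < n:
        tail = np.arange(i, n)
        if mode >= 0:
            up = x[i:] > mx
            down = x[i:] < mx - g[i:]
        else:
            up = np.zeros(n - i, dtype=bool)
            down = np.zeros(n - i, dtype=bool)
        if mode <= 0:
            lower = x[i:] < mi
            rise = x[i:] > mi + g[i:]
        else:
            lower = np.zeros(n - i, dtype=bool)
            rise = np.zeros(n - i, dtype=bool)
        any_trig = up | down | lower | rise
        if not any_trig.any():
            break
        j = int(tail[any_trig.argmax()])
        if mode >= 0 and x[j] > mx:
            mx, mxi = x[j], j
        if mode <= 0 and x[j] < mi:
            mi, mii = x[j], j
        if mode >= 0 and x[j] < mx - g[j]:
            peaks.append(mxi)
            mode = -1
            mi, mii = x[j], j
        elif mode <= 0 and x[j] > mi + g[j]:
            mode = 1
            mx, mxi = x[j], j
        i = j + 1
    return peaks


class TestOracleEquivalence:
    def test_random_signals_match_offline_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            x = np.cumsum(rng.standard_normal(1000)) + 5 * np.sin(
                np.linspace(0, 20, 1000)
            )
            tr = SignalTrace(x, 250.0)
            params = ThresholdParams(window_samples=125)
            got = peak_indices(detect_events(tr, params)).tolist()
            expected = offline_oracle_peaks(x, gradient_series(tr, params))
            assert got == expected
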