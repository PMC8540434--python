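"""Synthetic dual-channel generator: morphology, scheduling, ADC model,
and ground-truth bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsewave.beats import pair_peaks
from pulsewave.detect import ThresholdParams, detect_events, peak_indices
from pulsewave.synth import (
    SubjectConfig,
    beat_template,
    generate_subject,
    quantize,
)
from pulsewave.trace import SignalTrace


def local_maxima(y: np.ndarray) -> np.ndarray:
    return np.where((y[1:-1] > y[:-2]) & (y[1:-1] > y[2:]))[0] + 1


class TestBeatTemplate:
    def test_single_bump_when_ratio_zero(self):
        y = beat_template(100.0, 0.0, 0.95, 5000.0)
        assert len(local_maxima(y)) == 1

    def test_two_peaks_with_dicrotic_ratio(self):
        y = beat_template(100.0, 0.45, 0.95, 5000.0)
        maxima = local_maxima(y)
        assert len(maxima) == 2
        second_over_first = y[maxima[1]] / y[maxima[0]]
        assert 0.4 <= second_over_first <= 0.5

    def test_global_maximum_is_first_peak(self):
        y = beat_template(100.0, 0.45, 0.95, 5000.0)
        assert np.argmax(y) == local_maxima(y)[0]

    def test_segment_starts_and_ends_near_zero(self):
        y = beat_template(100.0, 0.45, 0.95, 5000.0)
        assert abs(y[0]) < 0.1 and abs(y[-1]) < 0.5

    def test_dominance_constraint(self):
        with pytest.raises(ValueError):
            beat_template(100.0, 1.2, 0.95, 5000.0)


class TestQuantize:
    def _tr(self, x):
        return SignalTrace(np.asarray(x, dtype=float), 5000.0)

    def test_idempotent(self, rng):
        t = self._tr(rng.uniform(-200, 200, 500))
        q1 = quantize(t, 12, 400.0)
        q2 = quantize(q1, 12, 400.0)
        np.testing.assert_array_equal(q1.samples, q2.samples)

    def test_zero_preserved(self):
        q = quantize(self._tr(np.zeros(10)), 12, 400.0)
        np.testing.assert_array_equal(q.samples, np.zeros(10))

    def test_ramp_error_bound(self):
        step = 400.0 / 4096
        ramp = np.linspace(-200 + step, 200 - step, 8192)
        q = quantize(self._tr(ramp), 12, 400.0)
        assert np.max(np.abs(q.samples - ramp)) <= step / 2 + 1e-12

    def test_clipping_at_fullscale(self):
        q = quantize(self._tr([1e6, -1e6]), 12, 400.0)
        assert q.samples[0] == pytest.approx(2047 * 400.0 / 4096)
        assert q.samples[1] == pytest.approx(-200.0)

    @given(bits=st.integers(min_value=2, max_value=16))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_error_bound_any_depth(self, bits):
        rng = np.random.default_rng(3)
        x = rng.uniform(-190, 190, 200)
        q = quantize(self._tr(x), bits, 400.0)
        assert np.max(np.abs(q.samples - x)) <= 400.0 / 2**bits


class TestGenerateSubject:
    def test_same_seed_bit_identical(self):
        cfg = SubjectConfig(duration_s=10.0, seed=11)
        a1, a2, ta = generate_subject(cfg)
        b1, b2, tb = generate_subject(cfg)
        np.testing.assert_array_equal(a1.samples, b1.samples)
        np.testing.assert_array_equal(a2.samples, b2.samples)
        np.testing.assert_array_equal(
            ta.peak_indices_ch1, tb.peak_indices_ch1
        )
        assert ta.labels == tb.labels

    def test_zero_ectopic_rate_all_normal(self):
        _, _, truth = generate_subject(
            SubjectConfig(duration_s=20.0, ectopic_rate=0.0, seed=2)
        )
        assert set(truth.labels) == {"normal"}

    def test_labels_align_with_peaks(self):
        for seed in (1, 2, 3):
            _, _, truth = generate_subject(
                SubjectConfig(duration_s=20.0, ectopic_rate=0.1, seed=seed)
            )
            assert len(truth.labels) == len(truth.peak_indices_ch1)
            assert np.all(np.diff(truth.peak_indices_ch1) > 0)

    def test_beat_count_near_heart_rate(self):
        _, _, truth = generate_subject(
            SubjectConfig(duration_s=60.0, ectopic_rate=0.0, seed=1)
        )
        assert 59 <= len(truth.peak_indices_ch1) <= 61

    def test_pac_short_interval_then_compensatory_pause(self):
        _, _, truth = generate_subject(
            SubjectConfig(duration_s=60.0, ectopic_rate=0.15,
                          ectopic_type="pac", seed=4)
        )
        ect = [i for i, lab in enumerate(truth.labels) if lab == "ectopic"]
        assert ect, "expected at least one PAC"
        iv = np.diff(truth.peak_indices_ch1) / 5000.0
        for i in ect:
            if 0 < i < len(iv):
                assert iv[i - 1] < 0.75  # premature arrival
                assert iv[i] > 1.1  # compensatory pause
                assert iv[i - 1] + iv[i] == pytest.approx(2.0, abs=0.1)

    def test_pvc_first_peak_attenuated_to_near_dicrotic(self):
        c1, _, truth = generate_subject(
            SubjectConfig(duration_s=60.0, ectopic_rate=0.15,
                          ectopic_type="pvc", noise_mv=0.0, drift_mv=0.0,
                          mains_mv=0.0, seed=4)
        )
        ect = [i for i, lab in enumerate(truth.labels) if lab == "ectopic"]
        assert ect
        normal_amp = np.median(
            [c1.samples[p] for p, lab in zip(truth.peak_indices_ch1, truth.labels)
             if lab == "normal"]
        )
        for i in ect:
            amp = c1.samples[truth.peak_indices_ch1[i]]
            assert amp == pytest.approx(0.5 * normal_amp, rel=0.1)

    def test_true_pwv_consistent_with_delay(self):
        cfg = SubjectConfig(duration_s=10.0, seed=0)
        _, _, truth = generate_subject(cfg)
        assert truth.true_pwv_m_s == pytest.approx(
            cfg.sensor_distance_m / (truth.true_ptt_samples / cfg.sample_rate_hz)
        )

    def test_channel2_is_delayed_channel1_without_disturbances(self):
        cfg = SubjectConfig(duration_s=10.0, noise_mv=0.0, drift_mv=0.0,
                            mains_mv=0.0, seed=5)
        c1, c2, truth = generate_subject(cfg)
        d = truth.true_ptt_samples
        np.testing.assert_array_equal(c2.samples[d:], c1.samples[:-d])

    def test_transit_delay_recovered_exactly_on_clean_traces(self):
        # detection straight on the noiseless traces: every pair's PTT is
        # the configured integer delay
        cfg = SubjectConfig(duration_s=20.0, noise_mv=0.0, drift_mv=0.0,
                            mains_mv=0.0, ectopic_rate=0.0, seed=6)
        c1, c2, truth = generate_subject(cfg)
        params = ThresholdParams()
        p1 = peak_indices(detect_events(c1, params))
        p2 = peak_indices(detect_events(c2, params))
        w = params.resolve_window(cfg.sample_rate_hz)
        p1 = p1[p1 >= w]
        p2 = p2[p2 >= w]
        pairs = pair_peaks(p1, p2, cfg.sample_rate_hz, max_lag_s=0.1)
        assert len(pairs) >= 15
        for p in pairs:
            assert p.ptt_s * cfg.sample_rate_hz == pytest.approx(
                truth.true_ptt_samples
            )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SubjectConfig(ectopic_rate=0.7)
        with pytest.raises(ValueError):
            SubjectConfig(transit_delay_samples=0)
        with pytest.raises(ValueError):
            SubjectConfig(pac_prematurity=1.5)
        with pytest.raises(ValueError):
            SubjectConfig(pvc_first_peak_ratio=0.3, second_peak_ratio=0.45)
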