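"""Pulse detector and summary statistics against constructed ground truth."""

import numpy as np
import pytest

from ddrsim.fixtures import SyntheticTraceSpec, make_p53_trace
from ddrsim.pulses import (
    Pulse,
    PulseError,
    detect_pulses,
    summarize_pulses,
    population_pulse_table,
    two_sample_t,
)


def trace(spec_kwargs):
    return make_p53_trace(SyntheticTraceSpec(**spec_kwargs))


class TestDetector:
    def test_constant_trace_has_no_pulses(self):
        t = np.arange(0, 1800, 5.0)
        assert detect_pulses(t, np.full_like(t, 30.0)) == []

    def test_trace_shorter_than_baseline_rejected(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(PulseError, match="baseline"):
            detect_pulses(t, np.full_like(t, 30.0), baseline_window=180.0)

    @pytest.mark.parametrize("shape", ["triangular", "gaussian"])
    def test_two_clean_bumps_recovered_with_exact_widths(self, shape):
        """Noise-free bumps of known FWHM are recovered within a grid step."""
        w1, w2 = 300.0, 420.0
        times, values, truth = trace(
            dict(baseline=25.0, noise_sd=0.0, peak_times=(600.0, 1400.0),
                 amplitudes=(200.0, 150.0), widths=(w1, w2), shape=shape)
        )
        pulses = detect_pulses(times, values, smooth_min=0.0)
        assert len(pulses) == 2
        for p, (tp, amp, w) in zip(pulses, [(600, 200, w1), (1400, 150, w2)]):
            assert p.peak_time == pytest.approx(tp, abs=5.0)
            assert p.amplitude == pytest.approx(amp, rel=0.05)
            assert p.width == pytest.approx(w, abs=10.0)

    def test_recovery_with_noise_and_smoothing(self):
        times, values, truth = trace(
            dict(baseline=25.0, noise_sd=5.0, peak_times=(600.0, 1400.0),
                 amplitudes=(200.0, 150.0), widths=(385.0, 385.0), seed=4)
        )
        pulses = detect_pulses(times, values)
        assert len(pulses) == 2
        assert pulses[0].width == pytest.approx(385.0, rel=0.15)

    def test_offset_invariance(self):
        times, values, _ = trace(
            dict(baseline=25.0, noise_sd=3.0, peak_times=(800.0,),
                 amplitudes=(180.0,), widths=(380.0,), seed=1)
        )
        base = detect_pulses(times, values)
        shifted = detect_pulses(times, values + 100.0)
        assert len(base) == len(shifted) == 1
        assert shifted[0].amplitude == pytest.approx(base[0].amplitude, rel=1e-6)
        assert shifted[0].width == pytest.approx(base[0].width, abs=5.0)

    def test_time_shift_equivariance(self):
        times, values, _ = trace(
            dict(baseline=25.0, noise_sd=3.0, peak_times=(800.0,),
                 amplitudes=(180.0,), widths=(380.0,), seed=2)
        )
        base = detect_pulses(times, values)
        moved = detect_pulses(times + 500.0, values)
        assert moved[0].peak_time == pytest.approx(base[0].peak_time + 500.0)
        assert moved[0].width == pytest.approx(base[0].width)

    def test_output_pulses_ordered_and_disjoint(self):
        times, values, _ = trace(
            dict(baseline=25.0, noise_sd=8.0,
                 peak_times=(350.0, 1000.0, 1650.0),
                 amplitudes=(150.0, 250.0, 120.0),
                 widths=(250.0, 300.0, 250.0), seed=3)
        )
        pulses = detect_pulses(times, values)
        for a, b in zip(pulses, pulses[1:]):
            assert a.peak_time < b.peak_time
            assert a.end <= b.start + 1e-9


class TestSummaries:
    def make_pulse(self, peak, width=400.0, amp=100.0):
        return Pulse(peak - width / 2, peak, peak + width / 2, amp, width)

    def test_identical_pulses_have_zero_cv(self):
        cells = [[self.make_pulse(500.0), self.make_pulse(1000.0)]] * 3
        s = summarize_pulses(cells)
        assert s.cv_amplitude == 0.0
        assert s.cv_interval == 0.0

    def test_hand_computed_width_statistics(self):
        """Widths 300/400/500 -> mean 400, SD 100 (sample SD convention)."""
        cells = [
            [self.make_pulse(500.0, width=300.0)],
            [self.make_pulse(500.0, width=400.0)],
            [self.make_pulse(500.0, width=500.0)],
        ]
        s = summarize_pulses(cells)
        assert s.mean_width == pytest.approx(400.0)
        assert s.sd_width == pytest.approx(100.0)

    def test_window_restricts_counts_but_not_widths(self):
        cells = [[self.make_pulse(500.0), self.make_pulse(2000.0)]]
        s = summarize_pulses(cells, window=960.0, t_ref=180.0)
        assert s.pulse_counts == (1,)
        assert s.mean_width == 400.0  # both pulses pooled for width

    def test_time_to_first_peak_relative_to_reference(self):
        cells = [[self.make_pulse(300.0), self.make_pulse(700.0)]]
        s = summarize_pulses(cells, t_ref=180.0)
        assert s.mean_time_to_first_peak == pytest.approx(120.0)

    def test_empty_input_rejected(self):
        with pytest.raises(PulseError):
            summarize_pulses([])

    def test_population_table_single_group(self):
        cells = [[self.make_pulse(500.0)]]
        df = population_pulse_table({5.0: cells})
        assert len(df) == 1
        assert df.iloc[0]["dose_gy"] == 5.0

    def test_welch_t_matches_closed_form(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.5, 3.5, 4.5, 5.5, 6.5]
        stat, p = two_sample_t(a, b)
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        assert stat == pytest.approx((ma - mb) / np.sqrt(va + vb))
        assert 0.0 < p < 1.0
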