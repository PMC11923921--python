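"""Beat metrics: detection counts, sub-frame timings, CaTD closed forms,
dominant frequency, inter-beat intervals and per-pixel maps."""

import math

import numpy as np
import pytest

import cardiomap as cm
from cardiomap.metrics import CATD_LEVELS
from cardiomap.sigproc import Trace
from cardiomap.synthdata import kernel_values


def kernel_train_trace(params, event_times, fs=50.0, duration=None):
    """Noise-free trace assembled directly from the transient kernel."""
    duration = duration or (max(event_times) + 2.0)
    t = np.arange(int(duration * fs)) / fs
    y = np.zeros_like(t)
    for te in event_times:
        y += kernel_values(params, t - te)
    return Trace(time_s=t, values=y / params.amplitude)


class TestDetectBeats:
    def test_three_transients_spaced_one_second(self):
        params = cm.WaveformParams(upstroke_duration_s=0.05, decay_tau_s=0.15)
        tr = kernel_train_trace(params, [1.0, 2.0, 3.0], fs=100.0)
        beats = cm.detect_beats(tr)
        assert len(beats) == 3
        spacing = np.diff([b.activation_time_s for b in beats])
        assert np.allclose(spacing, 1.0, atol=1e-3)

    def test_flat_trace_yields_no_beats(self):
        tr = Trace(time_s=np.arange(500) / 50.0, values=np.zeros(500))
        assert cm.detect_beats(tr) == []

    def test_beat_count_robust_at_snr8(self):
        """10 beats at 1 Hz in a 10-s SNR-8 recording, over many seeds."""
        params = cm.WaveformParams(upstroke_duration_s=0.05, decay_tau_s=0.3)
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tr0 = kernel_train_trace(params, np.arange(0.3, 10.0, 1.0), duration=10.0)
            noisy = tr0.values + rng.normal(0, 1 / 8, tr0.values.shape)
            tr = cm.condition_trace(1.0 + noisy, 50.0, polarity="up")
            if len(cm.detect_beats(tr)) == 10:
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.02, 0.05, 0.1])
        with pytest.raises(ValueError):
            Trace(time_s=t, values=np.zeros(4))

    def test_activation_precedes_peak(self, aggregate_trace):
        for b in cm.detect_beats(aggregate_trace):
            assert b.activation_time_s < b.peak_time_s


class TestUpstroke:
    def test_linear_ramp_gives_eighty_percent_of_rise(self):
        """A linear 0->1 rise over 0.1 s has a 10-90% time of 80 ms."""
        fs = 1000.0
        t = np.arange(int(3 * fs)) / fs
        y = np.clip((t - 1.0) / 0.1, 0, 1)
        y[t > 1.1] = np.exp(-(t[t > 1.1] - 1.1) / 0.5)
        tr = Trace(time_s=t, values=y)
        beats = cm.detect_beats(tr)
        assert len(beats) == 1
        assert beats[0].upstroke_s == pytest.approx(0.080, abs=1e-3)

    def test_smoothstep_upstroke_recovered_within_frame(self):
        """The generator's closed-form 10-90% time at 100 fps."""
        params = cm.WaveformParams(upstroke_duration_s=0.06, decay_tau_s=0.4)
        tr = kernel_train_trace(params, [1.0, 2.5], fs=100.0)
        beats = cm.detect_beats(tr)
        for b in beats:
            assert b.upstroke_s == pytest.approx(0.06, abs=0.01)

    def test_single_frame_rise_bounded_by_resolution(self):
        fs = 50.0
        t = np.arange(int(4 * fs)) / fs
        y = np.zeros_like(t)
        y[t >= 1.0] = np.exp(-(t[t >= 1.0] - 1.0) / 0.4)
        tr = Trace(time_s=t, values=y)
        beats = cm.detect_beats(tr)
        assert len(beats) == 1
        if beats[0].upstroke_s is not None:
            assert beats[0].upstroke_s <= 1.0 / fs + 1e-9


class TestCatd:
    def test_exponential_recovery_closed_forms(self):
        """Instantaneous rise, tau = 0.2 s: CaTD50 = tau ln 2, CaTD70 =
        tau ln(10/3), CaTD90 = tau ln 10, each within half a frame."""
        params = cm.WaveformParams(upstroke_duration_s=1e-4, decay_tau_s=0.2)
        tr = kernel_train_trace(params, [1.0, 3.0], fs=50.0, duration=5.0)
        beats = cm.detect_beats(tr)
        half_frame = 0.5 / 50.0 * 1000
        expected = {50: 138.63, 70: 240.79, 90: 460.52}
        for p, exp_ms in expected.items():
            assert beats[0].catd_ms[p] == pytest.approx(exp_ms, abs=half_frame)

    def test_encroached_recovery_flagged_undefined(self):
        """When the next activation arrives before the recovery level is
        crossed, CaTD is flagged undefined — and a trace that ends mid-decay
        leaves the last beat's CaTD90 undefined too."""
        params = cm.WaveformParams(upstroke_duration_s=0.02, decay_tau_s=0.4)
        tr = kernel_train_trace(params, [1.0, 3.0], fs=100.0, duration=3.8)
        beats = cm.detect_beats(tr)
        # explicit encroachment shortly after the peak
        assert cm.catd(beats[0], tr, 90, next_activation_s=beats[0].peak_time_s + 0.1) is None
        # trace ends 0.8 s after the last beat: 90% recovery (~0.92 s of
        # decay) is not reached before the recording stops
        assert 90 not in beats[-1].catd_ms
        assert 50 in beats[0].catd_ms

    def test_invalid_percentage_rejected(self, aggregate_trace):
        beats = cm.detect_beats(aggregate_trace)
        with pytest.raises(ValueError):
            cm.catd(beats[0], aggregate_trace, 0)
        with pytest.raises(ValueError):
            cm.catd(beats[0], aggregate_trace, 100)

    def test_catd_monotone_in_p(self, aggregate_trace):
        for b in cm.detect_beats(aggregate_trace):
            vals = [b.catd_ms[p] for p in CATD_LEVELS if p in b.catd_ms]
            assert vals == sorted(vals)


class TestIbi:
    def test_regular_rhythm(self):
        params = cm.WaveformParams(decay_tau_s=0.15)
        tr = kernel_train_trace(params, [1.0, 2.0, 3.0], fs=100.0)
        out = cm.ibi_series(cm.detect_beats(tr))
        assert out is not None
        _, mean, sd = out
        assert mean == pytest.approx(1.0, abs=2e-3)
        assert sd == pytest.approx(0.0, abs=2e-3)

    def test_alternating_intervals_population_sd(self):
        params = cm.WaveformParams(decay_tau_s=0.1)
        tr = kernel_train_trace(params, [1.0, 1.8, 3.0, 3.8, 5.0], fs=100.0)
        _, mean, sd = cm.ibi_series(cm.detect_beats(tr))
        assert mean == pytest.approx(1.0, abs=5e-3)
        assert sd == pytest.approx(0.2, abs=5e-3)

    def test_single_beat_undefined(self):
        params = cm.WaveformParams(decay_tau_s=0.15)
        tr = kernel_train_trace(params, [1.0], fs=100.0)
        assert cm.ibi_series(cm.detect_beats(tr)) is None


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        t = np.arange(500) / 50.0
        tr = Trace(time_s=t, values=np.sin(2 * np.pi * 1.0 * t))
        assert cm.dominant_frequency(tr) == pytest.approx(1.0, abs=0.02)

    def test_transient_train_snr8(self):
        params = cm.WaveformParams(upstroke_duration_s=0.05, decay_tau_s=0.25)
        errs = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            tr0 = kernel_train_trace(params, np.arange(0.2, 10.0, 1 / 1.5), duration=10.0)
            tr = cm.condition_trace(1 + tr0.values + rng.normal(0, 1 / 8, tr0.values.shape),
                                    50.0, polarity="up")
            errs.append(abs(cm.dominant_frequency(tr) - 1.5))
        assert np.median(errs) <= 0.05

    def test_too_short_for_band_rejected(self):
        t = np.arange(100) / 50.0
        tr = Trace(time_s=t, values=np.sin(2 * np.pi * t))
        with pytest.raises(ValueError, match="short"):
            cm.dominant_frequency(tr, band_hz=(0.2, 8.0))

    def test_amplitude_and_polarity_invariance(self, aggregate_video):
        """DF is unchanged by amplitude scaling and by polarity inversion
        followed by auto-correction."""
        stack, truth = aggregate_video
        rows, cols = np.nonzero(truth.footprint)
        raw = stack.frames[:, rows, cols].mean(1)
        df_ref = cm.dominant_frequency(cm.condition_trace(raw, 50.0))
        df_scaled = cm.dominant_frequency(cm.condition_trace(raw * 7.3, 50.0))
        df_flip = cm.dominant_frequency(
            cm.condition_trace(2 * np.median(raw) - raw, 50.0, polarity="auto")
        )
        assert df_scaled == df_ref
        assert df_flip == df_ref

    def test_reciprocity_with_ibi_on_periodic_input(self, aggregate_trace):
        df = cm.dominant_frequency(aggregate_trace)
        _, mean_ibi, _ = cm.ibi_series(cm.detect_beats(aggregate_trace))
        assert 0.98 <= df * mean_ibi <= 1.02


class TestMetricMaps:
    def test_synchronous_aggregate_maps_are_homogeneous(self, aggregate_video):
        stack, truth = aggregate_video
        maps = cm.metric_maps(stack, bin_factor=2)
        df_vals = maps.df_hz[np.isfinite(maps.df_hz)]
        assert df_vals.std() < 0.02
        assert maps.summary["df_hz"]["mean"] == pytest.approx(1.0, abs=0.02)
        c50 = maps.catd_ms[50]
        c50_vals = c50[np.isfinite(c50)]
        assert len(c50_vals) > 0.9 * maps.mask.n_valid
        assert np.median(np.abs(c50_vals - truth.catd_ms[50])) < 20.0

    def test_undefined_pixels_counted_not_zeroed(self, aggregate_video):
        stack, _ = aggregate_video
        maps = cm.metric_maps(stack, bin_factor=2)
        s = maps.summary["catd90_ms"]
        assert s["n_defined"] + s["n_undefined"] == maps.mask.n_valid
        # CaTD90 of a 0.35-s tail at 1 Hz is encroached: undefined, never 0
        assert not np.any(maps.catd_ms[90][np.isfinite(maps.catd_ms[90])] == 0.0)

    def test_empty_mask_rejected(self, aggregate_video):
        stack, _ = aggregate_video
        empty = cm.AnalysisMask(valid=np.zeros((64, 64), dtype=bool))
        with pytest.raises(ValueError, match="mask"):
            cm.metric_maps(stack, mask=empty, bin_factor=2)
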