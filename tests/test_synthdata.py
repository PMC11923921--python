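"""Generator correctness: closed-form waveform durations, capture logic,
wave geometry, perfusion forward model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardiomap as cm
from cardiomap.synthdata import analytic_catd_periodic, kernel_values


class TestWaveformKernel:
    @pytest.mark.parametrize(
        "p, expected_ms",
        [(50, 0.2 * math.log(2) * 1000), (70, 0.2 * math.log(10 / 3) * 1000),
         (90, 0.2 * math.log(10) * 1000)],
    )
    def test_instantaneous_rise_catd_closed_forms(self, p, expected_ms):
        """In the instantaneous-rise limit CaTD_p -> tau * ln(100/(100-p))."""
        params = cm.WaveformParams(upstroke_duration_s=1e-7, decay_tau_s=0.2)
        assert cm.analytic_catd(params, p) == pytest.approx(expected_ms, abs=0.01)

    def test_kernel_trace_matches_analytic_crossings(self):
        """Numeric level crossings of the sampled kernel agree with the
        closed-form CaTD (independent oracle: linear interpolation)."""
        params = cm.WaveformParams(upstroke_duration_s=0.04, decay_tau_s=0.3)
        t = np.arange(0, 3.0, 1e-4)
        values, catd = cm.waveform_kernel(params, t)
        for p, expect_ms in catd.items():
            level = (1 - p / 100) * params.amplitude
            after_peak = t > params.rise_time_s
            idx = np.argmax(values[after_peak] < level)
            ta = t[after_peak]
            crossing = np.interp(
                level,
                [values[after_peak][idx], values[after_peak][idx - 1]],
                [ta[idx], ta[idx - 1]],
            )
            assert crossing * 1000 == pytest.approx(expect_ms, abs=0.2)

    def test_zero_before_activation_and_peak_amplitude(self):
        params = cm.WaveformParams()
        t = np.linspace(-1, 2, 3001)
        v = kernel_values(params, t)
        assert np.all(v[t < 0] == 0)
        assert v.max() == pytest.approx(params.amplitude, rel=1e-3)

    def test_upstroke_fraction_of_smoothstep(self):
        """10->90% span of the cubic rise equals the configured upstroke."""
        params = cm.WaveformParams(upstroke_duration_s=0.1, decay_tau_s=1.0)
        t = np.linspace(0, params.rise_time_s, 200001)
        v = kernel_values(params, t)
        t10 = np.interp(0.1 * params.amplitude, v, t)
        t90 = np.interp(0.9 * params.amplitude, v, t)
        assert t90 - t10 == pytest.approx(0.1, abs=1e-5)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cm.WaveformParams(upstroke_duration_s=-0.1)
        with pytest.raises(ValueError):
            cm.WaveformParams(decay_tau_s=0.0)
        with pytest.raises(ValueError):
            cm.WaveformParams(upstroke_duration_s=0.5, refractory_period_s=0.1)

    @given(p=st.floats(1, 99), tau=st.floats(0.05, 1.0), period=st.floats(0.4, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_periodic_catd_below_isolated_and_converges(self, p, tau, period):
        """Tail superposition shortens CaTD relative to the isolated kernel,
        and the periodic form converges to it as the period grows."""
        params = cm.WaveformParams(upstroke_duration_s=0.02, decay_tau_s=tau)
        iso = cm.analytic_catd(params, p, reference="upslope")
        per = analytic_catd_periodic(params, p, period_s=period)
        if per is not None:
            assert per <= iso + 1e-9
        far = analytic_catd_periodic(params, p, period_s=1000.0)
        assert far == pytest.approx(iso, rel=1e-6)

    def test_ground_truth_catd_monotone_in_p(self):
        for period in (0.6, 1.0, 3.0, math.inf):
            params = cm.WaveformParams(upstroke_duration_s=0.05, decay_tau_s=0.3)
            vals = [analytic_catd_periodic(params, p, period_s=period) for p in (20, 50, 70, 90)]
            defined = [v for v in vals if v is not None]
            assert defined == sorted(defined)


class TestGenerateVideo:
    def test_refractory_0p8_at_3hz_blocks_stimuli(self):
        """A 0.8-s refractory period cannot follow 3-Hz pacing: only every
        third stimulus captures."""
        wave = cm.WaveformParams(decay_tau_s=0.15, refractory_period_s=0.8)
        proto = cm.PacingProtocol((cm.PacingSegment(0, 5, 3.0, "paced"),))
        scene = cm.SceneConfig(mode="aggregate", seed=0)
        _, truth = cm.generate_video(scene, wave, proto)
        assert truth.capture[0]["delivered"] == 15
        assert truth.capture[0]["ratio"] < 1.0
        assert truth.capture[0]["ratio"] == pytest.approx(1 / 3, abs=1e-9)

    def test_short_refractory_captures_every_stimulus(self):
        wave = cm.WaveformParams(decay_tau_s=0.15, refractory_period_s=0.2)
        proto = cm.PacingProtocol((cm.PacingSegment(0, 5, 3.0, "paced"),))
        scene = cm.SceneConfig(mode="aggregate", seed=0)
        _, truth = cm.generate_video(scene, wave, proto)
        assert truth.capture[0]["ratio"] == 1.0
        assert truth.df_hz[0] == pytest.approx(3.0, abs=1e-9)

    def test_monolayer_delay_is_distance_over_speed(self):
        """Pixels 1 mm apart activate 50 ms apart at 20 mm/s."""
        wave = cm.WaveformParams()
        proto = cm.PacingProtocol((cm.PacingSegment(0, 2, 1.0, "paced"),))
        scene = cm.SceneConfig(
            mode="monolayer", cv_mm_s=20.0, noise_sd=0.0, seed=0, pixel_size_mm=0.05
        )
        _, truth = cm.generate_video(scene, wave, proto)
        delays = truth.pixel_delays_s.reshape(128, 128)
        # 1 mm = 20 pixels along the first row from the (0, 0) origin
        assert delays[0, 20] - delays[0, 0] == pytest.approx(0.050, abs=1e-12)
        assert truth.cv_mm_s == 20.0

    def test_same_seed_bit_identical(self, basal_wave, basal_protocol):
        scene = cm.SceneConfig(mode="aggregate", noise_sd=0.1, seed=99)
        a, _ = cm.generate_video(scene, basal_wave, basal_protocol)
        b, _ = cm.generate_video(scene, basal_wave, basal_protocol)
        assert np.array_equal(a.frames, b.frames)

    def test_polarity_down_inverts_around_diastole(self, basal_wave, basal_protocol):
        up_scene = cm.SceneConfig(mode="aggregate", noise_sd=0.0, seed=1, polarity="up")
        dn_scene = cm.SceneConfig(mode="aggregate", noise_sd=0.0, seed=1, polarity="down")
        up, t_up = cm.generate_video(up_scene, basal_wave, basal_protocol)
        dn, _ = cm.generate_video(dn_scene, basal_wave, basal_protocol)
        inside = t_up.footprint
        mirrored = 2 * basal_wave.diastolic_level - dn.frames[:, inside]
        assert np.allclose(up.frames[:, inside], mirrored, atol=0.51)

    def test_protocol_longer_than_video_rejected(self, basal_wave, basal_protocol):
        scene = cm.SceneConfig(mode="aggregate", seed=0)
        with pytest.raises(ValueError, match="protocol"):
            cm.generate_video(scene, basal_wave, basal_protocol, n_frames=100)


class TestAggregateImage:
    def test_true_ferets(self):
        shapes = [
            cm.ShapeSpec((60, 60), "disc", 50),
            cm.ShapeSpec((200, 80), "square", 100),
            cm.ShapeSpec((80, 260), "ellipse", (120, 60)),
        ]
        _, ferets = cm.generate_aggregate_image(shapes, (400, 400))
        assert ferets == pytest.approx([100.0, 100 * math.sqrt(2), 120.0])

    def test_overlap_warns(self):
        shapes = [cm.ShapeSpec((50, 50), "disc", 30), cm.ShapeSpec((60, 60), "disc", 30)]
        with pytest.warns(UserWarning, match="overlap"):
            cm.generate_aggregate_image(shapes, (120, 120))

    def test_foreground_brighter_than_background(self):
        img, _ = cm.generate_aggregate_image([cm.ShapeSpec((40, 40), "disc", 20)], (80, 80))
        assert img.max() > img.min()


class TestSimulatePerfusion:
    def test_batch_constant_rate_closed_form(self):
        """D=0, mu=0: linear decline at q * X0 (in mM/day)."""
        t = np.linspace(0, 1, 11)
        s = cm.simulate_perfusion(-2.0, 1e6, 0.0, 0.0, 0.0, 10.0, t)
        assert np.allclose(s.conc_mM, 10.0 - 2.0 * t, rtol=1e-8)

    def test_washout_closed_form(self):
        """q=0, mu=0: C(t) = Cin + (C0 - Cin) e^(-Dt) to < 1e-6 relative."""
        t = np.linspace(0, 4, 21)
        s = cm.simulate_perfusion(0.0, 1e6, 0.0, 0.5, 20.0, 5.0, t)
        expect = 20.0 + (5.0 - 20.0) * np.exp(-0.5 * t)
        assert np.max(np.abs(s.conc_mM - expect) / expect) < 1e-6

    def test_matches_independent_rk4_oracle(self):
        """Adaptive integration agrees with a fixed-step RK4 at halved steps
        to < 0.1% (operating point: dilution 0.5/day)."""
        q, x0, mu, d, cin, c0 = -3.0, 0.27e6, 0.2, 0.5, 20.0, 20.0
        t_grid = np.linspace(0, 8, 9)

        def rhs(t, c):
            return q * x0 * np.exp(mu * t) * 1e-6 + d * (cin - c)

        def rk4(t_end, n):
            h = t_end / n
            c, t = c0, 0.0
            out = {0.0: c0}
            for _ in range(n):
                k1 = rhs(t, c)
                k2 = rhs(t + h / 2, c + h / 2 * k1)
                k3 = rhs(t + h / 2, c + h / 2 * k2)
                k4 = rhs(t + h, c + h * k3)
                c += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += h
                out[round(t, 10)] = c
            return out

        table = rk4(8.0, 8000)
        s = cm.simulate_perfusion(q, x0, mu, d, cin, c0, t_grid)
        for t, c in zip(t_grid, s.conc_mM):
            assert c == pytest.approx(table[round(float(t), 10)], rel=1e-3)

    def test_negative_concentration_reported_with_time(self):
        with pytest.raises(RuntimeError, match="at t ="):
            cm.simulate_perfusion(-3.0, 1e6, 0.2, 0.5, 20.0, 20.0, np.linspace(0, 10, 11))
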