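import numpy as np
import pytest

import cardiomap as cm


@pytest.fixture(scope="session")
def basal_wave():
    return cm.WaveformParams(
        upstroke_duration_s=0.05, decay_tau_s=0.35, refractory_period_s=0.3
    )


@pytest.fixture(scope="session")
def basal_protocol():
    """10 s of spontaneous beating at 1 Hz."""
    return cm.PacingProtocol((cm.PacingSegment(0.0, 10.0, 1.0, "basal"),))


@pytest.fixture(scope="session")
def aggregate_video(basal_wave, basal_protocol):
    """Noise-free spheroid movie: all pixels beat synchronously."""
    scene = cm.SceneConfig(mode="aggregate", noise_sd=0.0, seed=11)
    return cm.generate_video(scene, basal_wave, basal_protocol)


@pytest.fixture(scope="session")
def noisy_aggregate_video(basal_wave, basal_protocol):
    """SNR-8 spheroid movie (noise SD = amplitude / 8)."""
    scene = cm.SceneConfig(mode="aggregate", noise_sd=0.125, seed=12)
    return cm.generate_video(scene, basal_wave, basal_protocol)


@pytest.fixture(scope="session")
def monolayer_video(basal_wave):
    """Noise-free travelling wave at 20 mm/s, paced at 1 Hz for 5 s."""
    proto = cm.PacingProtocol((cm.PacingSegment(0.0, 5.0, 1.0, "paced"),))
    scene = cm.SceneConfig(mode="monolayer", cv_mm_s=20.0, noise_sd=0.0, seed=13)
    stack, truth = cm.generate_video(scene, basal_wave, proto)
    return stack, truth, proto


def global_conditioned_trace(stack, footprint):
    """Mask-mean trace conditioned with package defaults."""
    rows, cols = np.nonzero(footprint)
    raw = stack.frames[:, rows, cols].mean(axis=1)
    return cm.condition_trace(raw, stack.frame_rate_hz)


@pytest.fixture(scope="session")
def aggregate_trace(aggregate_video):
    stack, truth = aggregate_video
    return global_conditioned_trace(stack, truth.footprint)
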