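import numpy as np
import pytest

from aeye import (
    DistractorSpec,
    EyeAppearance,
    VideoClip,
    WaveformSpec,
    gen_trace,
    render_clip,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_clip(rng):
    """10 random 4×5 frames at 60 Hz."""
    frames = rng.uniform(0, 255, size=(10, 4, 5))
    return VideoClip(frames=frames, rate=60.0)


@pytest.fixture
def static_clip():
    """12 identical frames."""
    frame = np.full((6, 8), 120.0)
    return VideoClip(frames=np.repeat(frame[None], 12, axis=0), rate=60.0)


@pytest.fixture
def quiet_appearance():
    """Noise-free, evenly lit rendering parameters."""
    return EyeAppearance(sensor_noise_sd=0.0, illumination_gradient=0.0)


@pytest.fixture
def nystagmus_clip(quiet_appearance):
    """Short jerk-nystagmus clip at reduced resolution."""
    spec = WaveformSpec(kind="jerk_linear", n_beats=6, slow_phase_duration=200.0,
                        amplitude=2.0, onset=0.3)
    trace = gen_trace(spec, rate=60.0, duration=3.0, seed=5)
    return render_clip(trace, quiet_appearance, resolution=(60, 80), seed=5)
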