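import numpy as np
import pytest

from roipulse import RGBTrace, SimulationConfig


@pytest.fixture(scope="session")
def template():
    from roipulse import load_landmark_template

    return load_landmark_template()


@pytest.fixture()
def clean_config():
    """Noise-free 30 s recording at a constant 72 BPM."""
    return SimulationConfig(
        seed=0,
        white_sigma=0.0,
        drift_amplitude=0.0,
        burst_rate=0.0,
    )


def make_dichromatic_trace(
    hr_bpm: float = 72.0,
    fps: float = 30.0,
    duration: float = 30.0,
    baseline=(180.0, 120.0, 100.0),
    gains=(0.3, 0.7, 0.4),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RGBTrace:
    """Single-tone pulse riding on a constant skin color."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / fps)
    p = np.sin(2 * np.pi * (hr_bpm / 60.0) * t)
    samples = np.asarray(baseline) + p[:, None] * np.asarray(gains)
    if noise_sigma > 0:
        samples = samples + rng.normal(0, noise_sigma, samples.shape)
    return RGBTrace(fps, samples, np.ones(t.size, dtype=bool))


@pytest.fixture()
def dichromatic_trace():
    return make_dichromatic_trace()
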