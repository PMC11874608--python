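import numpy as np
import pytest

from coordlearn import OscillatorParams, SkillState


@pytest.fixture
def osc() -> OscillatorParams:
    return OscillatorParams()


@pytest.fixture
def short_osc() -> OscillatorParams:
    """Cheap 4-s oscillator for tests that only need a few cycles."""
    return OscillatorParams(duration=4.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


def sinusoid_pair(offset_deg: float, frequency: float = 1.0,
                  sample_rate: float = 60.0, duration: float = 10.0,
                  amplitude: float = 300.0):
    """Noiseless left/right sinusoids with a constant relative phase offset."""
    t = np.arange(int(round(duration * sample_rate))) / sample_rate
    left = amplitude * np.sin(2 * np.pi * frequency * t)
    right = amplitude * np.sin(2 * np.pi * frequency * t - np.radians(offset_deg))
    return t, left, right


@pytest.fixture
def skilled() -> SkillState:
    """A performer locked hard onto 90° (noiseless, strong coupling)."""
    return SkillState(target_phase=90.0, coupling_strength=50.0, noise_sd=0.0)
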