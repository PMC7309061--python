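import numpy as np
import pytest

from nits.session_io import AudioClip
from nits.synthetic import HEALTHY_PROFILE, random_subject, simulate_session


@pytest.fixture(scope="session")
def healthy_session():
    """One complete synthetic healthy session (all 16 task payloads)."""
    rng = np.random.default_rng(42)
    subject = random_subject("H01", 0, rng)
    return simulate_session(HEALTHY_PROFILE, subject, seed=42)


@pytest.fixture(scope="session")
def sine_clip():
    """One second of a 220 Hz tone at 48 kHz."""
    t = np.arange(48000) / 48000.0
    return AudioClip(samples=0.5 * np.sin(2 * np.pi * 220.0 * t), rate_hz=48000)


@pytest.fixture(scope="session")
def noise_clip():
    rng = np.random.default_rng(7)
    return AudioClip(samples=0.1 * rng.standard_normal(48000), rate_hz=48000)
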