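import numpy as np
import pytest

from voltwave import synth
from voltwave.types import TwoChannelTrace


@pytest.fixture(scope="session")
def heartbeat_artifact():
    """Heartbeat at 11 Hz with one harmonic, 20 ms cross-channel lag."""
    return synth.ArtifactSpec(
        heart_hz=11.0, n_harmonics=2, amp_gevi=(1.0, 0.5),
        amp_ref=(1.0, 0.5), phase_lag_s=(0.02, 0.02),
        slow_amp_gevi=0.0, slow_amp_ref=0.0,
        noise_sd_gevi=0.02, noise_sd_ref=0.02)


@pytest.fixture(scope="session")
def standard_trace(heartbeat_artifact):
    """The standard unmixing test condition: heartbeat artifact plus
    gamma-band (30-60 Hz) voltage, 60 s at 1 kHz."""
    osc = synth.OscillationSpec(bands=[(30.0, 60.0, 0.3)])
    trace, truth = synth.gen_trace(
        artifact=heartbeat_artifact, osc=osc, duration_s=60.0,
        rate_hz=1000.0, baseline=0.0, seed=11)
    return trace, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def white_noise_trace(rng):
    g = synth.band_limited_noise(rng, 60000, 1000.0, 1.0, 100.0)
    r = rng.standard_normal(60000)
    return TwoChannelTrace(g, r, 1000.0)
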