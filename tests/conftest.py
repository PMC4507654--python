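import numpy as np
import pytest

from oscibp.pipeline import process_recording
from oscibp.synthgen import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Noise-free, artifact-free simulator configuration."""
    return SynthConfig(seed=1, sensor_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    return generate_recording(clean_config, 0)


@pytest.fixture(scope="session")
def processed_clean(clean_recording):
    rec, _gt = clean_recording
    return process_recording(rec)


@pytest.fixture(scope="session")
def triangular_owe():
    """Symmetric triangular envelope: apex 3 mmHg at 100 mmHg, limbs to 140/60."""
    from oscibp.envelope import OWE, fit_spline

    cp = np.array([60.0, 70, 80, 90, 100, 110, 120, 130, 140])
    amp = 3.0 * (1.0 - np.abs(cp - 100.0) / 40.0)
    amp = np.maximum(amp, 1e-6)
    t = (140.0 - cp) / 2.5  # deflation clock: high pressure first
    return fit_spline(OWE(cp_knots=cp, amp_knots=amp, t_knots=t))
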