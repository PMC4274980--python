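import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from tvrf import (ModelCell, StimulusEnsemble, StimulusSpec, calibrate_cell,
                  gabor_strf, gen_stimulus, generate_spikes)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_ensemble():
    """Small white-noise ensemble: 3 channels, 200 bins, one segment."""
    r = np.random.default_rng(0)
    return StimulusEnsemble(spec=r.standard_normal((3, 200)), dt_s=0.01,
                            freqs_hz=[500.0, 1000.0, 2000.0])


@pytest.fixture(scope="session")
def speech_recording():
    """60 s speech-surrogate recording from a static Gabor cell.

    Shared across tests that need a realistic stimulus-response pair;
    9 channels x 12 lags at 5 ms bins, ~15 spikes/s.
    """
    ens = gen_stimulus(StimulusSpec("speech_surrogate", duration_s=60.0,
                                    dt_s=0.005, n_channels=9, seed=11))
    base = gabor_strf(9, 12)
    cell = ModelCell(filters=base)
    cell = calibrate_cell(cell, ens, target_rate_hz=15.0, target_z_sd=2.5)
    spikes = generate_spikes(cell, ens, seed=12)
    return ens, spikes, cell
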