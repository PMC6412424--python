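import numpy as np
import pytest

from ecgparafit import DetectorConfig, EcgSignal, generate_ecg


@pytest.fixture
def config():
    return DetectorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record():
    """20 clean beats at 75 bpm with exact ground truth."""
    return generate_ecg(fs=500.0, n_beats=20, rr_mean=0.8, rr_sd=0.02, seed=7)


@pytest.fixture
def gaussian_peak():
    """A single symmetric Gaussian bump; apex index is known exactly."""
    fs = 500.0
    t = np.arange(600) / fs
    apex = 300
    y = 0.8 * np.exp(-((t - t[apex]) ** 2) / (2 * 0.02**2))
    return EcgSignal(samples=y, fs=fs, record_id="gauss"), apex
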