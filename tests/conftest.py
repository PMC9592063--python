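import numpy as np
import pytest

from emg2prosody.signals import Contour, SignalTrack
from emg2prosody.synthgen import glottal_source


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_pulse_train(f0_hz: float, duration: float = 1.0, snr_db: float = 30.0,
                     fs: float = 44100.0, seed: int = 0) -> SignalTrack:
    """Constant-f0 synthetic voiced audio at a given SNR."""
    times = np.arange(0.0, duration, 0.005)
    contour = Contour(times, np.full(times.size, f0_hz), unit="Hz")
    src = glottal_source(contour, fs, seed=seed)
    p = np.mean(src.samples**2)
    noise_rng = np.random.default_rng(seed + 1)
    noise = np.sqrt(p * 10.0 ** (-snr_db / 10.0)) * noise_rng.standard_normal(
        src.n_samples
    )
    return SignalTrack(src.samples + noise, fs)


@pytest.fixture
def pulse_train_120():
    return make_pulse_train(120.0)
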