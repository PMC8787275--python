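import numpy as np
import pytest

from fractalbold.containers import UniformTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def white_noise_series(seed: int, n: int = 900, dt: float = 1.0) -> UniformTimeSeries:
    """Unit-variance Gaussian white noise, independent of the package's
    spectral synthesizer (plain rng draws)."""
    return UniformTimeSeries(np.random.default_rng(seed).standard_normal(n), dt)


def naive_periodogram_beta(values: np.ndarray, dt: float = 1.0,
                           f_min: float = 0.0) -> float:
    """Independent spectral-index oracle: full-length raw periodogram and an
    OLS fit of log power on log frequency (no Welch averaging, no taper)."""
    n = values.size
    x = values - values.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=dt)
    keep = (freqs > f_min) & (spec > 0) & (freqs > 0)
    slope = np.polyfit(np.log(freqs[keep]), np.log(spec[keep]), 1)[0]
    return -slope
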