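import numpy as np
import pytest

import critsig as cs


@pytest.fixture(scope="session")
def coin_avalanches_1e6():
    """Reflected fair-coin avalanches from a 1e6-flip run (fast, reused)."""
    return cs.stream_coin_flip_avalanches(10**6, seed=101)


@pytest.fixture(scope="session")
def small_network():
    """One 400-neuron topology shared across network tests."""
    params = cs.BrunelParams(n_neurons=400)
    return params, cs.build_network(params, seed=7)


def fractional_gaussian_walk(h: float, n: int, seed: int) -> np.ndarray:
    """Cumulative fractional Gaussian noise with Hurst index ``h``.

    Davies-Harte circulant embedding: exact fGn covariance, so the walk has
    genuine long-range (anti)persistence, unlike a Markov persistent walk
    whose memory dies within a few steps.
    """
    rng = np.random.default_rng(seed)
    k = np.arange(n + 1)
    gamma = 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h)
                   + np.abs(k - 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)
    m = len(row)
    z = rng.normal(size=m // 2 + 1) + 1j * rng.normal(size=m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    z[-1] = z[-1].real * np.sqrt(2)
    fgn = np.fft.irfft(z * np.sqrt(lam * m / 2))[:n]
    return np.cumsum(fgn)
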