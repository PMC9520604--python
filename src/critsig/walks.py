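"""Thresholded random-walk null models.

Two scalar stochastic processes serve as "no-interaction" surrogates for a
neural population: the reflected coin-flip walk (a fair or biased +/-1 walk
whose negative excursions are folded up) and a discrete Ornstein-Uhlenbeck
(AR(1)) process crossed with a threshold.  Either trace can be rendered into
a spike raster by activating a number of neurons proportional to the
instantaneous height above threshold.  These surrogates reproduce several
statistical signatures of criticality without any coupling between units,
which is exactly why they are interesting as null models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .types import Raster

__all__ = [
    "CoinFlipParams",
    "OUParams",
    "ThresholdRasterSpec",
    "WalkTrace",
    "simulate_coin_flip_walk",
    "simulate_ou",
    "walk_to_raster",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoinFlipParams:
    """+/-1 coin-flip walk: ``n_flips`` steps, heads (+1) with ``p_heads``."""

    n_flips: int
    p_heads: float = 0.5
    reflect: bool = True

    def __post_init__(self) -> None:
        if self.n_flips < 1:
            raise ValueError("n_flips must be >= 1")
        if not 0.0 <= self.p_heads <= 1.0:
            raise ValueError("p_heads must be in [0, 1]")


@dataclass(frozen=True)
class OUParams:
    """Discrete Ornstein-Uhlenbeck process.

    The update is ``x[t+1] = x[t] - eta*x[t] + (1-eta)*xi[t]`` with ``xi``
    i.i.d. Gaussian noise of standard deviation ``noise_scale``; ``eta`` is
    the per-step negative-feedback strength.  ``eta = 0`` degenerates to a
    pure random walk; ``eta`` close to 1 pins the process to the origin.
    """

    n_steps: int
    eta: float = 0.001
    noise_scale: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.eta > 1:
            raise ValueError("eta > 1 would overshoot the origin each step")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass(frozen=True)
class ThresholdRasterSpec:
    """How to render a scalar trace into a population raster.

    ``gain`` neurons are activated per unit of height above threshold
    (rounded half away from zero, clipped at ``n_neurons``).
    """

    n_neurons: int = 128
    gain: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


@dataclass
class WalkTrace:
    """A scalar time series produced by one of the walk generators."""

    values: np.ndarray
    dt: float = 1.0
    kind: str = "coin_flip"
    params_ref: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)

    def __len__(self) -> int:
        return len(self.values)


def coin_flip_steps(n_flips: int, p_heads: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_flips`` steps of +1 (heads) / -1 (tails)."""
    return np.where(rng.random(n_flips) < p_heads, 1, -1).astype(np.int64)


def simulate_coin_flip_walk(params: CoinFlipParams, seed: int) -> WalkTrace:
    """Cumulative +/-1 walk; if ``params.reflect``, the absolute value.

    For a +/-1 walk the sign is constant within each zero-to-zero excursion,
    so taking the absolute value of the cumulative sum is identical to
    flipping every negative excursion up, not merely equal in distribution.
    """
    rng = np.random.default_rng(seed)
    x = np.cumsum(coin_flip_steps(params.n_flips, params.p_heads, rng))
    if params.reflect:
        x = np.abs(x)
    return WalkTrace(values=x, kind="coin_flip",
                     params_ref=f"coin_flip(n={params.n_flips},p={params.p_heads},"
                                f"reflect={params.reflect})",
                     seed=seed)


def flips_to_walk(flips: str | list) -> WalkTrace:
    """Build the reflected walk for an explicit flip sequence like 'HHHTTT'."""
    steps = np.array([1 if str(f).upper() in ("H", "1", "+1") else -1 for f in flips])
    return WalkTrace(values=np.abs(np.cumsum(steps)), kind="coin_flip",
                     params_ref=f"explicit:{''.join(str(f) for f in flips)}")


def simulate_ou(params: OUParams, seed: int) -> WalkTrace:
    """Discrete OU trace ``x[t+1] = (1-eta)*(x[t] + xi[t])``, started at 0.

    The recurrence is the spec'd ``x - eta*x + (1-eta)*xi`` refactored; as an
    AR(1) with coefficient ``a = 1-eta`` its stationary variance is
    ``a^2 sigma^2 / (1 - a^2)`` for ``eta`` in (0, 1).
    """
    rng = np.random.default_rng(seed)
    a = 1.0 - params.eta
    xi = rng.normal(0.0, params.noise_scale, size=params.n_steps)
    # x[t] = a*x[t-1] + a*xi[t-1]  ->  IIR filter with b=[0, a], a=[1, -a]
    x = lfilter([0.0, a], [1.0, -a], xi)
    return WalkTrace(values=x, kind="ou",
                     params_ref=f"ou(n={params.n_steps},eta={params.eta},"
                                f"scale={params.noise_scale},thr={params.threshold})",
                     seed=seed)


def heights_above_threshold(values: np.ndarray, threshold: float, gain: float,
                            n_neurons: int | None = None) -> np.ndarray:
    """Integer activation counts: round-half-away-from-zero of gain*(x-thr)+."""
    excess = np.maximum(np.asarray(values, dtype=float) - threshold, 0.0)
    k = np.floor(gain * excess + 0.5).astype(np.int64)
    if n_neurons is not None:
        if k.max(initial=0) > n_neurons:
            logger.warning("drive heights exceed n_neurons=%d; clipping", n_neurons)
        k = np.minimum(k, n_neurons)
    return k


def walk_to_raster(trace: WalkTrace, spec: ThresholdRasterSpec,
                   threshold: float | None = None) -> Raster:
    """Render a trace into a binary raster.

    Per bin ``t``, ``k_t = round(gain * max(x_t - threshold, 0))`` distinct
    neurons chosen uniformly at random are set active.  ``threshold``
    defaults to 0 for coin-flip traces and to the OU threshold for OU traces
    (both zero by default).
    """
    if threshold is None:
        threshold = 0.0
    k = heights_above_threshold(trace.values, threshold, spec.gain, spec.n_neurons)
    rng = np.random.default_rng(spec.seed)
    n_bins = len(k)
    spikes = np.zeros((spec.n_neurons, n_bins), dtype=np.uint8)
    for t in np.flatnonzero(k):
        ids = rng.choice(spec.n_neurons, size=int(k[t]), replace=False)
        spikes[ids, t] = 1
    return Raster(spikes=spikes, bin_ms=trace.dt)
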