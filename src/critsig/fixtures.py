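"""Canned small inputs with known answers, generated programmatically.

These are the worked examples used throughout the tests and docs: the
five-neuron toy raster whose single avalanche has size 9 and duration 6,
the six-flip coin walk H,H,H,T,T,T, an exactly self-similar parabola
family (perfect shape collapse at gamma = 1.5), the equal-height tent
counter-example (no single gamma collapses it), and a joint
stimulus-response table whose mutual information is exactly 1.5 bits.
"""

from __future__ import annotations

import numpy as np

from .info import StimulusResponseTable
from .types import Raster
from .walks import WalkTrace, flips_to_walk

__all__ = ["make_fixture", "FIXTURES"]


def _toy_raster() -> Raster:
    # 5 neurons x 7 bins; silent first and last bins bracket a tent-shaped
    # avalanche with per-bin counts 1,2,3,2,1 (size 9, first-return time 6).
    counts = [0, 1, 2, 3, 2, 1, 0]
    spikes = np.zeros((5, 7), dtype=np.uint8)
    rng = np.random.default_rng(1)
    for t, c in enumerate(counts):
        if c:
            spikes[rng.choice(5, size=c, replace=False), t] = 1
    return Raster(spikes=spikes, bin_ms=1.0)


def _parabolas(gamma: float = 1.5, durations=(10, 20, 40)) -> dict:
    shapes = {}
    for T in durations:
        t = np.arange(1, T)
        u = t / T
        shapes[T] = T ** (gamma - 1.0) * 4.0 * u * (1.0 - u)
    return shapes


def _tents(peak: float = 5.0, rise: int = 2, durations=(10, 20, 40)) -> dict:
    # equal peak heights with a fixed rise time, so longer durations have
    # shallower decay slopes: the apex sits at a different fraction of each
    # duration and no single rescaling exponent can collapse the family
    shapes = {}
    for T in durations:
        t = np.arange(1, T, dtype=float)
        up = peak * t / rise
        down = peak * (T - t) / (T - rise)
        shapes[T] = np.minimum(up, down)
    return shapes


def _joint_mi_15() -> StimulusResponseTable:
    # joint counts [[10,0,0,0],[0,10,0,0],[0,0,5,5],[0,0,5,5]]:
    # H(R) = 2 bits, H(R|S) = 0.5 bits, MI = 1.5 bits exactly
    stimuli, responses = [], []
    joint = [[10, 0, 0, 0], [0, 10, 0, 0], [0, 0, 5, 5], [0, 0, 5, 5]]
    for s, row in enumerate(joint):
        for r, count in enumerate(row):
            stimuli.extend([s] * count)
            responses.extend([float(r)] * count)
    return StimulusResponseTable(stimuli=np.array(stimuli),
                                 responses=np.array(responses))


FIXTURES = {
    "toy_raster": _toy_raster,
    "coin6": lambda: flips_to_walk("HHHTTT"),
    "parabolas_gamma1.5": _parabolas,
    "tent_family": _tents,
    "joint_mi_1.5bits": _joint_mi_15,
}


def make_fixture(name: str):
    """Return a named fixture; unknown names raise with the available list."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
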