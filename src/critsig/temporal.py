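"""Temporal statistics: Hurst exponent, decay constants, branching ratio.

The Hurst exponent is estimated by windowed-standard-deviation scaling: the
series is partitioned into disjoint windows of length L, the within-window
standard deviations are averaged, and H is the log-log slope of that
average against L.  H ~ 0.5 marks a memoryless walk; H > 0.5 long-range
temporal correlations (persistence); H < 0.5 antipersistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Raster

__all__ = ["HurstEstimate", "DecayFit", "BranchingEstimate",
           "hurst_exponent", "fit_decay_constant", "branching_ratio_naive"]


@dataclass
class HurstEstimate:
    H: float
    window_lengths: np.ndarray
    mean_stds: np.ndarray


@dataclass
class DecayFit:
    tau_decay: float             # bins
    amplitude: float
    direction: str               # "growth" or "decay"
    fit_window: tuple[int, int]
    n_points: int


@dataclass
class BranchingEstimate:
    sigma: float
    n_pairs: int


def default_window_ladder(n: int, min_window: int = 8) -> np.ndarray:
    """Powers of two from ``min_window`` up to n // 8."""
    ladder = []
    L = min_window
    while L <= n // 8:
        ladder.append(L)
        L *= 2
    return np.array(ladder, dtype=np.int64)


def hurst_exponent(series, window_lengths=None,
                   min_window: int = 8) -> HurstEstimate:
    """Windowed-STD scaling estimate of the Hurst exponent.

    For each window length L the series is split into disjoint length-L
    segments (a trailing remainder is dropped), each segment's standard
    deviation is computed, and the segment values are averaged.  H is the
    least-squares slope of log(mean STD) versus log(L).
    """
    x = np.asarray(series, dtype=float)
    if window_lengths is None:
        window_lengths = default_window_ladder(len(x), min_window)
    window_lengths = np.asarray(window_lengths, dtype=np.int64)
    if len(window_lengths) < 3:
        raise ValueError("need at least 3 window sizes")
    if len(x) < 4 * window_lengths.max():
        raise ValueError("series too short for the largest window")
    mean_stds = np.empty(len(window_lengths))
    for i, L in enumerate(window_lengths):
        m = len(x) // L
        segs = x[:m * L].reshape(m, L)
        mean_stds[i] = segs.std(axis=1).mean()
    H, _ = np.polyfit(np.log(window_lengths), np.log(mean_stds), 1)
    return HurstEstimate(H=float(H), window_lengths=window_lengths,
                         mean_stds=mean_stds)


def fit_decay_constant(activity, fit_window: tuple[int, int] = (3, 40),
                       baseline: float | str = 0.0) -> DecayFit:
    """Exponential time constant of post-stimulus activity.

    With the default zero baseline this is a log-linear least-squares fit of
    ``A * exp(±t / tau)`` on the positive values in the window; the sign of
    the fitted slope gives the direction.  Invariant to uniform amplitude
    scaling.

    ``baseline="auto"`` (or an explicit asymptote value) instead fits the
    approach to a plateau, ``y(t) = C ± A * exp(-t / tau)``, with C taken
    as the mean of the last quarter of the window.  This is the form needed
    across a phase transition: amplified activity saturates at a ceiling
    and damped activity dies to zero, both with short time constants, while
    near the transition the approach to the asymptote is slow.  The
    direction reports whether activity approaches the asymptote from below
    (growth) or above (decay).
    """
    y = np.asarray(activity, dtype=float)
    lo, hi = fit_window
    hi = min(hi, len(y) - 1)
    if lo > hi:
        raise ValueError("fit window outside the activity trace")
    t = np.arange(lo, hi + 1)
    yw = y[lo:hi + 1]
    if baseline == "auto":
        tail = max(1, len(yw) // 4)
        c = float(yw[-tail:].mean())
        z = yw - c
        from_below = float(z[:max(1, len(z) // 4)].mean()) < 0
        mag = np.abs(z)
        z0 = float(mag[:2].mean())
        scale = max(c, float(yw.max(initial=0.0)), 1e-9)
        if z0 <= 0.02 * scale:
            # transient already over before the window: fast approach
            return DecayFit(tau_decay=1.0, amplitude=z0,
                            direction="growth" if from_below else "decay",
                            fit_window=(lo, hi), n_points=0)
        # fit only the informative initial segment, before the deviation
        # sinks into trial-averaging noise around the asymptote
        below = np.flatnonzero(mag < 0.05 * z0)
        end = int(below[0]) if len(below) else len(mag)
        sel = mag[:end] > 0
        if sel.sum() < 3:
            return DecayFit(tau_decay=1.0, amplitude=z0,
                            direction="growth" if from_below else "decay",
                            fit_window=(lo, hi), n_points=int(sel.sum()))
        slope, intercept = np.polyfit(t[:end][sel], np.log(mag[:end][sel]), 1)
        tau = np.inf if slope == 0 else 1.0 / abs(slope)
        return DecayFit(tau_decay=float(tau), amplitude=float(np.exp(intercept)),
                        direction="growth" if from_below else "decay",
                        fit_window=(lo, hi), n_points=int(sel.sum()))
    c = float(baseline)
    z = yw - c
    pos = z > 0
    if pos.sum() < 3:
        raise ValueError("fewer than 3 positive points in the fit window")
    slope, intercept = np.polyfit(t[pos], np.log(z[pos]), 1)
    tau = np.inf if slope == 0 else 1.0 / abs(slope)
    return DecayFit(tau_decay=float(tau), amplitude=float(np.exp(intercept)),
                    direction="growth" if slope > 0 else "decay",
                    fit_window=(lo, hi), n_points=int(pos.sum()))


def branching_ratio_naive(raster) -> BranchingEstimate:
    """Naive branching ratio: mean of A(t+1)/A(t) over bins with A(t) > 0.

    ``raster`` may be a :class:`~critsig.types.Raster` or a 1-D population
    activity vector.  Sub-sampling corrections are deliberately not applied.
    """
    A = raster.activity() if isinstance(raster, Raster) else \
        np.asarray(raster, dtype=float)
    if len(A) < 2:
        raise ValueError("need at least 2 bins")
    anc = A[:-1]
    desc = A[1:]
    mask = anc > 0
    if not mask.any():
        raise ValueError("no active ancestor bins")
    ratios = desc[mask] / anc[mask]
    return BranchingEstimate(sigma=float(ratios.mean()), n_pairs=int(mask.sum()))
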