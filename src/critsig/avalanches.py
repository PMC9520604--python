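"""Avalanche extraction and the criticality statistics battery.

An avalanche is a contiguous run of time bins with nonzero population
activity, bracketed by silent bins.  Its height profile is the per-bin
population count, its size S the summed profile, and its duration T the
first-return time: the number of steps from leaving silence to returning to
it (one more than the number of active bins).  This convention makes raster
avalanches and zero-to-zero excursions of a reflected random walk exactly
interchangeable — the six-flip walk H,H,H,T,T,T with heights 1,2,3,2,1,0 is
one avalanche of size 9 and duration 6 — and it is the convention under
which the analytic fair-coin first-return exponents (tau -> 4/3,
alpha -> 3/2, gamma -> 3/2) apply.

The battery on top: truncated power-law fits of sizes and durations
(:func:`critsig.powerlaw.fit_power_law`), the size-duration scaling
exponent gamma, the crackling-noise exponent relation
``(alpha-1)/(tau-1) = gamma``, and avalanche shape collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .powerlaw import PowerLawFit, fit_power_law  # noqa: F401  (re-export)
from .types import InsufficientDataError, Raster
from .walks import WalkTrace, coin_flip_steps

__all__ = [
    "Avalanche", "AvalancheSet", "ExponentTriplet", "CollapseResult",
    "GammaFit", "extract_avalanches", "walk_to_avalanches",
    "stream_coin_flip_avalanches", "size_duration_scaling",
    "exponent_relation", "average_shapes", "shape_collapse",
    "fit_power_law", "PowerLawFit",
]

logger = logging.getLogger(__name__)


@dataclass
class Avalanche:
    heights: np.ndarray          # per-bin active counts, all >= 1
    start_bin: int = 0

    @property
    def duration(self) -> int:
        """First-return time: active bins plus the returning silent step."""
        return len(self.heights) + 1

    @property
    def size(self) -> float:
        return float(np.sum(self.heights))


@dataclass
class AvalancheSet:
    """Sizes, durations and (optionally) height profiles of many avalanches.

    Very long simulations keep only per-duration running shape sums
    (``shape_sums``/``shape_counts``) instead of every profile.
    """

    sizes: np.ndarray
    durations: np.ndarray
    shapes: list | None = None
    starts: np.ndarray | None = None
    bin_ms: float = 1.0
    source: str = ""
    shape_sums: dict | None = None
    shape_counts: dict | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.durations = np.asarray(self.durations, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass
class ExponentTriplet:
    tau: float
    alpha: float
    gamma: float
    predicted_gamma: float
    relation_error: float        # percent


@dataclass
class GammaFit:
    gamma: float
    t_min: int
    t_max: int
    n_durations: int


@dataclass
class CollapseResult:
    gamma_used: float
    collapse_error: float
    shapes: dict
    gamma_grid: np.ndarray | None = None
    errors: np.ndarray | None = None


def _active_runs(active: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open runs of True in a boolean vector."""
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def extract_avalanches(raster: Raster, keep_shapes: bool = True) -> AvalancheSet:
    """Avalanches from a binary raster.

    Maximal runs of bins with nonzero column sum, delimited by silent bins;
    runs touching either raster edge are discarded because they are not
    bracketed by silence.
    """
    counts = raster.activity()
    runs = [(s, e) for s, e in _active_runs(counts > 0)
            if s > 0 and e < raster.n_bins]
    sizes = np.array([counts[s:e].sum() for s, e in runs], dtype=np.int64)
    durations = np.array([e - s + 1 for s, e in runs], dtype=np.int64)
    starts = np.array([s for s, _ in runs], dtype=np.int64)
    shapes = [counts[s:e].copy() for s, e in runs] if keep_shapes else None
    return AvalancheSet(sizes=sizes, durations=durations, shapes=shapes,
                        starts=starts, bin_ms=raster.bin_ms, source="raster")


def walk_to_avalanches(trace: WalkTrace, keep_shapes: bool = True) -> AvalancheSet:
    """Zero-to-zero excursions of a reflected (non-negative) trace.

    The walk is taken to start at the origin, so the first excursion counts;
    a final excursion that never returns to zero is discarded.
    """
    x = np.asarray(trace.values)
    if len(x) and x.min() < 0:
        raise ValueError("trace has negative values; reflect it first")
    zeros = np.concatenate(([-1], np.flatnonzero(x == 0)))
    csum = np.concatenate(([0], np.cumsum(x)))
    sizes, durations, starts, shapes = [], [], [], []
    for z0, z1 in zip(zeros[:-1], zeros[1:]):
        if z1 - z0 < 2:          # adjacent zeros: no excursion
            continue
        durations.append(z1 - z0)
        sizes.append(csum[z1 + 1] - csum[z0 + 1])
        starts.append(z0 + 1)
        if keep_shapes:
            shapes.append(x[z0 + 1:z1].copy())
    return AvalancheSet(sizes=np.array(sizes, dtype=np.int64),
                        durations=np.array(durations, dtype=np.int64),
                        shapes=shapes if keep_shapes else None,
                        starts=np.array(starts, dtype=np.int64),
                        bin_ms=trace.dt, source=f"walk:{trace.kind}")


def stream_coin_flip_avalanches(n_flips: int, p_heads: float = 0.5,
                                seed: int = 0, chunk_size: int = 2**23,
                                shape_max_duration: int = 64) -> AvalancheSet:
    """Avalanches of a reflected coin-flip walk, computed in chunks.

    Equivalent to ``walk_to_avalanches(simulate_coin_flip_walk(...))`` but
    never materialises the full trace, so billions of flips fit in memory.
    Height profiles are accumulated as per-duration sums for durations up to
    ``shape_max_duration`` (enough for shape collapse) rather than stored
    individually.
    """
    rng = np.random.default_rng(seed)
    sizes: list[int] = []
    durations: list[int] = []
    shape_sums: dict[int, np.ndarray] = {}
    shape_counts: dict[int, int] = {}

    pos = 0                       # signed walk position
    abs_carry = 0                 # cumulative |x| before this chunk
    last_zero_g = -1              # global index of last visit to the origin
    last_zero_abs = 0             # cumulative |x| at that visit
    pending: np.ndarray | None = np.empty(0, dtype=np.int64)  # heights since last zero
    offset = 0

    while offset < n_flips:
        m = min(chunk_size, n_flips - offset)
        x = pos + np.cumsum(coin_flip_steps(m, p_heads, rng))
        a = np.abs(x)
        acs = abs_carry + np.cumsum(a)
        zlocal = np.flatnonzero(x == 0)
        seg_start = 0
        for z in zlocal:
            g = offset + int(z)
            T = g - last_zero_g
            S = int(acs[z]) - last_zero_abs
            durations.append(T)
            sizes.append(S)
            if T <= shape_max_duration and pending is not None:
                heights = np.concatenate((pending, a[seg_start:z]))
                acc = shape_sums.get(T)
                if acc is None:
                    shape_sums[T] = heights.astype(np.int64)
                    shape_counts[T] = 1
                else:
                    acc += heights
                    shape_counts[T] += 1
            last_zero_g, last_zero_abs = g, int(acs[z])
            seg_start = int(z) + 1
            pending = np.empty(0, dtype=np.int64)
        # carry the unfinished excursion into the next chunk
        if pending is not None:
            tail = a[seg_start:]
            if len(pending) + len(tail) <= shape_max_duration:
                pending = np.concatenate((pending, tail))
            else:
                pending = None    # too long for shape bookkeeping
        pos = int(x[-1])
        abs_carry = int(acs[-1])
        offset += m

    return AvalancheSet(sizes=np.array(sizes, dtype=np.int64),
                        durations=np.array(durations, dtype=np.int64),
                        shapes=None, bin_ms=1.0,
                        source=f"coin_flip(p={p_heads},n={n_flips})",
                        shape_sums=shape_sums, shape_counts=shape_counts)


def size_duration_scaling(avs: AvalancheSet, t_min: int | None = None,
                          t_max: int | None = None,
                          min_count: int = 10) -> GammaFit:
    """Fit <S>(T) ~ T**gamma by least squares on log-log axes.

    Mean size is computed per exact duration; duration classes with fewer
    than ``min_count`` avalanches are dropped (set ``min_count=1`` to keep
    all).
    """
    T = avs.durations
    S = avs.sizes
    uniq, inv, counts = np.unique(T, return_inverse=True, return_counts=True)
    mean_s = np.bincount(inv, weights=S.astype(float)) / counts
    keep = counts >= min_count
    if t_min is not None:
        keep &= uniq >= t_min
    if t_max is not None:
        keep &= uniq <= t_max
    uniq, mean_s = uniq[keep], mean_s[keep]
    if len(uniq) < 2:
        raise InsufficientDataError("need >= 2 duration classes", n_tail=len(uniq))
    slope, _ = np.polyfit(np.log(uniq), np.log(mean_s), 1)
    return GammaFit(gamma=float(slope), t_min=int(uniq.min()),
                    t_max=int(uniq.max()), n_durations=len(uniq))


def exponent_relation(tau: float, alpha: float,
                      gamma: float | None = None) -> ExponentTriplet:
    """Crackling-noise exponent relation (alpha-1)/(tau-1) = gamma.

    Returns the predicted gamma and, when a fitted ``gamma`` is supplied,
    the percent discrepancy |predicted - gamma| / gamma * 100.
    """
    if tau == 1.0:
        raise ZeroDivisionError("tau = 1 makes the exponent relation undefined")
    predicted = (alpha - 1.0) / (tau - 1.0)
    if gamma is None:
        return ExponentTriplet(tau, alpha, np.nan, predicted, np.nan)
    err = abs(predicted - gamma) / gamma * 100.0
    return ExponentTriplet(tau, alpha, gamma, predicted, err)


def average_shapes(avs: AvalancheSet, durations=None,
                   min_count: int = 20) -> dict[int, np.ndarray]:
    """Mean height profile per exact duration.

    Duration-1 avalanches carry no profile under the first-return convention
    used here (duration 2 is the shortest with one active bin) and duration
    classes with fewer than ``min_count`` members are skipped with a log
    message.
    """
    out: dict[int, np.ndarray] = {}
    if avs.shape_sums is not None:
        pool = {T: (avs.shape_sums[T], avs.shape_counts[T]) for T in avs.shape_sums}
        for T in sorted(pool) if durations is None else durations:
            if T not in pool:
                logger.info("no avalanches of duration %d", T)
                continue
            s, c = pool[T]
            if c < min_count:
                logger.info("duration %d has only %d avalanches (< %d); skipped",
                            T, c, min_count)
                continue
            out[int(T)] = s / c
        return out
    if avs.shapes is None:
        raise ValueError("AvalancheSet carries no shape information")
    by_T: dict[int, list] = {}
    for shape, T in zip(avs.shapes, avs.durations):
        by_T.setdefault(int(T), []).append(np.asarray(shape, dtype=float))
    for T in sorted(by_T) if durations is None else durations:
        group = by_T.get(int(T))
        if not group:
            logger.info("no avalanches of duration %d", T)
            continue
        if len(group) < min_count:
            logger.info("duration %d has only %d avalanches (< %d); skipped",
                        T, len(group), min_count)
            continue
        out[int(T)] = np.mean(group, axis=0)
    return out


def shape_collapse(shapes: dict[int, np.ndarray], gamma: float | None = None,
                   grid_points: int = 50,
                   gamma_grid: np.ndarray | None = None) -> CollapseResult:
    """Rescale mean profiles onto a common [0, 1] grid and score the collapse.

    Time is rescaled to t/T, height by T**(gamma-1); the collapse error is
    the across-duration variance averaged over the grid, normalised by the
    squared mean rescaled height.  When ``gamma`` is omitted it is chosen to
    minimise the collapse error over ``gamma_grid``.
    """
    if len(shapes) < 3:
        raise InsufficientDataError("need >= 3 duration classes for collapse",
                                    n_tail=len(shapes))
    grid = (np.arange(grid_points) + 0.5) / grid_points
    interped = {}
    for T, profile in shapes.items():
        profile = np.asarray(profile, dtype=float)
        m = len(profile)
        # anchor the profile at zero on both sides: avalanches are bracketed
        # by silent bins, so the height vanishes at t/T = 0 and 1
        xs = np.arange(m + 2) / (m + 1.0)
        vals = np.concatenate(([0.0], profile, [0.0]))
        interped[T] = np.interp(grid, xs, vals)

    def error_at(gm: float) -> float:
        scaled = np.array([interped[T] / float(T) ** (gm - 1.0) for T in interped])
        var = scaled.var(axis=0).mean()
        mean = scaled.mean()
        return float(var / mean**2) if mean != 0 else np.inf

    if gamma is not None:
        return CollapseResult(gamma_used=float(gamma),
                              collapse_error=error_at(float(gamma)),
                              shapes=dict(shapes))
    if gamma_grid is None:
        gamma_grid = np.arange(1.0, 2.5 + 1e-9, 0.01)
    errs = np.array([error_at(gm) for gm in gamma_grid])
    best = int(np.argmin(errs))
    return CollapseResult(gamma_used=float(gamma_grid[best]),
                          collapse_error=float(errs[best]),
                          shapes=dict(shapes), gamma_grid=gamma_grid, errors=errs)
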