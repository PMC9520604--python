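"""Figure-level experiments: sweeps, ablations, attribution, classification.

Each experiment sweeps the inhibition ratio ``g`` (the control parameter)
and measures order parameters and information quantities.  Full-scale
presets reproduce the headline numbers (decay-constant peak at g ~ 2.99 for
N = 8000; MI-peak asymptote g ~ 2.95 across sizes); desk-scale presets use
smaller networks, sparser grids and fewer trials so the qualitative
structure — the coincidence of the temporal-correlation and mutual-
information peaks near g ~ 3, their degradation under noise and their
disappearance without connectivity — can be checked in minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import avalanches as av
from .info import InfoResult, StimulusResponseTable, entropies
from .network import (BrunelParams, NoiseDriveSpec, StimulusProtocol,
                      build_network, run_trials)
from .temporal import fit_decay_constant
from .types import InsufficientDataError

__all__ = [
    "SweepResult", "AsymptoteFit", "SystemClass",
    "phase_and_decay_sweep", "mi_sweep", "noise_sweep",
    "entropy_attribution", "connectivity_ablation", "classify_system",
    "fit_peak_asymptote", "mi_for_condition",
]

logger = logging.getLogger(__name__)


@dataclass
class SweepResult:
    g_values: np.ndarray
    table: pd.DataFrame          # one row per g; columns per measurement
    peak_g: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class AsymptoteFit:
    sizes: np.ndarray
    peak_gs: np.ndarray
    asymptote: float
    ci95: tuple[float, float]
    params: tuple = ()           # (g_inf, c, lam)


@dataclass
class SystemClass:
    label: str
    evidence: dict


def _seed_for(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 for a hierarchical key."""
    ss = np.random.SeedSequence([seed, *key])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _avg_activity(connectivity, params, n_trials, stim_frac, t_stim,
                  duration_bins, noise, seed):
    mags = np.full(n_trials, int(round(stim_frac * params.n_neurons)))
    act = run_trials(connectivity, params, duration_bins,
                     stim_magnitudes=mags, t_stim=t_stim, noise=noise,
                     seed=seed)
    return act.mean(axis=0)


def phase_and_decay_sweep(params: BrunelParams, g_grid, n_trials: int = 30,
                          stim_frac: float = 0.32, t_stim: int = 1,
                          duration_bins: int = 60,
                          fit_window: tuple[int, int] = (3, 40),
                          noise: NoiseDriveSpec | None = None,
                          seed: int = 0) -> SweepResult:
    """Firing rate and post-stimulus decay constant as functions of g.

    One topology (from ``seed``) is reused across the whole grid so the
    sweep isolates the effect of the control parameter.  The decay constant
    is fit to the trial-averaged post-stimulus activity on ``fit_window``
    bins after the stimulus; its argmax over the grid locates the phase
    transition.
    """
    g_grid = np.sort(np.asarray(g_grid, dtype=float))
    conn = build_network(params, seed=_seed_for(seed, 0))
    rows = []
    for gi, g in enumerate(g_grid):
        p = params.with_g(g)
        try:
            mean_act = _avg_activity(conn, p, n_trials, stim_frac, t_stim,
                                     duration_bins, noise,
                                     _seed_for(seed, 1, gi))
            post = mean_act[t_stim:]
            rate = post.sum() / (len(post) * p.n_neurons)
            # 2-bin boxcar removes the period-2 alternation that the
            # one-bin refractory period imprints on saturated activity
            smooth = np.convolve(post, [0.5, 0.5], mode="valid")
            fit = fit_decay_constant(smooth, fit_window, baseline="auto")
            rows.append({"g": g, "firing_rate": rate,
                         "tau_decay": fit.tau_decay,
                         "direction": fit.direction})
        except ValueError as exc:
            logger.warning("g=%.3f skipped: %s", g, exc)
            rows.append({"g": g, "firing_rate": np.nan,
                         "tau_decay": np.nan, "direction": "undefined"})
    table = pd.DataFrame(rows)
    taus = table["tau_decay"].to_numpy()
    peak_g = (float(table["g"].iloc[int(np.nanargmax(taus))])
              if np.isfinite(taus).any() else None)
    return SweepResult(g_values=g_grid, table=table, peak_g=peak_g,
                       meta={"n_trials": n_trials, "stim_frac": stim_frac,
                             "n_neurons": params.n_neurons})


def mi_for_condition(connectivity, params: BrunelParams,
                     protocol: StimulusProtocol,
                     noise: NoiseDriveSpec | None = None, seed: int = 0,
                     duration_bins: int | None = None,
                     n_bins: int | None = None,
                     edges: np.ndarray | None = None
                     ) -> tuple[InfoResult, StimulusResponseTable]:
    """MI between stimulus level and response for one network and one g.

    The response is the mean population count over the protocol's readout
    window (bins 3-5 after the stimulus by default).
    """
    levels = protocol.magnitudes(params.n_neurons)
    mags = np.repeat(levels, protocol.n_trials)
    w0, w1 = protocol.response_window
    if duration_bins is None:
        duration_bins = protocol.t_stim + w1 + 15
    act = run_trials(connectivity, params, duration_bins,
                     stim_magnitudes=mags, t_stim=protocol.t_stim,
                     noise=noise, seed=seed)
    # 2-bin boxcar cancels the period-2 refractory alternation, which would
    # otherwise make saturated responses spuriously stimulus-dependent
    smooth = 0.5 * (act[:, :-1] + act[:, 1:])
    resp = smooth[:, protocol.t_stim + w0:protocol.t_stim + w1 + 1].mean(axis=1)
    table = StimulusResponseTable(stimuli=mags, responses=resp)
    if n_bins is None:
        n_bins = len(levels)
    return entropies(table, n_bins=n_bins, edges=edges), table


def mi_sweep(params: BrunelParams, g_grid, sizes=None, n_models: int = 5,
             protocol: StimulusProtocol | None = None,
             noise: NoiseDriveSpec | None = None, seed: int = 0,
             fit_asymptote: bool = True
             ) -> tuple[dict[int, SweepResult], AsymptoteFit | None]:
    """MI(g) per network size, with across-model spread and peak location.

    For each size, ``n_models`` independent topologies are swept over the
    grid; the across-model mean MI determines the peak g.  When more than
    one size is given the peak locations are fit with a saturating
    exponential ``g_peak(N) = g_inf - c * exp(-N / lam)`` whose asymptote
    estimates the infinite-size transition point.
    """
    g_grid = np.sort(np.asarray(g_grid, dtype=float))
    if sizes is None:
        sizes = [params.n_neurons]
    protocol = protocol or StimulusProtocol()
    results: dict[int, SweepResult] = {}
    for size in sizes:
        p_size = replace(params, n_neurons=int(size))
        conns = [build_network(p_size, seed=_seed_for(seed, size, m))
                 for m in range(n_models)]
        mi = np.zeros((n_models, len(g_grid)))
        h_r = np.zeros_like(mi)
        for m, conn in enumerate(conns):
            for gi, g in enumerate(g_grid):
                res, _ = mi_for_condition(conn, p_size.with_g(g), protocol,
                                          noise=noise,
                                          seed=_seed_for(seed, size, m, gi))
                mi[m, gi] = res.MI
                h_r[m, gi] = res.H_R
        mean_mi = mi.mean(axis=0)
        table = pd.DataFrame({"g": g_grid, "mi_mean": mean_mi,
                              "mi_std": mi.std(axis=0),
                              "h_r_mean": h_r.mean(axis=0),
                              "h_r_std": h_r.std(axis=0)})
        peak_g = float(g_grid[int(np.argmax(mean_mi))])
        spread = mean_mi.max() - np.median(mean_mi)
        no_peak = mean_mi.max() <= 0 or spread < mi.std(axis=0).mean()
        results[int(size)] = SweepResult(
            g_values=g_grid, table=table,
            peak_g=None if no_peak else peak_g,
            meta={"n_models": n_models, "no_peak": bool(no_peak),
                  "peak_mi": float(mean_mi.max())})
    asym = None
    if fit_asymptote and len(sizes) >= 3:
        pts = [(s, r.peak_g) for s, r in results.items() if r.peak_g is not None]
        if len(pts) >= 3:
            asym = fit_peak_asymptote(np.array([p[0] for p in pts], dtype=float),
                                      np.array([p[1] for p in pts]))
    return results, asym


def fit_peak_asymptote(sizes: np.ndarray, peak_gs: np.ndarray) -> AsymptoteFit:
    """Saturating-exponential fit of peak location versus network size."""

    def model(N, g_inf, c, lam):
        return g_inf - c * np.exp(-N / lam)

    p0 = (float(peak_gs.max()), max(float(peak_gs.max() - peak_gs.min()), 0.1),
          float(np.median(sizes)))
    popt, pcov = curve_fit(model, sizes, peak_gs, p0=p0, maxfev=20000,
                           bounds=([0, 0, 1], [10, 10, 1e6]))
    se = float(np.sqrt(np.abs(pcov[0, 0])))
    g_inf = float(popt[0])
    return AsymptoteFit(sizes=sizes, peak_gs=peak_gs, asymptote=g_inf,
                        ci95=(g_inf - 1.96 * se, g_inf + 1.96 * se),
                        params=tuple(float(v) for v in popt))


def noise_sweep(params: BrunelParams, g_grid,
                p_spont_values=(0.001, 0.01, 0.1, 0.5),
                n_driven_values=(10, 100, 500, 1000),
                protocol: StimulusProtocol | None = None,
                n_models: int = 3, seed: int = 0) -> dict[str, SweepResult]:
    """MI(g) and H_R(g) under increasing uncorrelated and correlated noise.

    Returns one SweepResult per condition, keyed ``"none"``,
    ``"p_spont=..."`` and ``"n_driven=..."``.  Peak MI is expected to fall
    monotonically with either noise strength; strong correlated drive keeps
    H_R elevated even deep in the inactive phase.
    """
    conditions: list[tuple[str, NoiseDriveSpec]] = [("none", NoiseDriveSpec())]
    for p_s in p_spont_values:
        conditions.append((f"p_spont={p_s}",
                           NoiseDriveSpec(mode="uncorrelated", p_spont=p_s)))
    for n_d in n_driven_values:
        conditions.append((f"n_driven={n_d}",
                           NoiseDriveSpec(mode="correlated",
                                          n_driven=int(n_d))))
    out: dict[str, SweepResult] = {}
    for ci, (name, spec) in enumerate(conditions):
        res, _ = mi_sweep(params, g_grid, sizes=[params.n_neurons],
                          n_models=n_models, protocol=protocol, noise=spec,
                          seed=_seed_for(seed, 7, ci), fit_asymptote=False)
        sweep = res[params.n_neurons]
        sweep.meta["condition"] = name
        out[name] = sweep
    return out


def entropy_attribution(params: BrunelParams, g_grid=None,
                        protocol: StimulusProtocol | None = None,
                        noise: NoiseDriveSpec | None = None,
                        seed: int = 0, mode: str = "peak",
                        n_models: int = 5) -> dict:
    """Share of response entropy reproduced without internal connections.

    The connected (default-density) and fully disconnected versions of the
    same network receive identical correlated drive and stimulation (same
    seeds), and each condition's responses pass through the same readout
    and equal-width discretisation.  Entropy curves are averaged over
    ``n_models`` independent topologies and drive realisations; the
    statistic is 100 * H_R(disconnected) / H_R(connected), evaluated at
    the g where the connected H_R peaks (``mode="peak"``) or averaged over
    the grid (``mode="mean"``).
    """
    if g_grid is None:
        g_grid = np.array([3.0])
    g_grid = np.atleast_1d(np.asarray(g_grid, dtype=float))
    protocol = protocol or StimulusProtocol()
    noise = noise or NoiseDriveSpec(mode="correlated",
                                    n_driven=params.n_neurons)
    disc = None                  # no internal connections
    h_conn = np.zeros((n_models, len(g_grid)))
    h_disc = np.zeros_like(h_conn)
    for m in range(n_models):
        conn = build_network(params, seed=_seed_for(seed, 0, m))
        for gi, g in enumerate(g_grid):
            p = params.with_g(g)
            cond_seed = _seed_for(seed, 1, m, gi)
            res_c, _ = mi_for_condition(conn, p, protocol, noise=noise,
                                        seed=cond_seed)
            res_d, _ = mi_for_condition(disc, p, protocol, noise=noise,
                                        seed=cond_seed)
            h_conn[m, gi] = res_c.H_R
            h_disc[m, gi] = res_d.H_R
    h_conn, h_disc = h_conn.mean(axis=0), h_disc.mean(axis=0)
    if not (h_conn > 0).any():
        raise ValueError("connected network produced zero response entropy")
    if mode == "peak":
        i = int(np.argmax(h_conn))
        pct = 100.0 * h_disc[i] / h_conn[i]
        g_used = float(g_grid[i])
    else:
        ok = h_conn > 0
        pct = 100.0 * float(np.mean(h_disc[ok] / h_conn[ok]))
        g_used = float(np.mean(g_grid))
    return {"percent_from_drive": float(pct), "g_used": g_used,
            "g_grid": g_grid, "h_r_connected": h_conn,
            "h_r_disconnected": h_disc}


def connectivity_ablation(params: BrunelParams,
                          densities=(0.10, 0.05, 0.02, 0.01), g_grid=None,
                          protocol: StimulusProtocol | None = None,
                          n_trials: int = 30, seed: int = 0,
                          avalanche_bins: int = 1500,
                          n_boot: int = 50) -> dict[float, dict]:
    """Criticality signatures as internal connectivity is thinned.

    Per density: the decay-constant curve tau(g), the MI curve, and a
    truncated power-law fit of avalanche sizes harvested from runs driven
    by a weak correlated drive at g = 3.  The same topology seed family is
    used across densities so only the synapse count changes.
    """
    if g_grid is None:
        g_grid = np.array([1.5, 2.0, 2.5, 2.8, 3.0, 3.2, 3.6, 4.5])
    g_grid = np.asarray(g_grid, dtype=float)
    protocol = protocol or StimulusProtocol()
    out: dict[float, dict] = {}
    for di, dens in enumerate(densities):
        p_d = replace(params, connection_density=float(dens))
        decay = phase_and_decay_sweep(p_d, g_grid, n_trials=n_trials,
                                      seed=_seed_for(seed, 0))
        mi_res, _ = mi_sweep(p_d, g_grid, n_models=3, protocol=protocol,
                             seed=_seed_for(seed, 0), fit_asymptote=False)
        mi_sweep_res = mi_res[p_d.n_neurons]
        # avalanches under weak shared drive at g = 3: zero-crossings of the
        # drive walk leave the silent bins that bracket avalanches
        conn = (build_network(p_d, seed=_seed_for(seed, 0))
                if dens > 0 else None)
        drive = NoiseDriveSpec(mode="correlated", n_driven=max(
            1, p_d.n_neurons // 100), gain=1.0, burn_in=0)
        act = run_trials(conn, p_d.with_g(3.0), avalanche_bins,
                         stim_magnitudes=np.zeros(8, dtype=np.int64),
                         t_stim=0, noise=drive, seed=_seed_for(seed, 2, di))
        sizes_all = [_sizes_from_counts(row) for row in act]
        sizes = np.concatenate(sizes_all) if sizes_all else np.array([])
        try:
            pl = av.fit_power_law(sizes, n_boot=n_boot, compare=False,
                                  min_tail=50,
                                  seed=_seed_for(seed, 3, di))
            pl_summary = pl.summary()
        except (InsufficientDataError, ValueError) as exc:
            logger.warning("density %.2f power-law fit failed: %s", dens, exc)
            pl_summary = {"error": str(exc), "n": int(len(sizes))}
        out[float(dens)] = {
            "decay": decay, "mi": mi_sweep_res,
            "peak_tau": float(np.nanmax(decay.table["tau_decay"])),
            "peak_mi": mi_sweep_res.meta["peak_mi"],
            "power_law": pl_summary,
        }
    return out


def _sizes_from_counts(counts: np.ndarray) -> np.ndarray:
    """Avalanche sizes from a population-count vector (interior runs only)."""
    active = counts > 0
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    starts, stops = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    sizes = [counts[s:e].sum() for s, e in zip(starts, stops)
             if s > 0 and e < len(counts)]
    return np.array(sizes, dtype=np.int64)


def classify_system(beyond_power_laws: bool, survives_noise_block: bool,
                    survives_connection_cut: bool) -> SystemClass:
    """Decision flow for power-law data.

    No signatures beyond power laws -> not critical (e.g. sums of
    exponentials).  Signatures gone when the randomness source is blocked
    -> low-dimensional driven (coin flip, random walk, OU).  Signatures
    gone when connections are cut -> emergent criticality (interacting
    networks).  Signatures surviving everything -> novel.
    """
    evidence = {"beyond_power_laws": bool(beyond_power_laws),
                "survives_noise_block": bool(survives_noise_block),
                "survives_connection_cut": bool(survives_connection_cut)}
    if not beyond_power_laws:
        label = "not_critical"
    elif not survives_noise_block:
        label = "low_dimensional_driven"
    elif not survives_connection_cut:
        label = "emergent_critical"
    else:
        label = "novel"
    return SystemClass(label=label, evidence=evidence)
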