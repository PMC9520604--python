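"""Discrete-time Brunel-style sparse E/I leaky integrate-and-fire network.

The model is an 80/20 excitatory/inhibitory population with fixed in-degree
random connectivity at 10% density.  Inhibitory synapses are ``-g`` times
the excitatory efficacy; ``g`` is the control parameter that tunes the
network between an active (amplifying) and an inactive (damped) phase.
Time advances in bins of one synaptic delay (1.8 ms), spikes take one bin
to propagate, and stimulation or noise drive is delivered as forced spikes.

Synaptic efficacy is quoted at a reference size ``j_ref_n`` and scaled by
``j_ref_n / N`` so that the per-neuron recurrent drive — and hence the
location of the phase transition — is independent of network size; finite
networks then approach the infinite-size transition point from below as
fluctuation-driven extinction weakens.

Trials are simulated as a batch: the membrane update for all trials at once
is a single (trials x N) @ (N x N) matrix product, which is what makes the
sweep experiments affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import DegenerateNetworkError, Raster
from .walks import WalkTrace, heights_above_threshold

__all__ = [
    "BrunelParams", "Connectivity", "NoiseDriveSpec", "StimulusProtocol",
    "build_network", "simulate", "run_trials", "firing_rate",
]


@dataclass(frozen=True)
class BrunelParams:
    """LIF network constants.

    Voltages are in mV relative to rest; ``j_excit`` is the excitatory
    efficacy at the reference size ``j_ref_n`` (set ``j_ref_n=None`` for a
    raw, size-independent efficacy).
    """

    n_neurons: int = 1000
    frac_excitatory: float = 0.8
    connection_density: float = 0.1
    g: float = 3.0
    nu_ratio: float = 0.0
    delay_ms: float = 1.8
    j_excit: float = 1.0
    j_ref_n: int | None = 1000
    init_v: str = "uniform"
    membrane_tau_ms: float = 20.0
    threshold_v: float = 20.0
    reset_v: float = 10.0
    refractory_ms: float = 2.0
    dt_ms: float = 1.8

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0.0 <= self.connection_density <= 1.0:
            raise ValueError("connection_density must be in [0, 1]")
        if self.g < 0 or self.nu_ratio < 0:
            raise ValueError("g and nu_ratio must be >= 0")

    @property
    def j_eff(self) -> float:
        if self.j_ref_n is None:
            return self.j_excit
        return self.j_excit * self.j_ref_n / self.n_neurons

    @property
    def n_excitatory(self) -> int:
        return int(round(self.frac_excitatory * self.n_neurons))

    @property
    def in_degree_exc(self) -> int:
        return int(round(self.connection_density * self.n_excitatory))

    @property
    def in_degree_inh(self) -> int:
        return int(round(self.connection_density
                         * (self.n_neurons - self.n_excitatory)))

    @property
    def delay_bins(self) -> int:
        return max(1, int(round(self.delay_ms / self.dt_ms)))

    @property
    def refractory_bins(self) -> int:
        return int(round(self.refractory_ms / self.dt_ms))

    def with_g(self, g: float) -> "BrunelParams":
        return replace(self, g=g)


@dataclass
class Connectivity:
    """Adjacency of the network, split by synapse sign.

    ``exc[post, pre]`` is 1 where an excitatory synapse exists; weights are
    assembled per ``g`` as ``j_eff * (exc - g * inh)`` so one topology can
    be swept over the control parameter.
    """

    exc: np.ndarray
    inh: np.ndarray
    seed: int = 0

    @property
    def n_neurons(self) -> int:
        return self.exc.shape[0]

    @property
    def n_connections(self) -> int:
        return int(self.exc.sum() + self.inh.sum())

    def weight_matrix(self, j_eff: float, g: float) -> np.ndarray:
        return (j_eff * (self.exc.astype(np.float32)
                         - np.float32(g) * self.inh.astype(np.float32)))


@dataclass
class StimulusProtocol:
    """Pulse stimulation: forced activation of a set number of neurons.

    ``levels`` defaults to eight equally spaced magnitudes ``i*N/8`` for
    i = 0..7, giving log2(8) = 3 bits of input entropy.
    """

    levels: np.ndarray | None = None
    t_stim: int = 1
    n_trials: int = 30
    response_window: tuple[int, int] = (3, 5)

    def magnitudes(self, n_neurons: int) -> np.ndarray:
        if self.levels is not None:
            lv = np.asarray(self.levels, dtype=np.int64)
        else:
            lv = (np.arange(8) * n_neurons) // 8
        if len(np.unique(lv)) != len(lv):
            raise ValueError("stimulus levels must be distinct")
        if lv.max(initial=0) > n_neurons:
            raise ValueError("stimulus magnitude exceeds network size")
        return lv


@dataclass
class NoiseDriveSpec:
    """Ongoing drive: none, independent Bernoulli spikes, or a shared walk.

    ``uncorrelated``: every neuron fires spontaneously with probability
    ``p_spont`` per bin.  ``correlated``: ``k_t = round(gain * x_t)`` of the
    ``n_driven`` designated neurons are forced to spike each bin, where
    ``x_t`` is a reflected coin-flip trace (``drive_trace`` if supplied,
    otherwise a fresh walk per trial).  ``burn_in`` steps of walk evolution
    precede the simulation window for generated walks, so the drive arrives
    with the stationary excursion amplitude of an ongoing process rather
    than starting from the origin.
    """

    mode: str = "none"
    p_spont: float = 0.0
    n_driven: int = 0
    gain: float = 3.0
    drive_trace: WalkTrace | None = None
    burn_in: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in ("none", "uncorrelated", "correlated"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if not 0.0 <= self.p_spont <= 1.0:
            raise ValueError("p_spont must be in [0, 1]")
        if self.n_driven < 0:
            raise ValueError("n_driven must be >= 0")


def build_network(params: BrunelParams, seed: int = 0) -> Connectivity:
    """Fixed in-degree random connectivity without self-connections.

    Every neuron receives exactly ``round(density * 0.8 * N)`` excitatory
    and ``round(density * 0.2 * N)`` inhibitory inputs, drawn uniformly
    without replacement.
    """
    N = params.n_neurons
    if params.connection_density > 0 and params.connection_density * N < 1:
        raise DegenerateNetworkError(
            f"density {params.connection_density} x N {N} < 1 synapse per neuron")
    n_e = params.n_excitatory
    c_e, c_i = params.in_degree_exc, params.in_degree_inh
    rng = np.random.default_rng(seed)
    exc = np.zeros((N, N), dtype=np.uint8)
    inh = np.zeros((N, N), dtype=np.uint8)
    e_pool = np.arange(n_e)
    i_pool = np.arange(n_e, N)
    for post in range(N):
        if c_e:
            pool = e_pool[e_pool != post]
            exc[post, rng.choice(pool, size=c_e, replace=False)] = 1
        if c_i:
            pool = i_pool[i_pool != post]
            inh[post, rng.choice(pool, size=c_i, replace=False)] = 1
    return Connectivity(exc=exc, inh=inh, seed=seed)


def _correlated_drive_counts(noise: NoiseDriveSpec, n_trials: int,
                             duration_bins: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Per-trial, per-bin forced-spike counts for the correlated drive."""
    if noise.drive_trace is not None:
        x = np.asarray(noise.drive_trace.values[:duration_bins])
        if len(x) < duration_bins:
            raise ValueError("drive_trace shorter than the simulation")
        k = heights_above_threshold(x, 0.0, noise.gain, noise.n_driven)
        return np.broadcast_to(k, (n_trials, duration_bins)).copy()
    total = noise.burn_in + duration_bins
    steps = np.where(rng.random((n_trials, total)) < 0.5, 1, -1)
    walks = np.abs(np.cumsum(steps, axis=1))[:, noise.burn_in:]
    return np.minimum(
        np.floor(noise.gain * walks + 0.5).astype(np.int64), noise.n_driven)


def run_trials(connectivity: Connectivity | None, params: BrunelParams,
               duration_bins: int, stim_magnitudes=None, t_stim: int = 10,
               noise: NoiseDriveSpec | None = None, seed: int = 0,
               record: str = "counts"):
    """Simulate a batch of trials on one topology.

    Parameters
    ----------
    connectivity : ``None`` is treated as a fully disconnected network.
    stim_magnitudes : per-trial number of neurons forced to spike at
        ``t_stim`` (``None`` or 0 for no stimulation).
    record : ``"counts"`` returns the (trials, bins) population-activity
        array; ``"raster"`` additionally returns the full (trials, N, bins)
        spike tensor.

    Returns
    -------
    activity, or ``(activity, rasters)`` when ``record="raster"``.
    """
    N = params.n_neurons
    noise = noise or NoiseDriveSpec()
    if stim_magnitudes is None:
        stim_magnitudes = np.zeros(1, dtype=np.int64)
    stim_magnitudes = np.atleast_1d(np.asarray(stim_magnitudes, dtype=np.int64))
    if stim_magnitudes.max(initial=0) > N:
        raise ValueError("stimulus magnitude exceeds network size")
    n_trials = len(stim_magnitudes)

    ss = np.random.SeedSequence(seed)
    rng_stim, rng_noise, rng_init = [np.random.default_rng(s)
                                     for s in ss.spawn(3)]

    if connectivity is not None and connectivity.n_connections > 0:
        Wt = np.ascontiguousarray(
            connectivity.weight_matrix(params.j_eff, params.g).T)
    else:
        Wt = None

    lam = np.float32(np.exp(-params.dt_ms / params.membrane_tau_ms))
    thr = np.float32(params.threshold_v)
    reset = np.float32(params.reset_v)
    refr_bins = params.refractory_bins
    delay = params.delay_bins

    if params.init_v == "uniform":
        # random subthreshold membrane phases: a pulse then recruits a
        # graded fraction of the population instead of all or none
        V = rng_init.random((n_trials, N), dtype=np.float32) * thr
    else:
        V = np.zeros((n_trials, N), dtype=np.float32)
    refr = np.zeros((n_trials, N), dtype=np.int32)
    ring = [np.zeros((n_trials, N), dtype=np.float32) for _ in range(delay)]
    activity = np.zeros((n_trials, duration_bins), dtype=np.int64)
    rasters = (np.zeros((n_trials, N, duration_bins), dtype=np.uint8)
               if record == "raster" else None)

    if noise.mode == "correlated" and noise.n_driven > 0:
        drive_k = _correlated_drive_counts(noise, n_trials, duration_bins,
                                           rng_noise)
        driven_ids = rng_noise.choice(N, size=noise.n_driven, replace=False)
    else:
        drive_k = None
        driven_ids = None

    ext_lambda = 0.0
    if params.nu_ratio > 0:
        # Poisson external input: C_E synapses firing at nu_ratio * nu_thr,
        # nu_thr = threshold / (J * C_E * tau_m)  [spikes/ms per synapse]
        c_e = max(params.in_degree_exc, 1)
        nu_thr = params.threshold_v / (params.j_eff * c_e
                                       * params.membrane_tau_ms)
        ext_lambda = params.nu_ratio * nu_thr * c_e * params.dt_ms

    for t in range(duration_bins):
        V *= lam
        if Wt is not None:
            V += ring[t % delay] @ Wt
        if ext_lambda > 0:
            V += params.j_eff * rng_noise.poisson(
                ext_lambda, size=(n_trials, N)).astype(np.float32)

        forced = np.zeros((n_trials, N), dtype=bool)
        if t == t_stim:
            for i, m in enumerate(stim_magnitudes):
                if m > 0:
                    forced[i, rng_stim.choice(N, size=int(m), replace=False)] = True
        if noise.mode == "uncorrelated" and noise.p_spont > 0:
            forced |= rng_noise.random((n_trials, N)) < noise.p_spont
        elif drive_k is not None:
            for i in range(n_trials):
                k = int(drive_k[i, t])
                if k > 0:
                    forced[i, driven_ids[rng_noise.choice(
                        noise.n_driven, size=k, replace=False)]] = True

        spikes = ((V >= thr) & (refr <= 0)) | forced
        activity[:, t] = spikes.sum(axis=1)
        if rasters is not None:
            rasters[:, :, t] = spikes
        V[spikes] = reset
        refr[refr > 0] -= 1
        refr[spikes] = refr_bins
        ring[t % delay] = spikes.astype(np.float32)

    if record == "raster":
        return activity, rasters
    return activity


def simulate(connectivity: Connectivity | None, params: BrunelParams,
             duration_bins: int, noise: NoiseDriveSpec | None = None,
             stimulus: tuple[int, int] | None = None, seed: int = 0) -> Raster:
    """Single-trial simulation returning the full raster.

    ``stimulus`` is an optional ``(magnitude, t_stim)`` pair: that many
    randomly chosen neurons are forced to spike at the stated bin.
    """
    mag, t_stim = (stimulus if stimulus is not None else (0, 0))
    if t_stim >= duration_bins and mag > 0:
        raise ValueError("t_stim beyond simulation end")
    _, rasters = run_trials(connectivity, params, duration_bins,
                            stim_magnitudes=[mag], t_stim=t_stim,
                            noise=noise, seed=seed, record="raster")
    return Raster(spikes=rasters[0], bin_ms=params.dt_ms)


def firing_rate(raster: Raster) -> float:
    """Mean spikes per neuron per bin (the order parameter)."""
    if raster.spikes.size == 0:
        raise ValueError("empty raster")
    return float(raster.spikes.mean())
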