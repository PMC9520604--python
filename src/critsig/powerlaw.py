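"""Discrete truncated power-law fitting.

Maximum-likelihood fitting of ``p(x) ~ x**-a`` on an integer support
``[xmin, xmax]``, with the normalising constant expressed through the
Hurwitz zeta function, Kolmogorov-Smirnov selection of ``xmin``, a
parametric bootstrap of the KS statistic as a plausibility check, and
Vuong-style log-likelihood-ratio comparisons against discrete exponential
and lognormal alternatives.  This is the standard battery used to decide
whether avalanche size/duration distributions are power-law-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .types import InsufficientDataError

__all__ = ["PowerLawFit", "ComparisonResult", "fit_power_law",
           "sample_discrete_power_law"]

_A_LO, _A_HI = 1.000001, 8.0


@dataclass
class ComparisonResult:
    """Vuong-style comparison of the power law against one alternative.

    ``loglike_ratio > 0`` favours the power law; ``p_value`` is the
    two-sided significance of the normalised ratio.
    """

    alternative: str
    loglike_ratio: float
    p_value: float
    params: tuple = ()


@dataclass
class PowerLawFit:
    exponent: float
    xmin: int
    xmax: int
    n_tail: int
    ks: float
    goodness_p: float | None = None
    comparisons: dict[str, ComparisonResult] = field(default_factory=dict)

    def summary(self) -> dict:
        out = {"exponent": self.exponent, "xmin": self.xmin, "xmax": self.xmax,
               "n_tail": self.n_tail, "ks": self.ks, "goodness_p": self.goodness_p}
        for name, c in self.comparisons.items():
            out[f"llr_{name}"] = c.loglike_ratio
            out[f"llr_{name}_p"] = c.p_value
        return out


def _hurwitz_Z(a: float, xmin: int, xmax: int) -> float:
    """Sum of x**-a over integers xmin..xmax."""
    return float(special.zeta(a, xmin) - special.zeta(a, xmax + 1))


def _fit_exponent(x: np.ndarray, xmin: int, xmax: int) -> float:
    n = len(x)
    slogx = float(np.log(x).sum())

    def nll(a: float) -> float:
        return n * np.log(_hurwitz_Z(a, xmin, xmax)) + a * slogx

    res = optimize.minimize_scalar(nll, bounds=(_A_LO, _A_HI), method="bounded")
    return float(res.x)


def _model_cdf(u: np.ndarray, a: float, xmin: int, xmax: int) -> np.ndarray:
    """P(X <= u) for the truncated discrete power law, u integer array."""
    Z = _hurwitz_Z(a, xmin, xmax)
    return (special.zeta(a, xmin) - special.zeta(a, u + 1)) / Z


def _ks_stat(x: np.ndarray, a: float, xmin: int, xmax: int) -> float:
    u, counts = np.unique(x, return_counts=True)
    ecdf = np.cumsum(counts) / len(x)
    return float(np.abs(ecdf - _model_cdf(u, a, xmin, xmax)).max())


def sample_discrete_power_law(a: float, xmin: int, xmax: int, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Draw n samples from the truncated discrete power law.

    Exact inverse-CDF sampling when the support is small enough to tabulate;
    otherwise the continuous-approximation sampler (inverse CDF of the
    continuous power law on [xmin-1/2, xmax+1/2], then rounded), which is
    accurate for the broad supports where tabulation is impractical.
    """
    width = xmax - xmin + 1
    if width <= 2**21:
        support = np.arange(xmin, xmax + 1, dtype=np.int64)
        cdf = np.cumsum(support.astype(float) ** -a)
        cdf /= cdf[-1]
        return support[np.searchsorted(cdf, rng.random(n))]
    lo, hi = (xmin - 0.5) ** (1.0 - a), (xmax + 0.5) ** (1.0 - a)
    u = rng.random(n)
    xs = (lo + u * (hi - lo)) ** (1.0 / (1.0 - a))
    return np.clip(np.rint(xs).astype(np.int64), xmin, xmax)


def _fit_exponential(x: np.ndarray, xmin: int, xmax: int) -> tuple[float, np.ndarray]:
    """Discrete exponential p(x) ~ exp(-lam*x) on [xmin, xmax]; returns (lam, logpmf)."""
    n, sx = len(x), float(x.sum())
    width = xmax - xmin + 1

    def logZ(lam: float) -> float:
        # geometric series: exp(-lam*xmin) * (1 - r**width) / (1 - r), r = exp(-lam)
        r = np.exp(-lam)
        return -lam * xmin + np.log1p(-r**width) - np.log1p(-r)

    def nll(lam: float) -> float:
        return n * logZ(lam) + lam * sx

    res = optimize.minimize_scalar(nll, bounds=(1e-9, 20.0), method="bounded")
    lam = float(res.x)
    return lam, -lam * x - logZ(lam)


def _lognormal_logw(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    lx = np.log(x)
    return -lx - (lx - mu) ** 2 / (2.0 * sigma**2)


def _lognormal_logZ(mu: float, sigma: float, xmin: int, xmax: int) -> float:
    width = xmax - xmin + 1
    if width <= 2**21:
        support = np.arange(xmin, xmax + 1, dtype=float)
        return float(special.logsumexp(_lognormal_logw(support, mu, sigma)))
    # continuous integral of exp(-(ln x - mu)^2 / 2 s^2)/x over [xmin-.5, xmax+.5]
    a = (np.log(xmin - 0.5) - mu) / (sigma * np.sqrt(2))
    b = (np.log(xmax + 0.5) - mu) / (sigma * np.sqrt(2))
    return float(np.log(sigma * np.sqrt(np.pi / 2) * (special.erf(b) - special.erf(a))))


def _fit_lognormal(x: np.ndarray, xmin: int, xmax: int) -> tuple[tuple[float, float], np.ndarray]:
    lx = np.log(x)
    n = len(x)

    def nll(theta):
        mu, logsig = theta
        sigma = np.exp(logsig)
        return n * _lognormal_logZ(mu, sigma, xmin, xmax) \
            - float(_lognormal_logw(x, mu, sigma).sum())

    res = optimize.minimize(nll, x0=[float(lx.mean()), float(np.log(lx.std() + 1e-3))],
                            method="Nelder-Mead")
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    logpmf = _lognormal_logw(x, mu, sigma) - _lognormal_logZ(mu, sigma, xmin, xmax)
    return (mu, sigma), logpmf


def _vuong(ll_pl: np.ndarray, ll_alt: np.ndarray) -> tuple[float, float]:
    d = ll_pl - ll_alt
    n = len(d)
    r = float(d.sum())
    sd = float(d.std())
    if sd == 0:
        return r, 1.0
    z = r / (np.sqrt(n) * sd)
    return r, float(2.0 * stats.norm.sf(abs(z)))


def _select_xmin(x: np.ndarray, xmax: int, min_tail: int,
                 max_candidates: int = 40) -> tuple[int, float, float]:
    uniq = np.unique(x)
    # candidate xmins that keep at least min_tail samples in range
    counts_ge = len(x) - np.searchsorted(np.sort(x), uniq, side="left")
    cand = uniq[(counts_ge >= min_tail) & (uniq < xmax)]
    if len(cand) == 0:
        cand = uniq[:1]
    if len(cand) > max_candidates:
        idx = np.unique(np.geomspace(1, len(cand), max_candidates).astype(int)) - 1
        cand = cand[idx]
    best = (int(cand[0]), np.inf, np.nan)
    for xm in cand:
        tail = x[x >= xm]
        a = _fit_exponent(tail, int(xm), xmax)
        ks = _ks_stat(tail, a, int(xm), xmax)
        if ks < best[1]:
            best = (int(xm), ks, a)
    return best[0], best[2], best[1]


def fit_power_law(samples, xmin: int | None = None, xmax: int | None = None,
                  n_boot: int = 200, compare: bool = True,
                  min_tail: int = 100, seed: int = 0) -> PowerLawFit:
    """Fit a discrete truncated power law by maximum likelihood.

    Parameters
    ----------
    samples : array of positive integers (avalanche sizes or durations).
    xmin, xmax : fit range; ``xmin`` is KS-selected if omitted, ``xmax``
        defaults to the sample maximum.
    n_boot : parametric-bootstrap replicates for the KS plausibility
        ``goodness_p`` (0 skips the bootstrap).
    compare : also fit discrete exponential and lognormal alternatives and
        report Vuong-style log-likelihood ratios.
    min_tail : minimum samples required in the fit range.
    """
    x = np.asarray(samples, dtype=np.int64)
    if len(x) and x.min() < 1:
        raise ValueError("samples must be positive integers")
    if xmax is None:
        xmax = int(x.max()) if len(x) else 1
    xmax = int(xmax)
    x = x[x <= xmax]

    if xmin is None:
        if len(x) < min_tail or len(np.unique(x)) < 2:
            raise InsufficientDataError(
                f"need >= {min_tail} samples spanning >= 2 values", n_tail=len(x))
        xmin, a, ks = _select_xmin(x, xmax, min_tail)
        tail = x[x >= xmin]
    else:
        xmin = int(xmin)
        tail = x[x >= xmin]
        if len(tail) < min_tail or len(np.unique(tail)) < 2:
            raise InsufficientDataError(
                f"need >= {min_tail} samples in [{xmin}, {xmax}]", n_tail=len(tail))
        a = _fit_exponent(tail, xmin, xmax)
        ks = _ks_stat(tail, a, xmin, xmax)

    if len(tail) < min_tail or len(np.unique(tail)) < 2:
        raise InsufficientDataError("degenerate fit range", n_tail=len(tail))

    fit = PowerLawFit(exponent=a, xmin=xmin, xmax=xmax, n_tail=len(tail), ks=ks)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_boot):
            xb = sample_discrete_power_law(a, xmin, xmax, len(tail), rng)
            ab = _fit_exponent(xb, xmin, xmax)
            if _ks_stat(xb, ab, xmin, xmax) >= ks:
                hits += 1
        fit.goodness_p = hits / n_boot

    if compare:
        Z = _hurwitz_Z(a, xmin, xmax)
        ll_pl = -a * np.log(tail) - np.log(Z)
        lam, ll_exp = _fit_exponential(tail, xmin, xmax)
        r, p = _vuong(ll_pl, ll_exp)
        fit.comparisons["exponential"] = ComparisonResult("exponential", r, p, (lam,))
        ln_params, ll_ln = _fit_lognormal(tail, xmin, xmax)
        r, p = _vuong(ll_pl, ll_ln)
        fit.comparisons["lognormal"] = ComparisonResult("lognormal", r, p, ln_params)

    return fit
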