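"""Posterior-summary machinery shared by every Bayesian model in the package.

Given a vector of retained MCMC draws this module computes the quantities the
analyses report: the 95% highest density interval (HDI), a kernel-density
posterior mode (boundary-corrected by reflection when the parameter has known
support, e.g. a correlation on [-1, 1]), the posterior proportion PP (the
fraction of posterior mass on the dominant side of zero) and the Savage-Dickey
Bayes factor BF10 (prior density at the null divided by posterior density at
the null, the latter estimated from the draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InsufficientSamplesError

__all__ = [
    "PosteriorSamples",
    "PosteriorSummary",
    "hdi",
    "posterior_mode",
    "posterior_proportion",
    "savage_dickey_bf10",
    "effective_sample_size",
]

#: minimum draws required by the summary operations
MIN_DRAWS = 10

#: minimum draws required for a Savage-Dickey density-ratio estimate
MIN_DRAWS_BF = 1000


def _clean(draws, min_n: int = MIN_DRAWS) -> np.ndarray:
    d = np.asarray(draws, dtype=float).ravel()
    d = d[np.isfinite(d)]
    if d.size < min_n:
        raise InsufficientSamplesError(
            f"need at least {min_n} finite draws, got {d.size}"
        )
    return d


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Exact for unimodal posteriors and deterministic given the draws.

    Parameters
    ----------
    draws : array-like
        Retained MCMC draws (>= 10).
    mass : float
        Probability mass of the interval, in (0, 1). Default 0.95.

    Returns
    -------
    (low, high) : tuple of float
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must lie in (0, 1), got {mass}")
    d = np.sort(_clean(draws))
    n = d.size
    k = min(max(int(math.ceil(mass * n)), 1), n)
    if k == n:
        return float(d[0]), float(d[-1])
    widths = d[k - 1 :] - d[: n - k + 1]
    i = int(np.argmin(widths))
    return float(d[i]), float(d[i + k - 1])


def _silverman_bandwidth(d: np.ndarray) -> float:
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    q75, q25 = np.percentile(d, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return 0.9 * spread * d.size ** (-0.2)


def _kde_density(points, d: np.ndarray, support=None, bandwidth=None) -> np.ndarray:
    """Gaussian KDE of the draws evaluated at ``points``.

    Finite support bounds are handled by reflecting the sample about each
    bound, which removes the boundary bias a plain KDE has when posterior
    mass piles up at the edge of the parameter space (rho near +-1, sigma
    near 0).
    """
    pts = np.atleast_1d(np.asarray(points, dtype=float))
    h = _silverman_bandwidth(d) if bandwidth is None else float(bandwidth)
    if h <= 0:
        # degenerate sample: point mass
        out = np.where(np.isclose(pts, d[0]), np.inf, 0.0)
        return out
    copies = [d]
    lo = hi = None
    if support is not None:
        lo, hi = support
        if lo is not None and np.isfinite(lo):
            copies.append(2.0 * lo - d)
        if hi is not None and np.isfinite(hi):
            copies.append(2.0 * hi - d)
    data = np.concatenate(copies)
    n = d.size  # normalize by the ORIGINAL sample size: reflection folds mass back in
    dens = np.empty(pts.size)
    # chunk the grid so the (grid x draws) matrix stays modest
    chunk = max(1, int(4e6 // max(data.size, 1)) or 1)
    for s in range(0, pts.size, chunk):
        block = pts[s : s + chunk, None] - data[None, :]
        dens[s : s + chunk] = np.exp(-0.5 * (block / h) ** 2).sum(axis=1)
    dens /= n * h * math.sqrt(2.0 * math.pi)
    if support is not None:
        inside = np.ones(pts.size, dtype=bool)
        if lo is not None and np.isfinite(lo):
            inside &= pts >= lo
        if hi is not None and np.isfinite(hi):
            inside &= pts <= hi
        dens = np.where(inside, dens, 0.0)
    return dens


def posterior_mode(draws, support=None, grid_size: int = 512) -> float:
    """Mode of the draws' kernel density estimate.

    Parameters
    ----------
    draws : array-like
        Retained MCMC draws (>= 10).
    support : (low, high) or None
        Known bounds of the parameter. The density is boundary-corrected by
        reflection at finite bounds and the mode clipped into the support.
    """
    d = _clean(draws)
    if np.ptp(d) == 0.0:
        return float(d[0])
    h = _silverman_bandwidth(d)
    glo, ghi = d.min() - h, d.max() + h
    if support is not None:
        lo, hi = support
        if lo is not None and np.isfinite(lo):
            glo = max(glo, float(lo))
        if hi is not None and np.isfinite(hi):
            ghi = min(ghi, float(hi))
    grid = np.linspace(glo, ghi, grid_size)
    dens = _kde_density(grid, d, support=support, bandwidth=h)
    return float(grid[int(np.argmax(dens))])


def posterior_proportion(draws) -> float:
    """Fraction of posterior mass on the dominant side of zero.

    ``max(P(theta > 0), P(theta < 0))`` over the draws; draws exactly equal
    to zero count to neither side. An all-zero sample returns 0.5 by
    convention (no direction is favoured). Always in [0.5, 1].
    """
    d = _clean(draws, min_n=1)
    pos = float(np.mean(d > 0))
    neg = float(np.mean(d < 0))
    if pos + neg == 0.0:
        return 0.5
    return max(pos, neg, 0.5)


def savage_dickey_bf10(
    draws, prior_density_at_null: float, null_value: float = 0.0, support=None
) -> float:
    """Savage-Dickey Bayes factor of the alternative over the point null.

    ``BF10 = p_prior(null) / p_posterior(null)`` where the posterior density
    at the null value is estimated from the draws with the same
    boundary-corrected KDE used by :func:`posterior_mode`. For the
    Uniform[-1, 1] prior on a correlation, ``prior_density_at_null = 0.5``.
    """
    if prior_density_at_null <= 0:
        raise ValueError("prior density at the null must be positive")
    d = _clean(draws, min_n=MIN_DRAWS_BF)
    dens = float(_kde_density(null_value, d, support=support)[0])
    if dens <= 0.0:
        # no posterior mass anywhere near the null: overwhelming evidence
        return float("inf")
    return prior_density_at_null / dens


def effective_sample_size(draws) -> float:
    """ESS of a single chain via Geyer's initial-monotone-sequence estimator."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / var
    # sum adjacent pairs while they stay positive and non-increasing
    tau = 1.0
    prev = float("inf")
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2.0 * pair
    return float(n / max(tau, 1.0))


@dataclass(frozen=True)
class PosteriorSummary:
    """Scalar posterior summarized the way the reports print it."""

    mean: float
    median: float
    mode: float
    hdi_low: float
    hdi_high: float
    pp: float

    def __post_init__(self):
        if self.hdi_low > self.hdi_high:
            raise ValueError("hdi_low must not exceed hdi_high")
        if not 0.5 <= self.pp <= 1.0:
            raise ValueError(f"pp must lie in [0.5, 1], got {self.pp}")

    @classmethod
    def from_draws(cls, draws, support=None, mass: float = 0.95) -> "PosteriorSummary":
        d = _clean(draws)
        lo, hi = hdi(d, mass)
        return cls(
            mean=float(d.mean()),
            median=float(np.median(d)),
            mode=posterior_mode(d, support=support),
            hdi_low=lo,
            hdi_high=hi,
            pp=posterior_proportion(d),
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "mode": self.mode,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "pp": self.pp,
        }


@dataclass
class PosteriorSamples:
    """Named matrix of retained MCMC draws plus chain metadata.

    ``draws`` has one row per retained iteration and one named column per
    parameter. ``thin`` and ``burn_in`` are on the retained scale: the raw
    chain ran ``(burn_in + n_kept) * thin`` iterations.
    """

    draws: pd.DataFrame
    thin: int
    burn_in: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.columns.duplicated().any():
            raise ValueError("parameter names must be unique")

    @property
    def n_kept(self) -> int:
        return len(self.draws)

    def column(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    def summarize(self, support_map: Mapping | None = None, mass: float = 0.95) -> dict:
        """PosteriorSummary per column; ``support_map`` gives per-name bounds."""
        support_map = support_map or {}
        return {
            name: PosteriorSummary.from_draws(
                self.draws[name].to_numpy(), support=support_map.get(name), mass=mass
            )
            for name in self.draws.columns
        }
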