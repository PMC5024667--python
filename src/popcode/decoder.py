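"""Maximum a posteriori decoding of population spiking activity.

With a uniform prior over orientation, MAP decoding equals maximum
likelihood.  Dropping the spike-count-independent terms, the log posterior
over orientation theta given counts n is

    log p(theta | n) = const + sum_i n_i log r_i(theta)

For a baseline-free population (eta = 0) this reduces to
kappa * sum_i n_i cos(theta - phi_i), so the decoded orientation is the
resultant direction of the spike-weighted preferred orientations and the
posterior is Von Mises with concentration kappa * R, where
R = |sum_i n_i exp(i phi_i)| is the (unnormalised) resultant length.  With
baseline activity the posterior is evaluated on a grid.

Zero total count, and the measure-zero event of an exactly vanishing
resultant, leave the posterior uniform; the decoder then guesses uniformly
at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import bessel_ratio, wrap_angle
from .encoder import PopulationParams, SpikeVector, mean_rates

__all__ = [
    "DecodeResult",
    "decode_map",
    "default_grid",
    "posterior_density",
    "posterior_precision",
    "precision_from_concentration",
    "decode_resultant_many",
]

DEFAULT_GRID_SIZE = 1024


def default_grid(n: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Uniform grid of n points on (-pi, pi] (cell centers)."""
    step = 2.0 * np.pi / n
    return -np.pi + step * (np.arange(n) + 0.5)


@dataclass
class DecodeResult:
    """Outcome of decoding one spike vector."""

    theta_map: float
    report: float
    total_count: int
    posterior_precision: float
    guessed: bool


def precision_from_concentration(conc):
    """Posterior precision 1/sigma**2 for a Von Mises posterior of
    concentration conc, using the Fisher circular SD."""
    conc = np.asarray(conc, dtype=float)
    rbar = bessel_ratio(conc)
    with np.errstate(divide="ignore"):
        out = np.where(rbar > 0, -1.0 / (2.0 * np.log(np.where(rbar > 0, rbar, 0.5))), 0.0)
    return out if out.ndim else float(out)


def decode_map(spikes: SpikeVector, params: PopulationParams, rng, c=None,
               grid=None) -> DecodeResult:
    """MAP-decode a spike vector.

    For eta = 0 uses the closed-form resultant decoder; for eta > 0 the log
    posterior is evaluated on a grid (the stimulus contrast ``c`` is then
    required to weight tuned against baseline activity).  Exact ties /
    vanishing resultants are broken by a uniform random draw and flagged.
    """
    counts = spikes.counts
    if counts.shape[0] != params.M:
        raise ValueError("spike vector length does not match params.M")
    m = int(counts.sum())
    if m == 0:
        theta = float(rng.uniform(-np.pi, np.pi))
        return DecodeResult(theta, wrap_angle(theta + params.beta), 0, 0.0, True)

    if params.eta == 0.0:
        z = np.sum(counts * np.exp(1j * params.preferred))
        R = np.abs(z)
        if R < 1e-12:
            theta = float(rng.uniform(-np.pi, np.pi))
            return DecodeResult(theta, wrap_angle(theta + params.beta), m, 0.0, True)
        theta = float(np.angle(z))
        prec = precision_from_concentration(params.kappa * R)
        return DecodeResult(theta, wrap_angle(theta + params.beta), m, float(prec), False)

    if c is None:
        raise ValueError("contrast c is required for decoding with baseline activity")
    if grid is None:
        grid = default_grid()
    dens = posterior_density(spikes, params, grid, c=c)
    best = np.flatnonzero(dens >= dens.max() * (1.0 - 1e-12))
    guessed = False
    if best.size > 1:
        idx = int(best[rng.integers(best.size)])
        guessed = True
    else:
        idx = int(best[0])
    theta = float(grid[idx])
    prec = posterior_precision(dens, grid)
    return DecodeResult(theta, wrap_angle(theta + params.beta), m, float(prec), guessed)


def posterior_density(spikes: SpikeVector, params: PopulationParams, grid,
                      c=None) -> np.ndarray:
    """Posterior density over orientation on a uniform grid.

    Proportional to exp(sum_i n_i log r_i(theta)); the theta-independent
    total-rate term is constant under dense uniform tuning coverage and is
    dropped.  For zero total count the posterior is uniform.
    """
    grid = np.asarray(grid, dtype=float)
    counts = spikes.counts
    m = counts.sum()
    if m == 0:
        return np.full(grid.shape, 1.0 / (2.0 * np.pi))
    if params.eta == 0.0:
        z = np.sum(counts * np.exp(1j * params.preferred))
        loglik = params.kappa * np.abs(z) * np.cos(grid - np.angle(z))
    else:
        if c is None:
            raise ValueError("contrast c is required with baseline activity")
        # rate of neuron i when the stimulus is hypothesised at grid angle
        rates = np.array([mean_rates(t, c, params) for t in grid])  # (G, M)
        loglik = (np.log(rates) * counts[None, :]).sum(axis=1)
    loglik -= loglik.max()
    dens = np.exp(loglik)
    step = 2.0 * np.pi / grid.size
    dens /= dens.sum() * step
    return dens


def posterior_precision(density, grid) -> float:
    """Precision 1/sigma**2 of a gridded density via its resultant length;
    0 for a (numerically) uniform posterior."""
    grid = np.asarray(grid, dtype=float)
    density = np.asarray(density, dtype=float)
    step = 2.0 * np.pi / grid.size
    rbar = np.abs(np.sum(density * np.exp(1j * grid)) * step)
    if rbar < 1e-12:
        return 0.0
    rbar = min(rbar, 1.0 - 1e-16)
    return float(-1.0 / (2.0 * np.log(rbar)))


# ---------------------------------------------------------------------------
# Vectorised helpers used by the simulation-heavy modules
# ---------------------------------------------------------------------------

def decode_resultant_many(count_matrix, params: PopulationParams, rng):
    """Closed-form (eta = 0) decoding of many spike vectors at once.

    Parameters
    ----------
    count_matrix : (n, M) integer array of spike counts.

    Returns
    -------
    theta_map : (n,) decoded orientations (guesses filled in uniformly)
    total : (n,) total spike counts
    precision : (n,) posterior precisions (0 on guesses)
    guessed : (n,) boolean mask of guess trials
    """
    if params.eta != 0.0:
        raise ValueError("closed-form decoding requires eta = 0")
    counts = np.asarray(count_matrix)
    z = counts @ np.exp(1j * params.preferred)
    R = np.abs(z)
    total = counts.sum(axis=1)
    guessed = (total == 0) | (R < 1e-12)
    theta = np.where(guessed, rng.uniform(-np.pi, np.pi, size=R.shape), np.angle(z))
    precision = np.where(guessed, 0.0,
                         precision_from_concentration(params.kappa * np.maximum(R, 1e-12)))
    return theta, total, precision, guessed
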