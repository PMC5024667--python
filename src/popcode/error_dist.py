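"""Analytic distribution of the MAP decoding error.

The decoded error is the resultant direction of a Von Mises random walk
with one unit step per spike.  Conditional on the walk's resultant length
r, the error is Von Mises with concentration kappa * r; the resultant
length of m Von Mises(0, kappa) steps has density obtained by exponential
tilting of the uniform-walk resultant density psi_m(r):

    p(r | m, kappa)  propto  r psi_m(r) * I0(kappa r) / I0(kappa)**m

and the total spike count m is Poisson with mean xi (the expected total
count).  The marginal error density is therefore the Poisson mixture

    p(dtheta) = exp(-xi)/(2 pi)
              + sum_{m>=1} Pois(m; xi) * E_r[ VM(dtheta; 0, kappa r) ]

shifted by the response bias beta.

Numerics.  The uniform-walk density r psi_m(r) is tabulated by Monte
Carlo (10^3 bins per m).  Exponential tilting of a Monte Carlo histogram
is only trustworthy while the tilted mass sits in a well-sampled region
of the uniform walk; that holds when m * A(kappa)**2 <~ 8, where
A = I1/I0 is the mean step resultant (beyond it the required r values lie
e^{-m A^2} deep in the uniform walk's tail).  For larger m the conditional
error density is computed instead as the direction density of the
resultant vector under a bivariate-normal (projected-normal)
approximation with the exact per-step trigonometric moments; cross-checks
against brute-force Von Mises walks put both routes within total
variation ~0.01 of the truth throughout their operating ranges, with the
switch point chosen where they overlap.

The mixture is, in general, not a Von Mises: at intermediate gains it has
a sharp peak with long tails (positive circular-kurtosis excess), tending
to a circular normal at high gain and to uniform as xi -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from scipy.special import log_ndtr

from .circular import bessel_ratio, vm_pdf, wrap_angle
from .decoder import default_grid

__all__ = [
    "ResultantTable",
    "WalkTableSet",
    "uniform_walk_resultant",
    "walk_table_set",
    "save_table",
    "load_table",
    "vm_walk_resultant",
    "projected_normal_logpdf",
    "tilt_cutoff_m",
    "error_density_given_m",
    "conditional_matrix",
    "error_density",
    "ErrorDensity",
    "simulate_error_sample",
]

TABLE_M_MAX = 100
TABLE_BINS = 1000
TABLE_NSIM = 1_000_000
TABLE_SEED = 20160907
POISSON_TAIL = 1e-8
TILT_BUDGET = 8.0       # largest m * A(kappa)**2 served by the tilted table


@dataclass
class ResultantTable:
    """Histogram of the resultant length r of a uniform random walk of m
    unit steps: the density r * psi_m(r), discretised over bins on [0, m]."""

    m: int
    bin_centers: np.ndarray
    density: np.ndarray     # probabilities per bin, summing to 1
    n_sim: int
    seed: int

    def __post_init__(self):
        s = float(self.density.sum())
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError("resultant-table density must sum to 1")


class WalkTableSet:
    """Uniform-walk resultant tables for every m = 1 .. m_max, built in a
    single simulation pass (the same walkers are extended one step at a
    time, so consecutive tables share walkers but each marginal is exact)."""

    def __init__(self, m_max=TABLE_M_MAX, bins=TABLE_BINS, n_sim=TABLE_NSIM,
                 seed=TABLE_SEED):
        self.m_max = m_max
        self.bins = bins
        self.n_sim = n_sim
        self.seed = seed
        rng = np.random.default_rng(seed)
        dens = np.empty((m_max + 1, bins))
        dens[0] = 0.0
        z = np.zeros(n_sim, dtype=complex)
        for m in range(1, m_max + 1):
            z += np.exp(1j * rng.uniform(-np.pi, np.pi, size=n_sim))
            r = np.clip(np.abs(z), 0.0, m)  # |z| may exceed m by rounding
            hist, _ = np.histogram(r, bins=bins, range=(0.0, m))
            dens[m] = hist / n_sim
        self._density = dens

    def centers(self, m):
        step = m / self.bins
        return step * (np.arange(self.bins) + 0.5)

    def table(self, m) -> ResultantTable:
        if not 1 <= m <= self.m_max:
            raise ValueError(f"m must be in [1, {self.m_max}]")
        return ResultantTable(m, self.centers(m), self._density[m],
                              self.n_sim, self.seed)


_TABLE_CACHE: dict = {}


def walk_table_set(m_max=TABLE_M_MAX, bins=TABLE_BINS, n_sim=TABLE_NSIM,
                   seed=TABLE_SEED) -> WalkTableSet:
    """Memoised accessor for the uniform-walk table set."""
    key = (m_max, bins, n_sim, seed)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = WalkTableSet(*key)
    return _TABLE_CACHE[key]


def uniform_walk_resultant(m, n_sim, rng, bins=TABLE_BINS) -> ResultantTable:
    """Monte Carlo density of the resultant length of a uniform random walk
    of m steps, over ``bins`` equal bins on [0, m]."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_sim < 10_000:
        raise ValueError("n_sim must be at least 10^4")
    hist = np.zeros(bins)
    chunk = 200_000
    done = 0
    while done < n_sim:
        k = min(chunk, n_sim - done)
        steps = rng.uniform(-np.pi, np.pi, size=(k, m))
        r = np.clip(np.abs(np.exp(1j * steps).sum(axis=1)), 0.0, m)
        h, _ = np.histogram(r, bins=bins, range=(0.0, m))
        hist += h
        done += k
    step = m / bins
    centers = step * (np.arange(bins) + 0.5)
    return ResultantTable(m, centers, hist / n_sim, n_sim, -1)


def save_table(table: ResultantTable, path) -> None:
    """Write a resultant table as a delimited text file with a header
    recording m, bin count, n_sim and seed."""
    header = (f"m={table.m} bins={table.bin_centers.size} "
              f"n_sim={table.n_sim} seed={table.seed}")
    np.savetxt(path, np.column_stack([table.bin_centers, table.density]),
               header=header, fmt="%.12g", delimiter="\t")


def load_table(path) -> ResultantTable:
    """Read a resultant table written by :func:`save_table`."""
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=") for item in header.split())
    data = np.loadtxt(path, delimiter="\t")
    return ResultantTable(int(meta["m"]), data[:, 0], data[:, 1],
                          int(meta["n_sim"]), int(meta["seed"]))


def _log_i0(x):
    return np.log(special.i0e(x)) + x


def vm_walk_resultant(m, kappa, table: ResultantTable) -> np.ndarray:
    """Density over resultant length r for a walk of m Von Mises(0, kappa)
    steps, by exponential tilting of the uniform-walk table:
    p(r) propto table.density(r) * I0(kappa r) / I0(kappa)**m."""
    if table.m != m:
        raise ValueError("table was built for a different m")
    if kappa == 0.0:
        return table.density.copy()
    logw = np.where(table.density > 0,
                    np.log(np.where(table.density > 0, table.density, 1.0))
                    + _log_i0(kappa * table.bin_centers) - m * _log_i0(kappa),
                    -np.inf)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Projected-normal conditional for large m
# ---------------------------------------------------------------------------

def _step_moments(kappa):
    """Mean and variances of (cos e, sin e) for e ~ VM(0, kappa)."""
    a1 = bessel_ratio(kappa)
    a2 = float(special.ive(2, kappa) / special.i0e(kappa)) if kappa > 0 else 0.0
    var_c = 0.5 * (1.0 + a2) - a1**2
    var_s = 0.5 * (1.0 - a2)
    return a1, var_c, var_s


def projected_normal_logpdf(theta, mean_len, var_c, var_s):
    """Log density of the direction of X ~ N((mean_len, 0),
    diag(var_c, var_s)) — the offset-normal direction distribution."""
    theta = np.asarray(theta, dtype=float)
    u1, u2 = np.cos(theta), np.sin(theta)
    Aq = u1**2 / var_c + u2**2 / var_s
    Bq = u1 * mean_len / var_c
    Cq = mean_len**2 / var_c
    z = Bq / np.sqrt(Aq)
    base = -0.5 * Cq - np.log(2.0 * np.pi * Aq * np.sqrt(var_c * var_s))
    # t = z * Phi(z) / phi(z); log1p(t) in log space where t may overflow
    log_phi = -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi)
    out = np.empty_like(z)
    pos = z > 0
    logt = np.log(np.abs(z) + 1e-300) + log_ndtr(z) - log_phi
    out[pos] = base[pos] + np.logaddexp(0.0, logt[pos])
    t_neg = -np.exp(logt[~pos])
    out[~pos] = base[~pos] + np.log1p(np.maximum(t_neg, -1.0 + 1e-300))
    return out


def _projected_normal_pdf_rows(ms, kappa, grid):
    """(len(ms), G) matrix of projected-normal conditionals, normalised on
    the grid.  Fully vectorised over m: with mean (m a1, 0) and covariance
    m diag(vc, vs), the quadratic forms scale as A = a0/m, B = b0,
    C = m c0, z = sqrt(m) z0, with a0, b0, c0, z0 functions of the grid
    only."""
    a1, var_c, var_s = _step_moments(kappa)
    ms = np.asarray(ms, dtype=float)[:, None]
    u1, u2 = np.cos(grid), np.sin(grid)
    a0 = u1**2 / var_c + u2**2 / var_s
    b0 = u1 * a1 / var_c
    c0 = a1**2 / var_c
    z0 = b0 / np.sqrt(a0)
    z = np.sqrt(ms) * z0[None, :]
    base = -0.5 * ms * c0 - np.log(2.0 * np.pi * a0 *
                                   np.sqrt(var_c * var_s))[None, :]
    log_phi = -0.5 * z**2 - 0.5 * np.log(2.0 * np.pi)
    logt = np.log(np.abs(z) + 1e-300) + log_ndtr(z) - log_phi
    # for z <= 0 the term t = z Phi(z)/phi(z) lies in (-1, 0]; log1p may
    # legitimately hit -inf for directions opposite a strong offset
    with np.errstate(divide="ignore"):
        neg = np.log1p(np.maximum(-np.exp(np.minimum(logt, 0.0)),
                                  -1.0 + 1e-300))
        lp = base + np.where(z > 0, np.logaddexp(0.0, logt), neg)
    lp -= lp.max(axis=1, keepdims=True)
    rows = np.exp(lp)
    rows /= rows.sum(axis=1, keepdims=True) * (2.0 * np.pi / grid.size)
    return rows


def tilt_cutoff_m(kappa, m_max=TABLE_M_MAX) -> int:
    """Largest spike count m whose conditional density is served by the
    tilted Monte Carlo table (m * A(kappa)**2 <= TILT_BUDGET); larger m use
    the projected-normal route."""
    a1 = bessel_ratio(kappa)
    if a1 <= 0:
        return m_max
    return int(min(m_max, np.floor(TILT_BUDGET / a1**2)))


def _compress_weights(r, w, max_components):
    """Equal-mass compression of a discrete distribution over r to at most
    ``max_components`` representative points (weighted quantiles)."""
    keep = w > 1e-13
    r, w = r[keep], w[keep]
    if r.size <= max_components:
        return r, w / w.sum()
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    q = (np.arange(max_components) + 0.5) / max_components
    rq = np.interp(q, cdf, r)
    return rq, np.full(max_components, 1.0 / max_components)


def error_density_given_m(m, kappa, grid, table_set: WalkTableSet | None = None,
                          max_components=None) -> np.ndarray:
    """Density of the decoding error conditional on m >= 1 spikes.

    Marginalises VM(dtheta; 0, kappa r) over the resultant-length
    distribution of the m-step walk (tilted table for small m * A^2,
    projected normal otherwise).  ``max_components`` caps the number of
    mixture components used from the table (equal-mass compression),
    trading a little accuracy for speed during fitting.
    """
    if m < 1:
        raise ValueError("m must be >= 1; the m = 0 term is uniform")
    grid = np.asarray(grid, dtype=float)
    if kappa == 0.0:
        return np.full(grid.shape, 1.0 / (2.0 * np.pi))
    if m == 1:
        return vm_pdf(grid, 0.0, kappa)
    if table_set is None:
        table_set = walk_table_set()
    if m > tilt_cutoff_m(kappa, table_set.m_max):
        return _projected_normal_pdf_rows([m], kappa, grid)[0]
    tab = table_set.table(m)
    w = vm_walk_resultant(m, kappa, tab)
    if max_components:
        r, w = _compress_weights(tab.bin_centers, w, max_components)
    else:
        keep = w > 1e-14
        r, w = tab.bin_centers[keep], w[keep]
    conc = kappa * r
    kern = np.exp(conc[:, None] * (np.cos(grid)[None, :] - 1.0))
    kern /= (2.0 * np.pi * special.i0e(conc))[:, None]
    return w @ kern


def conditional_matrix(kappa, grid, m_hi, table_set: WalkTableSet | None = None,
                       max_components=None) -> np.ndarray:
    """Matrix F of shape (m_hi + 1, G) with F[m] the error density
    conditional on m spikes (row 0 is the uniform density).

    Computing this once per kappa lets mixture densities for several xi
    values (contrast conditions) be formed as Poisson-weight vector
    products; this is the workhorse of likelihood evaluation.
    """
    grid = np.asarray(grid, dtype=float)
    if table_set is None:
        table_set = walk_table_set()
    F = np.empty((m_hi + 1, grid.size))
    F[0] = 1.0 / (2.0 * np.pi)
    if m_hi == 0:
        return F
    if kappa == 0.0:
        F[1:] = 1.0 / (2.0 * np.pi)
        return F
    m_tilt = min(m_hi, tilt_cutoff_m(kappa, table_set.m_max))
    for m in range(1, m_tilt + 1):
        F[m] = error_density_given_m(m, kappa, grid, table_set=table_set,
                                     max_components=max_components)
    if m_hi > m_tilt:
        F[m_tilt + 1:] = _projected_normal_pdf_rows(
            np.arange(m_tilt + 1, m_hi + 1), kappa, grid)
    return F


# ---------------------------------------------------------------------------
# Marginal error density
# ---------------------------------------------------------------------------

@dataclass
class ErrorDensity:
    """A decoding-error density on a uniform circular grid."""

    grid: np.ndarray
    density: np.ndarray
    xi: float
    kappa: float
    beta: float = 0.0
    mode: str = "analytic"

    @property
    def step(self) -> float:
        return 2.0 * np.pi / self.grid.size

    def interp(self, x):
        """Periodic linear interpolation of the density at angles x."""
        return np.interp(wrap_angle(x), self.grid, self.density,
                         period=2.0 * np.pi)

    def loglik(self, errors, floor=1e-300):
        """Summed log density at the given error angles (floored)."""
        p = np.maximum(self.interp(errors), floor)
        return float(np.log(p).sum())

    def circ_moments(self):
        """First and second circular moments of the density (complex)."""
        z1 = np.sum(self.density * np.exp(1j * self.grid)) * self.step
        z2 = np.sum(self.density * np.exp(2j * self.grid)) * self.step
        return z1, z2

    def circ_sd(self) -> float:
        z1, _ = self.circ_moments()
        r = abs(z1)
        if r <= 0:
            return float("inf")
        return float(np.sqrt(-2.0 * np.log(min(r, 1.0))))

    def circ_kurtosis_excess(self) -> float:
        """Fisher circular kurtosis of the density minus that of the Von
        Mises matched in circular variance."""
        from .circular import kappa_from_rbar, vm_reference_kurtosis

        z1, z2 = self.circ_moments()
        r1, mu1 = abs(z1), np.angle(z1)
        r2, mu2 = abs(z2), np.angle(z2)
        if r1 < 1e-9:
            return 0.0
        k_hat = (r2 * np.cos(mu2 - 2.0 * mu1) - r1**4) / (1.0 - r1) ** 2
        return float(k_hat - vm_reference_kurtosis(kappa_from_rbar(r1)))

    def tv_distance_hist(self, samples, n_bins=50) -> float:
        """Total-variation distance between this density (binned) and the
        histogram of a sample of angles."""
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        emp, _ = np.histogram(wrap_angle(samples), bins=edges)
        emp = emp / emp.sum()
        idx = np.clip(np.digitize(self.grid, edges) - 1, 0, n_bins - 1)
        ana = np.bincount(idx, weights=self.density * self.step,
                          minlength=n_bins)
        ana = ana / ana.sum()
        return float(0.5 * np.abs(emp - ana).sum())


def error_density(xi, kappa, beta=0.0, grid=None, n_grid=1024,
                  table_set: WalkTableSet | None = None,
                  max_components=None) -> ErrorDensity:
    """Marginal density of the response error for expected total count xi.

    p(dtheta) = exp(-xi)/(2 pi) + sum_m Pois(m; xi) p(dtheta | m), shifted
    by the response bias beta; the Poisson sum is truncated at its
    1 - 1e-8 quantile.  The result is renormalised on the grid.
    """
    if xi < 0 or kappa < 0:
        raise ValueError("xi and kappa must be nonnegative")
    if grid is None:
        grid = default_grid(n_grid)
    grid = np.asarray(grid, dtype=float)
    x = wrap_angle(grid - beta)

    if xi == 0.0 or kappa == 0.0:
        dens = np.full(grid.shape, 1.0 / (2.0 * np.pi))
        return ErrorDensity(grid, dens, xi, kappa, beta)

    if table_set is None:
        table_set = walk_table_set()
    m_hi = int(stats.poisson.ppf(1.0 - POISSON_TAIL, xi)) + 1
    pmf = stats.poisson.pmf(np.arange(m_hi + 1), xi)
    F = conditional_matrix(kappa, x, m_hi, table_set=table_set,
                           max_components=max_components)
    dens = pmf @ F
    step = 2.0 * np.pi / grid.size
    dens /= dens.sum() * step
    return ErrorDensity(grid, dens, xi, kappa, beta)


def simulate_error_sample(xi, kappa, beta, n, rng):
    """Draw decoding errors directly from the mixture construction (Poisson
    m, then an m-step VM walk) — an independent sampling route used for
    cross-checks; the encode/decode pipeline in :mod:`popcode.analysis`
    provides the full end-to-end oracle."""
    m = rng.poisson(xi, size=n)
    out = np.empty(n)
    zero = m == 0
    out[zero] = rng.uniform(-np.pi, np.pi, size=int(zero.sum()))
    for mv in np.unique(m[~zero]):
        sel = m == mv
        steps = rng.vonmises(0.0, kappa, size=(int(sel.sum()), int(mv)))
        z = np.exp(1j * steps).sum(axis=1)
        ang = np.angle(z)
        bad = np.abs(z) < 1e-12
        if bad.any():
            ang[bad] = rng.uniform(-np.pi, np.pi, size=int(bad.sum()))
        out[sel] = ang
    return wrap_angle(out + beta)
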