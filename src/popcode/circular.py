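"""Circular (directional) statistics on the doubled orientation circle.

Orientation is a periodic variable with period 180 deg; following common
practice the interval (-90, 90] deg is mapped linearly onto the full circle
(-pi, pi] so that standard circular statistics apply.  All functions in this
module work in radians on that doubled circle.

Conventions
-----------
* Angles are always wrapped to the half-open interval (-pi, pi]; the
  boundary -pi maps to +pi.
* Circular standard deviation follows Fisher: sigma = sqrt(-2 ln Rbar)
  where Rbar is the mean resultant length; precision is 1/sigma**2.
* Von Mises concentration kappa and Fisher circular SD are interconverted
  through the Bessel-function ratio A(kappa) = I1(kappa)/I0(kappa) via
  sigma = sqrt(-2 ln A(kappa)).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "wrap_angle",
    "orientation_to_circle",
    "circle_to_orientation",
    "circ_diff",
    "resultant",
    "circ_mean",
    "circ_sd",
    "circ_precision",
    "v_test",
    "trig_moment",
    "circ_kurtosis",
    "circ_kurtosis_excess",
    "vm_pdf",
    "vm_logpdf",
    "vm_sample",
    "bessel_ratio",
    "kappa_from_rbar",
    "kappa_to_sd",
    "sd_to_kappa",
    "vm_reference_kurtosis",
]


def wrap_angle(x):
    """Wrap angle(s) to the interval (-pi, pi]; -pi is mapped to +pi."""
    x = np.asarray(x, dtype=float)
    out = np.pi - np.mod(np.pi - x, 2.0 * np.pi)
    return out if out.ndim else float(out)


def orientation_to_circle(orientation_deg):
    """Map an orientation in degrees on [-90, 90] to radians on (-pi, pi].

    The orientation space (-90, 90] deg is doubled onto the circle:
    theta_rad = orientation_deg * pi / 90.  The boundary -90 deg denotes the
    same orientation as +90 deg and wraps to +pi.
    """
    deg = np.asarray(orientation_deg, dtype=float)
    if np.any(deg < -90.0) or np.any(deg > 90.0):
        raise ValueError("orientation must lie in [-90, 90] degrees")
    return wrap_angle(deg * (np.pi / 90.0))


def circle_to_orientation(theta_rad):
    """Inverse of :func:`orientation_to_circle`: radians back to degrees."""
    return wrap_angle(theta_rad) * (90.0 / np.pi)


def circ_diff(a, b):
    """Angular difference a (-) b on the circle, wrapped to (-pi, pi]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def _check_weights(angles, weights):
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("need at least one angle")
    if weights is None:
        return angles, np.ones_like(angles)
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if weights.shape != angles.shape:
        raise ValueError("weights must match angles in length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("weights must not all be zero")
    return angles, weights


def resultant(angles, weights=None):
    """Mean resultant length and direction of a set of angles.

    Returns
    -------
    (rbar, mean_angle) : tuple of floats
        ``rbar`` is |sum w_j exp(i theta_j)| / sum w_j in [0, 1].  If the
        resultant vector is exactly zero (antipodal cancellation) the mean
        direction is undefined and returned as ``nan``.
    """
    angles, weights = _check_weights(angles, weights)
    z = np.sum(weights * np.exp(1j * angles)) / np.sum(weights)
    rbar = float(np.abs(z))
    if rbar < 1e-12:  # exact cancellation up to rounding
        return 0.0, float("nan")
    return min(rbar, 1.0), float(np.angle(z))


def circ_mean(angles, weights=None):
    """Circular mean direction (nan when the resultant vanishes)."""
    return resultant(angles, weights)[1]


def circ_sd(angles, weights=None):
    """Fisher's circular standard deviation sqrt(-2 ln Rbar).

    Returns +inf when the mean resultant length is zero (maximal
    dispersion), and 0 when all angles coincide.
    """
    rbar, _ = resultant(angles, weights)
    if rbar <= 0.0:
        return float("inf")
    if rbar >= 1.0 - 1e-12:  # identical angles up to rounding
        return 0.0
    return float(np.sqrt(-2.0 * np.log(rbar)))


def circ_precision(angles, weights=None):
    """Precision 1/sigma**2 of a sample; 0 for maximal dispersion, inf if
    all angles coincide."""
    sd = circ_sd(angles, weights)
    if sd == 0.0:
        return float("inf")
    if np.isinf(sd):
        return 0.0
    return 1.0 / sd**2


def v_test(angles, mu0=0.0, weights=None):
    """Modified Rayleigh (V) test for nonuniformity with known mean direction.

    V = n * Rbar * cos(theta_bar - mu0).  The p value uses the large-sample
    approximation u = V * sqrt(2/n) compared against the standard normal
    upper tail.

    Returns
    -------
    (V, p) : tuple of floats
    """
    angles, weights = _check_weights(angles, weights)
    n = angles.size
    rbar, mean_angle = resultant(angles, weights)
    if np.isnan(mean_angle):
        return 0.0, 1.0
    V = n * rbar * np.cos(mean_angle - mu0)
    u = V * np.sqrt(2.0 / n)
    p = float(stats.norm.sf(u))
    return float(V), p


def trig_moment(angles, p=1, weights=None, center=False):
    """p-th trigonometric moment: (R_p, mu_p) of exp(i p theta)."""
    angles, weights = _check_weights(angles, weights)
    ref = 0.0
    if center:
        ref = circ_mean(angles, weights)
    z = np.sum(weights * np.exp(1j * p * (angles - ref))) / np.sum(weights)
    return float(np.abs(z)), float(np.angle(z))


def circ_kurtosis(angles, weights=None):
    """Fisher's sample circular kurtosis.

    k = (R2 * cos(mu2 - 2*mu1) - Rbar**4) / (1 - Rbar)**2, with (R2, mu2)
    the second trigonometric moment and (Rbar, mu1) the first.
    """
    angles, weights = _check_weights(angles, weights)
    r1, mu1 = trig_moment(angles, 1, weights)
    r2, mu2 = trig_moment(angles, 2, weights)
    if r1 >= 1.0 - 1e-12:
        raise ValueError("circular kurtosis undefined for degenerate sample (Rbar ~ 1)")
    return (r2 * np.cos(mu2 - 2.0 * mu1) - r1**4) / (1.0 - r1) ** 2


def vm_reference_kurtosis(kappa):
    """Fisher circular kurtosis of a Von Mises distribution with
    concentration kappa (its second moment is I2/I0, first is I1/I0)."""
    if kappa == 0.0:
        return 0.0
    r1 = bessel_ratio(kappa)
    r2 = special.ive(2, kappa) / special.ive(0, kappa)
    return (r2 - r1**4) / (1.0 - r1) ** 2


def circ_kurtosis_excess(angles, weights=None):
    """Sample circular kurtosis minus that of a Von Mises matched in
    circular variance (concentration chosen so A(kappa) = Rbar).

    Positive values indicate tails heavier than the circular normal; the
    statistic is the non-normality signature used throughout the package.
    """
    angles, weights = _check_weights(angles, weights)
    if np.atleast_1d(angles).size < 4:
        raise ValueError("need at least 4 observations")
    k_hat = circ_kurtosis(angles, weights)
    r1, _ = trig_moment(angles, 1, weights)
    kappa = kappa_from_rbar(r1)
    return float(k_hat - vm_reference_kurtosis(kappa))


# ---------------------------------------------------------------------------
# Von Mises distribution
# ---------------------------------------------------------------------------

def vm_pdf(x, mu=0.0, kappa=1.0):
    """Von Mises density exp(kappa cos(x - mu)) / (2 pi I0(kappa)).

    kappa = 0 gives the circular uniform density 1/(2 pi).  Uses the
    exponentially scaled Bessel function, so it is stable for large kappa.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (2.0 * np.pi * special.i0e(kappa))
    return out if out.ndim else float(out)


def vm_logpdf(x, mu=0.0, kappa=1.0):
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    x = np.asarray(x, dtype=float)
    out = kappa * (np.cos(x - mu) - 1.0) - np.log(2.0 * np.pi * special.i0e(kappa))
    return out if out.ndim else float(out)


def vm_sample(mu, kappa, n, rng):
    """Draw n Von Mises variates, wrapped to (-pi, pi]."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if kappa == 0.0:
        draws = rng.uniform(-np.pi, np.pi, size=n)
    else:
        draws = rng.vonmises(mu, kappa, size=n)
    return wrap_angle(draws)


# ---------------------------------------------------------------------------
# kappa <-> dispersion conversions
# ---------------------------------------------------------------------------

def bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the mean resultant length of a
    Von Mises distribution with concentration kappa."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.where(kappa > 0, special.i1e(kappa) / special.i0e(kappa), 0.0)
    return out if out.ndim else float(out)


def kappa_from_rbar(rbar):
    """Invert A(kappa) = rbar numerically (rbar in [0, 1))."""
    if rbar <= 0.0:
        return 0.0
    if rbar >= 1.0:
        raise ValueError("rbar must be < 1 for a finite concentration")
    # Banerjee-style starting point, then bracketed root refinement.
    k0 = rbar * (2.0 - rbar**2) / (1.0 - rbar**2)
    lo, hi = 0.0, max(2.0 * k0, 1.0)
    while bessel_ratio(hi) < rbar:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - rbar numerically at 1
            return hi
    return float(optimize.brentq(lambda k: bessel_ratio(k) - rbar, lo, hi, xtol=1e-12))


def kappa_to_sd(kappa):
    """Fisher circular SD of a Von Mises with concentration kappa:
    sigma = sqrt(-2 ln A(kappa))."""
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if kappa == 0.0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(bessel_ratio(kappa))))


def sd_to_kappa(sigma):
    """Concentration of the Von Mises whose Fisher circular SD is sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rbar = float(np.exp(-0.5 * sigma**2))
    return kappa_from_rbar(rbar)
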