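"""Idealized orientation-tuned neural population with Poisson spiking.

The population has M neurons with Von Mises tuning curves of concentration
kappa, preferred orientations evenly spaced on the (doubled) circle, and a
sigmoidal contrast response.  The mean rate of neuron i to a stimulus of
orientation theta and contrast c is

    r_i(theta, c) = eta + g(c) * gamma * exp(kappa cos(theta - phi_i)) / (M I0(kappa))

where g(c) = c**alpha / (c**alpha + sigma_c**alpha) is the contrast response
(a logistic in log contrast), gamma is the population gain and eta an
optional baseline rate.  The normalisation by M I0(kappa) makes the summed
stimulus-driven rate equal gamma * g(c) independent of kappa and M, so the
expected total spike count in a decode window of length T is

    xi = T * (gamma * g(c) + M * eta).

Spikes are independent Poisson counts with means r_i * T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import special

__all__ = ["PopulationParams", "SpikeVector", "contrast_response", "mean_rates",
           "expected_total", "sample_spikes"]


@dataclass
class PopulationParams:
    """Parameters of the neural population model.

    Attributes
    ----------
    M : int
        Number of neurons (>= 1).
    gamma : float
        Population gain in spikes/s: total stimulus-driven rate at full
        contrast response.
    kappa : float
        Tuning-curve concentration (dimensionless, on the doubled circle).
    alpha : float
        Contrast-response slope exponent.
    sigma_c : float
        Contrast-response semi-saturation contrast (g(sigma_c) = 1/2).
    beta : float
        Response bias in radians, added to the decoded orientation.
    T : float
        Decoding window in seconds.
    eta : float
        Baseline firing rate per neuron, spikes/s.
    """

    M: int = 100
    gamma: float = 145.0
    kappa: float = 2.40
    alpha: float = 48.2
    sigma_c: float = 0.096
    beta: float = -0.050
    T: float = 0.1
    eta: float = 0.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.gamma < 0 or self.kappa < 0 or self.eta < 0:
            raise ValueError("gamma, kappa and eta must be nonnegative")
        if self.alpha <= 0 or self.sigma_c <= 0 or self.T <= 0:
            raise ValueError("alpha, sigma_c and T must be positive")

    @property
    def preferred(self):
        """Preferred orientations, evenly spaced with spacing 2 pi / M,
        wrapped to (-pi, pi]."""
        from .circular import wrap_angle

        return wrap_angle(2.0 * np.pi * np.arange(self.M) / self.M)

    def replace(self, **kwargs) -> "PopulationParams":
        d = asdict(self)
        d.update(kwargs)
        return PopulationParams(**d)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationParams":
        return cls(**json.loads(text))


@dataclass
class SpikeVector:
    """Per-neuron spike counts within one decode window."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def contrast_response(c, params: PopulationParams):
    """Contrast-response gain g(c) = c**alpha / (c**alpha + sigma_c**alpha).

    A hyperbolic-ratio (Naka-Rushton) function: logistic in log contrast,
    with semi-saturation at c = sigma_c and slope controlled by alpha.
    Computed in log space so very large alpha does not overflow.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast must be nonnegative")
    with np.errstate(divide="ignore"):
        # g = 1 / (1 + (sigma_c / c)**alpha), stable via expit of logs
        logratio = params.alpha * (np.log(c) - np.log(params.sigma_c))
    out = special.expit(logratio)
    out = np.where(c == 0.0, 0.0, out)
    return out if out.ndim else float(out)


def mean_rates(theta, c, params: PopulationParams):
    """Mean firing rates (spikes/s) of all M neurons for stimulus
    (theta, c).  Returns an array of shape (M,)."""
    g = contrast_response(c, params)
    tuning = np.exp(params.kappa * (np.cos(theta - params.preferred) - 1.0))
    tuning /= params.M * special.i0e(params.kappa)
    return params.eta + g * params.gamma * tuning


def expected_total(c, params: PopulationParams):
    """Expected total spike count xi = T (gamma g(c) + M eta)."""
    g = contrast_response(c, params)
    out = params.T * (params.gamma * g + params.M * params.eta)
    return out if np.ndim(out) else float(out)


def sample_spikes(theta, c, params: PopulationParams, rng) -> SpikeVector:
    """Draw one Poisson spike vector for stimulus (theta, c)."""
    rates = mean_rates(theta, c, params)
    return SpikeVector(rng.poisson(rates * params.T))


def sample_spike_matrix(theta, c, params: PopulationParams, n, rng) -> np.ndarray:
    """Draw n independent spike vectors as an (n, M) integer array.

    theta may be a scalar or an (n,) array of per-trial orientations.
    """
    theta = np.broadcast_to(np.asarray(theta, dtype=float), (n,))
    g = contrast_response(c, params)
    tuning = np.exp(
        params.kappa * (np.cos(theta[:, None] - params.preferred[None, :]) - 1.0)
    ) / (params.M * special.i0e(params.kappa))
    lam = (params.eta + g * params.gamma * tuning) * params.T
    return rng.poisson(lam)
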