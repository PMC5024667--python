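"""Two-interval forced-choice (2AFC) detection under the population model.

The model observer sees two decoding windows of length T, one containing
the stimulus, and chooses the interval with the larger total spike count
(fair coin on ties).  Without baseline activity the null interval is
always silent, so errors arise only when the stimulus interval is also
silent, giving

    P(correct) = 1 - 0.5 * exp(-xi(c))

and a closed-form 75%-correct threshold: g(c) = ln 2 / (gamma T), inverted
through the contrast-response function.  With baseline activity the
psychometric function is estimated by Monte Carlo; only the two total
counts matter (Poisson superposition), so each interval is simulated as a
single Poisson draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import PopulationParams, contrast_response, expected_total

__all__ = ["DetectionPrediction", "p_zero_spikes", "threshold_closed_form",
           "simulate_2afc", "threshold_monte_carlo"]

LN2 = float(np.log(2.0))


@dataclass
class DetectionPrediction:
    """Psychometric function and 75%-correct threshold."""

    threshold_contrast: float
    contrasts: np.ndarray
    proportion_correct: np.ndarray
    method: str


def p_zero_spikes(c, params: PopulationParams) -> float:
    """Probability of zero total spikes in the decode window at contrast c
    (baseline included): exp(-xi(c))."""
    return float(np.exp(-expected_total(c, params)))


def threshold_closed_form(params: PopulationParams) -> float:
    """Contrast at which 2AFC detection is 75% correct, for eta = 0.

    Solves 1 - 0.5 exp(-gamma T g(c)) = 0.75, i.e. g(c) = ln2/(gamma T),
    giving c = sigma_c * (q / (1 - q))**(1/alpha) with q = ln2/(gamma T).
    """
    if params.eta != 0.0:
        raise ValueError("closed-form threshold requires eta = 0; "
                         "use threshold_monte_carlo")
    q = LN2 / (params.gamma * params.T)
    if q >= 1.0:
        raise ValueError(
            f"75% correct unreachable: gamma*T = {params.gamma * params.T:.3g}"
            " <= ln 2")
    return float(params.sigma_c * (q / (1.0 - q)) ** (1.0 / params.alpha))


def simulate_2afc(c, params: PopulationParams, n_trials, rng,
                  return_counts=False):
    """Simulate n_trials two-interval detections at contrast c and return
    the fraction correct.

    Each interval contributes a single Poisson total (stimulus interval
    mean xi(c); null interval mean M eta T); the observer picks the larger
    count and guesses on ties.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lam_stim = expected_total(c, params)
    lam_null = params.M * params.eta * params.T
    stim = rng.poisson(lam_stim, size=n_trials)
    null = rng.poisson(lam_null, size=n_trials)
    correct = (stim > null) + 0.5 * (stim == null)
    if return_counts:
        return float(correct.mean()), stim, null
    return float(correct.mean())


def threshold_monte_carlo(params: PopulationParams, contrast_grid,
                          n_trials=100_000, rng=None) -> DetectionPrediction:
    """Monte Carlo psychometric function over a contrast grid, with the
    75%-correct threshold by monotone interpolation.

    The raw proportions are made nondecreasing (cumulative maximum) before
    interpolation to suppress Monte Carlo jitter.
    """
    if rng is None:
        rng = np.random.default_rng()
    grid = np.sort(np.asarray(contrast_grid, dtype=float))
    pc = np.array([simulate_2afc(c, params, n_trials, rng) for c in grid])
    pc_mono = np.maximum.accumulate(pc)
    if pc_mono[0] > 0.75 or pc_mono[-1] < 0.75:
        raise ValueError(
            "0.75 not bracketed by the contrast grid: attained range "
            f"[{pc_mono[0]:.3f}, {pc_mono[-1]:.3f}]")
    thr = float(np.interp(0.75, pc_mono, grid))
    return DetectionPrediction(thr, grid, pc, "monte_carlo")
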