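"""Synthetic behavioural datasets with the structure of the orientation
estimation study.

Each synthetic subject is a population-coding observer: spikes are sampled
from the encoder at contrasts fixed relative to that subject's own
model-derived detection threshold, MAP-decoded, and the biased decoded
orientation is the subject's report.  Confidence ratings are a noisy
monotone quantisation of the trial's posterior precision into the five
levels {0, 25, 50, 75, 100}.  The confidence-generation mechanism is a
synthetic stand-in (the behavioural study records confidence but does not
model how it is produced); it exists so the analysis pipeline has a
realistic criterion to detect.

Ground-truth generating parameters are returned alongside the trials so
parameter-recovery experiments can score fitted estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .circular import wrap_angle
from .decoder import decode_resultant_many
from .detection import threshold_closed_form
from .encoder import PopulationParams, sample_spike_matrix
from .fitting import make_trials

__all__ = ["SynthConfig", "assign_threshold", "draw_subject_params",
           "generate_dataset", "generate_subject_trials",
           "CONFIDENCE_LEVELS"]

CONFIDENCE_LEVELS = np.array([0, 25, 50, 75, 100])
# latent-score cut points for the five confidence levels
_CONF_CUTS = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass
class SynthConfig:
    """Configuration of a synthetic multi-subject dataset.

    Defaults reproduce the study's structure: 8 subjects, 280-480 trials
    each, contrasts at 50/100/200/400% of a per-subject detection
    threshold, 100 ms decoding window, and group-mean generating
    parameters equal to the maximum-likelihood group means of the
    population-coding fit (gamma 145 Hz, kappa 2.40, alpha 48.2,
    sigma_c 0.096, beta -0.050 rad).  Between-subject spread is log-normal
    on the positive parameters with per-parameter coefficients of
    variation equal to the reported between-subject dispersion of each
    maximum-likelihood estimate (e.g. 92/145 for the gain), and Gaussian
    (SD ``beta_sd``) on the bias.
    """

    n_subjects: int = 8
    trials_min: int = 280
    trials_max: int = 480
    contrast_levels: tuple = (0.5, 1.0, 2.0, 4.0)
    gamma: float = 145.0
    kappa: float = 2.40
    alpha: float = 48.2
    sigma_c: float = 0.096
    beta: float = -0.050
    M: int = 100
    T: float = 0.1
    gamma_cv: float = 92.0 / 145.0
    kappa_cv: float = 0.58 / 2.40
    alpha_cv: float = 16.6 / 48.2
    sigma_c_cv: float = 0.0081 / 0.096
    beta_sd: float = 0.028
    confidence_noise: float = 0.6
    confidence_scale: float = 1.0
    confidence_mid: float = 0.5
    seed: int = 0

    def group_params(self) -> PopulationParams:
        return PopulationParams(M=self.M, gamma=self.gamma, kappa=self.kappa,
                                alpha=self.alpha, sigma_c=self.sigma_c,
                                beta=self.beta, T=self.T, eta=0.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        if "contrast_levels" in d:
            d["contrast_levels"] = tuple(d["contrast_levels"])
        return cls(**d)


def assign_threshold(params: PopulationParams) -> float:
    """Detection threshold (75% correct contrast) for a synthetic subject,
    from the closed-form no-baseline expression.  Refuses configurations
    whose gain is too low for 75% correct to be reachable."""
    try:
        return threshold_closed_form(params)
    except ValueError as exc:
        raise ValueError(
            "cannot assign a detection threshold for these parameters: "
            f"{exc}") from exc


def draw_subject_params(config: SynthConfig, rng) -> PopulationParams:
    """Draw one synthetic subject's generating parameters around the group
    means (log-normal, median-preserving, per-parameter CV; Gaussian bias).
    Redraws the gain until a 75%-correct detection threshold exists."""

    def _lognorm(mean, cv):
        sd_log = np.sqrt(np.log1p(cv**2))
        return mean * float(np.exp(rng.normal(0, sd_log)))

    params = PopulationParams(
        M=config.M,
        gamma=_lognorm(config.gamma, config.gamma_cv),
        kappa=_lognorm(config.kappa, config.kappa_cv),
        alpha=_lognorm(config.alpha, config.alpha_cv),
        sigma_c=_lognorm(config.sigma_c, config.sigma_c_cv),
        beta=config.beta + float(rng.normal(0, config.beta_sd)),
        T=config.T, eta=0.0,
    )
    while params.gamma * params.T <= np.log(2.0) * 1.05:
        params = params.replace(gamma=_lognorm(config.gamma, config.gamma_cv))
    return params


def _confidence_from_precision(precision, cfg: SynthConfig, rng):
    z = (np.log(np.asarray(precision, dtype=float) + 0.1)
         - cfg.confidence_mid) / cfg.confidence_scale
    z = z + rng.normal(0.0, cfg.confidence_noise, size=z.shape)
    return CONFIDENCE_LEVELS[np.searchsorted(_CONF_CUTS, z)]


def generate_subject_trials(params: PopulationParams, n_trials, rng,
                            contrast_levels=(0.5, 1.0, 2.0, 4.0),
                            subject="s1", cfg: SynthConfig | None = None,
                            balanced=False) -> pd.DataFrame:
    """Simulate one subject's trial table.

    Stimulus orientations are uniform on the circle; contrast levels are
    drawn uniformly (or cycled exactly when ``balanced``).  Reports are
    the bias-shifted MAP decodes of sampled spike vectors.
    """
    if cfg is None:
        cfg = SynthConfig()
    levels = np.asarray(contrast_levels, dtype=float)
    thr = assign_threshold(params)
    if balanced:
        lev_idx = np.repeat(np.arange(levels.size),
                            int(np.ceil(n_trials / levels.size)))[:n_trials]
    else:
        lev_idx = rng.integers(levels.size, size=n_trials)
    c_rel = levels[lev_idx]
    c_abs = c_rel * thr
    theta = rng.uniform(-np.pi, np.pi, size=n_trials)
    counts = np.empty((n_trials, params.M), dtype=int)
    for k in range(levels.size):
        sel = lev_idx == k
        if sel.any():
            counts[sel] = sample_spike_matrix(theta[sel], c_abs[sel][0],
                                              params, int(sel.sum()), rng)
    theta_map, total, prec, guessed = decode_resultant_many(counts, params, rng)
    report = wrap_angle(theta_map + params.beta)
    confidence = _confidence_from_precision(prec, cfg, rng)
    df = make_trials(subject, theta, report, c_rel, contrast_abs=c_abs,
                     confidence=confidence)
    df["total_count"] = total
    df["posterior_precision"] = prec
    df["guessed"] = guessed
    return df


def generate_dataset(config: SynthConfig | None = None, rng=None):
    """Generate a full multi-subject dataset.

    Returns
    -------
    trials : DataFrame
        Pooled trial table with per-trial latent quantities (total count,
        posterior precision, guess flag) included for diagnostics.
    truth : dict
        Generating parameters: the config plus per-subject parameter sets
        and thresholds.
    """
    if config is None:
        config = SynthConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    truth_subjects = {}
    for s in range(config.n_subjects):
        name = f"s{s + 1:02d}"
        params = draw_subject_params(config, rng)
        n_trials = int(rng.integers(config.trials_min, config.trials_max + 1))
        df = generate_subject_trials(params, n_trials, rng,
                                     contrast_levels=config.contrast_levels,
                                     subject=name, cfg=config)
        frames.append(df)
        truth_subjects[name] = {
            "params": asdict(params),
            "threshold": assign_threshold(params),
            "n_trials": n_trials,
        }
    trials = pd.concat(frames, ignore_index=True)
    truth = {"config": asdict(config), "subjects": truth_subjects}
    return trials, truth
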