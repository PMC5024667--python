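"""Maximum-likelihood fitting of trial-level estimation data.

Three rival accounts of orientation-estimation errors are implemented as
model classes in the statsmodels style — construct from a trial table,
call :meth:`fit`, inspect the returned results object:

``PopulationCodingModel``
    Errors follow the analytic population-decoding distribution; five free
    parameters (gamma, kappa, beta, alpha, sigma_c), with the expected
    total count xi = gamma * T * g(c) varying with contrast.
``ThresholdModel``
    Each trial is "seen" with contrast-dependent probability p_c (Von
    Mises error with SD sigma_seen, bias beta) or "unseen" (uniform
    error); 2 + (number of contrast levels) parameters.
``TwoStageModel``
    A circular-normal first stage (per-contrast SD) convolved with the
    population-decoding distribution at fixed (xi, kappa); 4 + 3
    parameters at the study's four contrast levels.

All three are fitted by Nelder-Mead with multiple jittered starts from a
moment-based initializer.  Positivity and range constraints are enforced
by log / logit transforms.  Models are compared by AICc and BIC.

Trial tables are pandas DataFrames with columns ``subject``, ``theta``,
``report`` (radians on the doubled circle), ``contrast_rel`` (multiples of
the subject's detection threshold), optional ``contrast_abs`` and
``confidence``; ``error`` = report (-) theta is derived.  On disk the
angles are stored in degrees of orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import circular
from .circular import bessel_ratio, circ_diff, sd_to_kappa, vm_pdf, wrap_angle
from .decoder import default_grid
from .encoder import PopulationParams, contrast_response
from .error_dist import WalkTableSet, conditional_matrix, walk_table_set

__all__ = [
    "read_trials", "write_trials", "make_trials", "information_criteria",
    "ModelResults", "PopulationCodingModel", "ThresholdModel", "TwoStageModel",
    "compare_models", "loglik_popcode", "fit_popcode", "fit_threshold_model",
    "fit_two_stage",
]

LOGLIK_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def make_trials(subject, theta, report, contrast_rel, contrast_abs=None,
                confidence=None) -> pd.DataFrame:
    """Assemble a trial table from per-trial arrays (angles in radians on
    the doubled circle)."""
    df = pd.DataFrame({
        "subject": subject,
        "theta": wrap_angle(np.asarray(theta, dtype=float)),
        "report": wrap_angle(np.asarray(report, dtype=float)),
        "contrast_rel": np.asarray(contrast_rel, dtype=float),
    })
    if contrast_abs is not None:
        df["contrast_abs"] = np.asarray(contrast_abs, dtype=float)
    if confidence is not None:
        df["confidence"] = np.asarray(confidence)
    if (df["contrast_rel"] <= 0).any():
        raise ValueError("contrast_rel must be positive")
    df["error"] = circ_diff(df["report"].to_numpy(), df["theta"].to_numpy())
    return df


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table to CSV; angles are stored as orientation degrees."""
    out = pd.DataFrame({
        "subject": trials["subject"],
        "theta_deg": circular.circle_to_orientation(trials["theta"].to_numpy()),
        "report_deg": circular.circle_to_orientation(trials["report"].to_numpy()),
        "contrast_rel": trials["contrast_rel"],
    })
    if "contrast_abs" in trials:
        out["contrast_abs"] = trials["contrast_abs"]
    if "confidence" in trials:
        out["confidence"] = trials["confidence"]
    out.to_csv(path, index=False, float_format="%.10g")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table CSV (degrees on disk, radians in memory)."""
    raw = pd.read_csv(path)
    for col in ("subject", "theta_deg", "report_deg", "contrast_rel"):
        if col not in raw:
            raise ValueError(f"trial file is missing column {col!r}")
    return make_trials(
        raw["subject"],
        circular.orientation_to_circle(raw["theta_deg"].to_numpy()),
        circular.orientation_to_circle(raw["report_deg"].to_numpy()),
        raw["contrast_rel"].to_numpy(),
        contrast_abs=raw["contrast_abs"].to_numpy() if "contrast_abs" in raw else None,
        confidence=raw["confidence"].to_numpy() if "confidence" in raw else None,
    )


def information_criteria(llf, k, n):
    """AICc and BIC; AICc is nan when the correction is undefined
    (n <= k + 1)."""
    aic = -2.0 * llf + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1) if n > k + 1 else float("nan")
    bic = -2.0 * llf + k * np.log(n)
    return aicc, bic


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class ModelResults:
    """Fit results for one model on one trial table."""

    model_name: str
    params: dict
    llf: float
    n_params: int
    nobs: int
    converged: bool
    n_starts: int = 1
    nfev: int = 0
    bse: dict | None = None
    notes: list = field(default_factory=list)
    start_llfs: list = field(default_factory=list)

    @property
    def aicc(self) -> float:
        return information_criteria(self.llf, self.n_params, self.nobs)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.llf, self.n_params, self.nobs)[1]

    def to_json(self) -> str:
        import json

        return json.dumps({
            "model_name": self.model_name,
            "params": self.params,
            "log_likelihood": self.llf,
            "n_params": self.n_params,
            "n_trials": self.nobs,
            "aicc": None if np.isnan(self.aicc) else self.aicc,
            "bic": self.bic,
            "converged": self.converged,
            "bse": self.bse,
            "notes": self.notes,
        }, indent=2)

    def summary(self) -> str:
        lines = [
            f"{self.model_name} fit",
            "=" * 58,
            f"{'observations':<22}{self.nobs:>10}",
            f"{'free parameters':<22}{self.n_params:>10}",
            f"{'log-likelihood':<22}{self.llf:>14.3f}",
            f"{'AICc':<22}{self.aicc:>14.3f}",
            f"{'BIC':<22}{self.bic:>14.3f}",
            f"{'converged':<22}{str(self.converged):>10}",
            "-" * 58,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for name, val in self.params.items():
            se = "" if not self.bse or name not in self.bse or \
                not np.isfinite(self.bse[name]) else f"{self.bse[name]:>12.4g}"
            lines.append(f"{name:<14}{val:>12.4g}{se:>12}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Shared optimisation machinery
# ---------------------------------------------------------------------------

def _multistart_nm(neg_loglike, starts, maxfev, xatol=1e-3, fatol=1e-3,
                   polish=True):
    best = None
    llfs = []
    nfev = 0
    for x0 in starts:
        res = optimize.minimize(
            neg_loglike, x0, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                     "adaptive": True})
        nfev += res.nfev
        llfs.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if polish:  # fresh simplex at the incumbent often escapes a stalled one
        res = optimize.minimize(
            neg_loglike, best.x, method="Nelder-Mead",
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                     "adaptive": True})
        nfev += res.nfev
        if res.fun < best.fun:
            best = res
    return best, llfs, nfev


def _numeric_bse(neg_loglike, x, natural, eps=0.005):
    """Standard errors on the natural scale from a central-difference
    Hessian of the negative log likelihood in the transformed space,
    propagated through the full covariance by the delta method.

    On a strongly curved likelihood ridge (gamma-kappa trade-off) these
    local curvature SEs are the honest Wald answer but can still
    understate replicate-to-replicate dispersion.
    """
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei, ej = _unit(n, i, eps), _unit(n, j, eps)
            H[i, j] = H[j, i] = (
                neg_loglike(x + ei + ej) - neg_loglike(x + ei - ej)
                - neg_loglike(x - ei + ej) + neg_loglike(x - ei - ej)
            ) / (4 * eps**2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(cov) <= 0):
        return None
    # delta method: G[i, p] = d natural_p / d x_i at the optimum
    G = np.array([(natural(x + _unit(n, i, eps))
                   - natural(x - _unit(n, i, eps))) / (2 * eps)
                  for i in range(n)])
    var_nat = np.diag(G.T @ cov @ G)
    if np.any(var_nat < 0):
        return None
    return np.sqrt(var_nat)


def _unit(n, i, eps):
    e = np.zeros(n)
    e[i] = eps
    return e


# ---------------------------------------------------------------------------
# Population coding model
# ---------------------------------------------------------------------------

class PopulationCodingModel:
    """Likelihood model for estimation errors under Poisson population
    coding and MAP decoding.

    Parameters
    ----------
    trials : DataFrame
        Trial table (see module docstring).  If a ``contrast_abs`` column
        is present it is used as the contrast entering the contrast
        response function; otherwise ``contrast_rel`` is used and the
        fitted (alpha, sigma_c) are expressed in threshold-relative units.
    T : float
        Decoding window (s).
    grid_n, max_components
        Resolution of the internal density grid and of the equal-mass
        compression of the random-walk table used during optimisation.
    """

    param_names = ("gamma", "kappa", "beta", "alpha", "sigma_c")

    def __init__(self, trials: pd.DataFrame, T=0.1, grid_n=512, max_components=80,
                 table_set: WalkTableSet | None = None):
        self.trials = trials
        self.T = T
        self.grid = default_grid(grid_n)
        self.max_components = max_components
        self.table_set = table_set if table_set is not None else walk_table_set()
        col = "contrast_abs" if "contrast_abs" in trials else "contrast_rel"
        self.contrast_col = col
        self.contrasts = np.sort(trials[col].unique())
        self.errors = trials["error"].to_numpy()
        self._level_idx = [trials.index[trials[col] == c] for c in self.contrasts]
        self._level_err = [trials.loc[ix, "error"].to_numpy() for ix in self._level_idx]
        self.nobs = len(trials)

    # -- likelihood --------------------------------------------------------

    def xi_at(self, c, gamma, alpha, sigma_c):
        g = contrast_response(np.asarray(c, dtype=float),
                              PopulationParams(alpha=alpha, sigma_c=sigma_c,
                                               gamma=max(gamma, 1e-9)))
        return gamma * self.T * g

    def level_densities(self, gamma, kappa, alpha, sigma_c):
        """Error densities (beta = 0) per contrast level on the internal
        grid, sharing one conditional matrix per kappa."""
        xis = np.atleast_1d(self.xi_at(self.contrasts, gamma, alpha, sigma_c))
        m_hi = int(stats.poisson.ppf(1.0 - 1e-8, max(xis.max(), 1e-12))) + 1
        F = conditional_matrix(kappa, self.grid, m_hi, self.table_set,
                               max_components=self.max_components)
        step = 2.0 * np.pi / self.grid.size
        out = []
        for xi in xis:
            pmf = stats.poisson.pmf(np.arange(m_hi + 1), xi)
            dens = pmf @ F
            dens /= dens.sum() * step
            out.append(dens)
        return out

    def loglike(self, params) -> float:
        """Log-likelihood at a parameter dict or array ordered as
        (gamma, kappa, beta, alpha, sigma_c)."""
        if isinstance(params, dict):
            gamma, kappa, beta, alpha, sigma_c = (params[k] for k in self.param_names)
        else:
            gamma, kappa, beta, alpha, sigma_c = params
        if min(gamma, kappa) < 0 or min(alpha, sigma_c) <= 0:
            return -np.inf
        dens_levels = self.level_densities(gamma, kappa, alpha, sigma_c)
        ll = 0.0
        for dens, err in zip(dens_levels, self._level_err):
            p = np.interp(wrap_angle(err - beta), self.grid, dens,
                          period=2.0 * np.pi)
            ll += float(np.log(np.maximum(p, LOGLIK_FLOOR)).sum())
        return ll

    # -- transforms --------------------------------------------------------

    _BOUNDS = {  # transformed-space soft box
        "log_gamma": (np.log(0.5), np.log(3e3)),
        "log_kappa": (np.log(1e-3), np.log(200.0)),
        "beta": (-1.5, 1.5),
        "log_alpha": (np.log(0.2), np.log(1e3)),
        "log_sigma_c": None,  # set per dataset
    }

    def _natural(self, x):
        return np.array([np.exp(x[0]), np.exp(x[1]), x[2], np.exp(x[3]),
                         np.exp(x[4])])

    def _transform(self, p):
        return np.array([np.log(p[0]), np.log(p[1]), p[2], np.log(p[3]),
                         np.log(p[4])])

    def _penalty(self, x):
        lo_sc = np.log(self.contrasts.min() * 1e-3)
        hi_sc = np.log(self.contrasts.max() * 10.0)
        bounds = [self._BOUNDS["log_gamma"], self._BOUNDS["log_kappa"],
                  self._BOUNDS["beta"], self._BOUNDS["log_alpha"],
                  (lo_sc, hi_sc)]
        pen = 0.0
        for xi_, (lo, hi) in zip(x, bounds):
            if xi_ < lo:
                pen += 1e4 * (lo - xi_) ** 2
            elif xi_ > hi:
                pen += 1e4 * (xi_ - hi) ** 2
        return pen

    # -- initialisation ----------------------------------------------------

    def start_params(self) -> dict:
        """Moment-based starting point: per-level precision inverted to an
        expected count through the high-gain limit precision ~= kappa
        A(kappa) xi, then gain/contrast-response constants read off the
        xi-vs-contrast profile."""
        kappa0 = 2.0
        scale = kappa0 * bessel_ratio(kappa0)
        prec = []
        for err in self._level_err:
            rbar, _ = circular.resultant(err)
            rbar = min(rbar, 1.0 - 1e-9)
            sd2 = -2.0 * np.log(rbar) if rbar > 0 else np.inf
            prec.append(0.0 if not np.isfinite(sd2) else 1.0 / sd2)
        xi_hat = np.clip(np.asarray(prec) / scale, 0.05, 500.0)
        gamma0 = float(xi_hat.max() / self.T)
        # half-saturation: contrast where xi crosses half its maximum
        target = 0.5 * xi_hat.max()
        logc = np.log(self.contrasts)
        if np.all(xi_hat >= target):
            sigma_c0 = float(self.contrasts[0] * 0.7)
        else:
            below = np.flatnonzero(xi_hat < target)
            i = below[-1]
            if i + 1 < len(xi_hat):
                frac = (target - xi_hat[i]) / max(xi_hat[i + 1] - xi_hat[i], 1e-9)
                sigma_c0 = float(np.exp(logc[i] + frac * (logc[i + 1] - logc[i])))
            else:
                sigma_c0 = float(self.contrasts[-1])
        alpha0 = 10.0
        top_err = self._level_err[-1]
        _, beta0 = circular.resultant(top_err)
        if not np.isfinite(beta0):
            beta0 = 0.0
        return {"gamma": gamma0, "kappa": kappa0, "beta": float(beta0),
                "alpha": alpha0, "sigma_c": sigma_c0}

    # -- fitting -----------------------------------------------------------

    def fit(self, start=None, n_starts=4, seed=0, maxfev=600,
            compute_se=True) -> ModelResults:
        start = dict(self.start_params(), **(start or {}))
        x0 = self._transform([start[k] for k in self.param_names])
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(n_starts - 1):
            jit = x0 + np.r_[rng.normal(0, 0.35, 2), rng.normal(0, 0.1),
                             rng.normal(0, 0.5, 2)]
            starts.append(jit)

        def nll(x):
            pen = self._penalty(x)
            return -self.loglike(self._natural(x)) + pen

        best, llfs, nfev = _multistart_nm(nll, starts, maxfev)
        nat = self._natural(best.x)
        params = dict(zip(self.param_names, map(float, nat)))
        notes = []
        if len(self.contrasts) < 2:
            notes.append("alpha and sigma_c are unidentifiable with a single "
                         "contrast level (flat likelihood)")
        bse = None
        if compute_se and best.success:
            se = _numeric_bse(nll, best.x, self._natural)
            if se is not None:
                bse = dict(zip(self.param_names, map(float, se)))
        return ModelResults("population coding", params, -best.fun
                            + self._penalty(best.x), 5, self.nobs,
                            bool(best.success), len(starts), nfev, bse, notes,
                            llfs)


# ---------------------------------------------------------------------------
# Threshold (seen / unseen mixture) model
# ---------------------------------------------------------------------------

class ThresholdModel:
    """Seen/unseen mixture: with probability p_c the error is Von Mises
    (SD sigma_seen, bias beta); otherwise uniform."""

    def __init__(self, trials: pd.DataFrame):
        self.trials = trials
        self.levels = np.sort(trials["contrast_rel"].unique())
        self._level_err = [trials.loc[trials["contrast_rel"] == c, "error"].to_numpy()
                           for c in self.levels]
        self.nobs = len(trials)
        self.param_names = ("sigma_seen", "beta") + tuple(
            f"p_{_fmt_level(c)}" for c in self.levels)

    def loglike(self, params) -> float:
        if isinstance(params, dict):
            vals = [params[k] for k in self.param_names]
        else:
            vals = list(params)
        sigma_seen, beta = vals[0], vals[1]
        ps = np.asarray(vals[2:], dtype=float)
        if sigma_seen <= 0 or np.any((ps < 0) | (ps > 1)):
            return -np.inf
        kappa = sd_to_kappa(min(sigma_seen, 10.0))
        ll = 0.0
        for p, err in zip(ps, self._level_err):
            dens = p * vm_pdf(err, beta, kappa) + (1.0 - p) / (2.0 * np.pi)
            ll += float(np.log(np.maximum(dens, LOGLIK_FLOOR)).sum())
        return ll

    def start_params(self) -> dict:
        out = {}
        top = self._level_err[-1]
        sd = circular.circ_sd(top)
        out["sigma_seen"] = float(np.clip(sd if np.isfinite(sd) else 1.0, 0.1, 2.0))
        _, mu = circular.resultant(top)
        out["beta"] = float(mu) if np.isfinite(mu) else 0.0
        for c, err in zip(self.levels, self._level_err):
            central = np.mean(np.abs(err) < np.pi / 2)
            out[f"p_{_fmt_level(c)}"] = float(np.clip(2 * central - 1, 0.02, 0.98))
        return out

    def _natural(self, x):
        from scipy.special import expit
        return np.r_[np.exp(x[0]), x[1], expit(x[2:])]

    def _transform(self, vals):
        from scipy.special import logit
        return np.r_[np.log(vals[0]), vals[1],
                     logit(np.clip(vals[2:], 1e-4, 1 - 1e-4))]

    def fit(self, start=None, n_starts=3, seed=0, maxfev=1200,
            compute_se=False) -> ModelResults:
        start = dict(self.start_params(), **(start or {}))
        x0 = self._transform(np.array([start[k] for k in self.param_names]))
        rng = np.random.default_rng(seed)
        starts = [x0] + [x0 + rng.normal(0, 0.4, x0.size)
                         for _ in range(n_starts - 1)]

        def nll(x):
            if abs(x[0]) > 6 or np.any(np.abs(x[2:]) > 12):
                return 1e12
            return -self.loglike(self._natural(x))

        best, llfs, nfev = _multistart_nm(nll, starts, maxfev)
        nat = self._natural(best.x)
        params = dict(zip(self.param_names, map(float, nat)))
        notes = []
        if all(params[k] < 0.02 for k in self.param_names[2:]):
            notes.append("all p_c near 0: sigma_seen is unidentifiable")
        if sd_to_kappa(min(params["sigma_seen"], 10.0)) < 0.2:
            notes.append("seen component is near-uniform: sigma_seen and "
                         "p_c are jointly unidentifiable")
        bse = None
        if compute_se and best.success:
            se = _numeric_bse(nll, best.x, self._natural)
            if se is not None:
                bse = dict(zip(self.param_names, map(float, se)))
        k = len(self.param_names)
        return ModelResults("threshold", params, -best.fun, k, self.nobs,
                            bool(best.success), len(starts), nfev, bse, notes,
                            llfs)


def _fmt_level(c):
    pct = 100.0 * c
    return f"{pct:g}%"


# ---------------------------------------------------------------------------
# Two-stage (normal perception -> population code) model
# ---------------------------------------------------------------------------

class TwoStageModel:
    """Circular-normal first-stage error (per-contrast SD) convolved with
    the population-decoding error distribution at shared (xi, kappa)."""

    def __init__(self, trials: pd.DataFrame, grid_n=512, max_components=80,
                 table_set: WalkTableSet | None = None):
        self.trials = trials
        self.levels = np.sort(trials["contrast_rel"].unique())
        self._level_err = [trials.loc[trials["contrast_rel"] == c, "error"].to_numpy()
                           for c in self.levels]
        self.nobs = len(trials)
        self.grid = default_grid(grid_n)
        self.max_components = max_components
        self.table_set = table_set if table_set is not None else walk_table_set()
        self.param_names = tuple(f"sigma_{_fmt_level(c)}" for c in self.levels) \
            + ("beta", "kappa", "xi")

    def _popcode_density(self, xi, kappa):
        m_hi = int(stats.poisson.ppf(1.0 - 1e-8, max(xi, 1e-12))) + 1
        F = conditional_matrix(kappa, self.grid, m_hi, self.table_set,
                               max_components=self.max_components)
        pmf = stats.poisson.pmf(np.arange(m_hi + 1), xi)
        dens = pmf @ F
        step = 2.0 * np.pi / self.grid.size
        return dens / (dens.sum() * step)

    def predicted_density(self, sigma, beta, kappa, xi, _base=None):
        """Density for one contrast level: circular convolution of the Von
        Mises first stage (SD sigma) with the decoding distribution, then
        bias shift (applied by the caller through the evaluation point)."""
        base = self._popcode_density(xi, kappa) if _base is None else _base
        n = self.grid.size
        step = 2.0 * np.pi / n
        kap1 = sd_to_kappa(min(sigma, 10.0))
        offs = wrap_angle(step * np.arange(n))
        kern = vm_pdf(offs, 0.0, kap1)
        conv = np.fft.irfft(np.fft.rfft(base) * np.fft.rfft(kern), n) * step
        conv = np.maximum(conv, 0.0)
        return conv / (conv.sum() * step)

    def loglike(self, params) -> float:
        if isinstance(params, dict):
            vals = [params[k] for k in self.param_names]
        else:
            vals = list(params)
        nlev = len(self.levels)
        sigmas = np.asarray(vals[:nlev], dtype=float)
        beta, kappa, xi = vals[nlev], vals[nlev + 1], vals[nlev + 2]
        if np.any(sigmas <= 0) or kappa < 0 or xi < 0:
            return -np.inf
        base = self._popcode_density(xi, kappa)  # shared across levels
        ll = 0.0
        for sigma, err in zip(sigmas, self._level_err):
            dens = self.predicted_density(sigma, beta, kappa, xi, _base=base)
            p = np.interp(wrap_angle(err - beta), self.grid, dens,
                          period=2.0 * np.pi)
            ll += float(np.log(np.maximum(p, LOGLIK_FLOOR)).sum())
        return ll

    def start_params(self) -> dict:
        out = {}
        for c, err in zip(self.levels, self._level_err):
            sd = circular.circ_sd(err)
            out[f"sigma_{_fmt_level(c)}"] = float(np.clip(
                sd if np.isfinite(sd) else 3.0, 0.05, 5.0))
        _, mu = circular.resultant(self._level_err[-1])
        out["beta"] = float(mu) if np.isfinite(mu) else 0.0
        out["kappa"] = 5.0
        out["xi"] = 10.0
        return out

    def _natural(self, x):
        nlev = len(self.levels)
        return np.r_[np.exp(x[:nlev]), x[nlev], np.exp(x[nlev + 1]),
                     np.exp(x[nlev + 2])]

    def _transform(self, vals):
        nlev = len(self.levels)
        vals = np.asarray(vals, dtype=float)
        return np.r_[np.log(vals[:nlev]), vals[nlev], np.log(vals[nlev + 1]),
                     np.log(vals[nlev + 2])]

    def fit(self, start=None, n_starts=3, seed=0, maxfev=900,
            compute_se=False) -> ModelResults:
        start = dict(self.start_params(), **(start or {}))
        x0 = self._transform([start[k] for k in self.param_names])
        rng = np.random.default_rng(seed)
        starts = [x0] + [x0 + rng.normal(0, 0.3, x0.size)
                         for _ in range(n_starts - 1)]

        def nll(x):
            if np.any(np.abs(x) > 9):
                return 1e12
            return -self.loglike(self._natural(x))

        best, llfs, nfev = _multistart_nm(nll, starts, maxfev)
        nat = self._natural(best.x)
        params = dict(zip(self.param_names, map(float, nat)))
        bse = None
        if compute_se and best.success:
            se = _numeric_bse(nll, best.x, self._natural)
            if se is not None:
                bse = dict(zip(self.param_names, map(float, se)))
        k = len(self.param_names)
        return ModelResults("two-stage", params, -best.fun, k, self.nobs,
                            bool(best.success), len(starts), nfev, bse, [],
                            llfs)


# ---------------------------------------------------------------------------
# Model comparison and functional wrappers
# ---------------------------------------------------------------------------

def compare_models(results) -> pd.DataFrame:
    """AICc / BIC comparison table; deltas are relative to the best
    (smallest) value.  All results must come from the same trial set."""
    nobs = {r.nobs for r in results}
    if len(nobs) != 1:
        raise ValueError("all fits must be on the identical trial set")
    df = pd.DataFrame({
        "model": [r.model_name for r in results],
        "k": [r.n_params for r in results],
        "loglik": [r.llf for r in results],
        "aicc": [r.aicc for r in results],
        "bic": [r.bic for r in results],
    })
    df["d_aicc"] = df["aicc"] - np.nanmin(df["aicc"])
    df["d_bic"] = df["bic"] - np.nanmin(df["bic"])
    return df


def loglik_popcode(trials, params, **kwargs) -> float:
    """Log-likelihood of the population coding model at a parameter dict
    with keys gamma, kappa, beta, alpha, sigma_c."""
    return PopulationCodingModel(trials, **kwargs).loglike(params)


def fit_popcode(trials, start=None, **kwargs) -> ModelResults:
    model_kw = {k: kwargs.pop(k) for k in ("T", "grid_n", "max_components",
                                           "table_set") if k in kwargs}
    return PopulationCodingModel(trials, **model_kw).fit(start=start, **kwargs)


def fit_threshold_model(trials, start=None, **kwargs) -> ModelResults:
    return ThresholdModel(trials).fit(start=start, **kwargs)


def fit_two_stage(trials, start=None, **kwargs) -> ModelResults:
    model_kw = {k: kwargs.pop(k) for k in ("grid_n", "max_components",
                                           "table_set") if k in kwargs}
    return TwoStageModel(trials, **model_kw).fit(start=start, **kwargs)
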