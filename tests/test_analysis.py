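"""Results-level analyses on simulated and synthetic data."""

import numpy as np
import pandas as pd
import pytest

from popcode.analysis import (anisotropy_control, confidence_error_correlation,
                              deviation_from_normal, match_baseline,
                              median_split, precision_by_contrast,
                              simulate_decoding_trials,
                              spikecount_posterior_corr)
from popcode.circular import vm_sample
from popcode.detection import threshold_closed_form
from popcode.encoder import PopulationParams
from popcode.fitting import make_trials


def _sim_trials(params, rng, n_per=4000):
    thr = threshold_closed_form(params)
    levels = np.array([0.5, 1.0, 2.0, 4.0])
    return simulate_decoding_trials(params, thr * levels, n_per, rng,
                                    contrast_rel=levels)


class TestPrecisionByContrast:
    def test_monotone_in_contrast(self, group_params, rng):
        # the top two levels share a saturated expected count at the
        # group-mean contrast response, so they are equal up to noise
        sims = _sim_trials(group_params, rng)
        out = precision_by_contrast(sims).sort_values("contrast_rel")
        prec = out["precision"].to_numpy()
        se = out["se"].to_numpy()
        assert np.all(np.diff(prec) >= -2 * np.hypot(se[:-1], se[1:]))
        assert np.all(np.diff(prec[:3]) > 0)
        assert prec[-1] > prec[0]

    def test_uniform_errors_at_chance(self, rng):
        df = pd.DataFrame({"contrast_rel": 1.0,
                           "error": rng.uniform(-np.pi, np.pi, 5000)})
        out = precision_by_contrast(df)
        assert out["precision"].iloc[0] == pytest.approx(
            out["chance"].iloc[0], abs=0.05)

    def test_degenerate_all_zero_errors(self):
        df = pd.DataFrame({"contrast_rel": 1.0, "error": np.zeros(100)})
        out = precision_by_contrast(df)
        assert np.isinf(out["precision"].iloc[0])


class TestDeviationFromNormal:
    def test_vm_data_self_match(self, rng):
        errors = vm_sample(0.1, 3.0, 100_000, rng)
        curve = deviation_from_normal(errors)
        n_per_bin = errors.size / curve.bin_centers.size
        se = np.sqrt(1.0 / (curve.bin_centers.size * errors.size))
        assert np.abs(curve.deviation).mean() < 3 * se
        assert curve.deviation.sum() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_data_near_zero(self, rng):
        errors = rng.uniform(-np.pi, np.pi, 50_000)
        curve = deviation_from_normal(errors)
        assert np.abs(curve.deviation).max() < 0.01
        assert curve.matched_kappa < 0.05

    def test_threshold_regime_long_tail_signature(self, group_params,
                                                  table_set, rng):
        """Positive deviation at the centre and in the far tails, negative
        at the flanks: the long-tail signature at threshold gain."""
        from popcode.error_dist import simulate_error_sample
        errors = simulate_error_sample(np.log(2), 2.4, 0.0, 200_000, rng)
        curve = deviation_from_normal(errors)
        x = curve.bin_centers
        centre = np.abs(x) < 0.2
        tails = np.abs(x) > 2.5
        flanks = (np.abs(x) > 0.5) & (np.abs(x) < 1.3)
        assert curve.deviation[centre].mean() > 0
        assert curve.deviation[tails].mean() > 0
        assert curve.deviation[flanks].mean() < 0


class TestConfidenceCorrelation:
    @staticmethod
    def _table(rng, link):
        theta = rng.uniform(-np.pi, np.pi, 800)
        err = vm_sample(0.0, 2.0, 800, rng)
        conf = link(np.abs(err), rng)
        return make_trials("s1", theta, theta + err, np.ones(800),
                           confidence=conf)

    def test_deterministic_link_r2_one(self, rng):
        t = self._table(rng, lambda a, r: 100 - 100 * a / np.pi)
        out = confidence_error_correlation(t)
        assert out["r2_mean"].iloc[0] == pytest.approx(1.0)

    def test_independent_confidence_nonsignificant(self, rng):
        frames = [make_trials(f"s{i}", np.zeros(200),
                              vm_sample(0.0, 2.0, 200, rng),
                              np.ones(200),
                              confidence=rng.choice([0, 25, 50, 75, 100], 200))
                  for i in range(8)]
        out = confidence_error_correlation(pd.concat(frames,
                                                     ignore_index=True))
        assert out["p"].iloc[0] > 0.01
        assert out["r2_mean"].iloc[0] < 0.05  # small-sample bias only

    def test_constant_confidence_excluded(self, rng):
        t = self._table(rng, lambda a, r: np.full(a.size, 50))
        out = confidence_error_correlation(t)
        assert out["n_excluded"].iloc[0] == 1


class TestMedianSplit:
    def test_balanced_halves(self, rng):
        df = pd.DataFrame({"contrast_rel": np.repeat([1.0, 2.0], 101),
                           "error": rng.normal(0, 0.3, 202),
                           "crit": rng.random(202)})
        out = median_split(df, "crit", rng=rng)
        assert (np.abs(out.table["n_high"] - out.table["n_low"]) <= 1).all()

    def test_ties_randomised_to_balance(self, rng):
        df = pd.DataFrame({"contrast_rel": 1.0,
                           "error": rng.normal(0, 0.3, 400),
                           "crit": np.zeros(400)})
        out = median_split(df, "crit", rng=rng)
        assert out.table["n_high"].iloc[0] == out.table["n_low"].iloc[0] == 200

    def test_precision_split_ordering(self, group_params, rng):
        """Trials with high posterior precision are more precise at every
        contrast level."""
        sims = _sim_trials(group_params, rng, n_per=8000)
        out = median_split(sims, "posterior_precision", rng=rng)
        # at 50% of threshold all trials are zero-count guesses: the
        # criterion is constant and the split carries no information
        informative = out.table[out.table["contrast_rel"] >= 1.0]
        assert len(informative) == 3
        assert (informative["precision_high"] >
                informative["precision_low"]).all()

    def test_mse_against_reference(self, group_params, rng):
        sims = _sim_trials(group_params, rng, n_per=4000)
        ref = median_split(sims, "posterior_precision", rng=rng)
        out = median_split(sims, "total_count", rng=rng, reference=ref)
        assert out.mse_vs_reference is not None
        assert out.mse_vs_reference >= 0


class TestSpikecountPosteriorCorr:
    def test_near_deterministic_regime(self, rng):
        p = PopulationParams(gamma=80.0, kappa=20.0)
        r2 = spikecount_posterior_corr(p, [10.0], 10_000, rng)
        assert r2 > 0.9

    def test_degenerate_counts_flagged(self, rng):
        p = PopulationParams(gamma=8.0)
        with pytest.warns(UserWarning):
            r2 = spikecount_posterior_corr(p, [1e-6], 2_000, rng)
        assert np.isnan(r2)


class TestAnisotropyControl:
    def test_homogeneous_bins_near_zero(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 20_000)
        err = vm_sample(0.0, 3.0, 20_000, rng)
        t = make_trials("s1", theta, theta + err, np.ones(20_000))
        curve = anisotropy_control(t, n_sim=100_000, rng=rng)
        assert np.abs(curve.deviation).max() < 0.01

    def test_single_bin_reduces_to_matched_vm(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 5_000)
        err = vm_sample(0.0, 3.0, 5_000, rng)
        t = make_trials("s1", theta, theta + err, np.ones(5_000))
        curve = anisotropy_control(t, n_bins=1, n_sim=100_000, rng=rng)
        assert np.abs(curve.deviation).max() < 0.01

    def test_oblique_bias_far_below_threshold_signature(self, table_set,
                                                        rng):
        """Stimulus-dependent biases alone produce deviations an order of
        magnitude smaller than the population model at threshold gain."""
        from popcode.error_dist import simulate_error_sample
        n = 40_000
        theta = rng.uniform(-np.pi, np.pi, n)
        bias = 0.15 * np.sin(2 * theta)  # repulsion from cardinals
        err = vm_sample(0.0, 3.0, n, rng) + bias
        t = make_trials("s1", theta, theta + err, np.ones(n))
        aniso = anisotropy_control(t, n_sim=200_000, rng=rng)
        popdev = deviation_from_normal(
            simulate_error_sample(np.log(2), 2.4, 0.0, 200_000, rng))
        assert np.abs(aniso.deviation).max() < \
            np.abs(popdev.deviation).max() / 5


class TestMatchBaseline:
    def test_self_match_at_zero_eta(self, table_set):
        p = PopulationParams(gamma=28.8, kappa=2.12)
        res = match_baseline(p, 0.0,
                             gamma_grid=p.gamma * np.array([0.8, 1.0, 1.25]),
                             kappa_grid=p.kappa * np.array([0.8, 1.0, 1.25]),
                             n_sim=4000, rng=np.random.default_rng(0))
        assert res.gamma_matched == pytest.approx(28.8)
        assert res.kappa_matched == pytest.approx(2.12)
        # the floor is Monte Carlo histogram noise (4 contrasts summed)
        assert res.distance < 0.3
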