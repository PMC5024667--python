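"""The analytic decoding-error distribution and its building blocks."""

import numpy as np
import pytest

from popcode.circular import bessel_ratio, vm_pdf
from popcode.decoder import default_grid
from popcode.error_dist import (ErrorDensity, conditional_matrix,
                                error_density, error_density_given_m,
                                projected_normal_logpdf, simulate_error_sample,
                                tilt_cutoff_m, uniform_walk_resultant,
                                vm_walk_resultant, walk_table_set)


class TestUniformWalkTable:
    def test_one_step_mass_at_unit_length(self, rng):
        tab = uniform_walk_resultant(1, 20_000, rng)
        assert tab.density[tab.bin_centers <= 0.99].sum() < 1e-12
        assert tab.density[np.abs(tab.bin_centers - 1.0) < 0.01].sum() == \
            pytest.approx(1.0)

    def test_two_step_closed_form_cdf(self, rng):
        # r = 2|cos(D/2)| with D uniform: P(r <= sqrt(2)) = 1/2
        tab = uniform_walk_resultant(2, 200_000, rng)
        cdf_at_sqrt2 = tab.density[tab.bin_centers <= np.sqrt(2)].sum()
        assert cdf_at_sqrt2 == pytest.approx(0.5, abs=0.01)

    def test_hundred_step_rayleigh_moments(self, table_set):
        # m large: r is Rayleigh(sigma^2 = m/2): E r = sqrt(pi m)/2,
        # SD = sqrt((4 - pi) m / 4)
        tab = table_set.table(100)
        mean = (tab.bin_centers * tab.density).sum()
        sd = np.sqrt((tab.bin_centers**2 * tab.density).sum() - mean**2)
        assert mean == pytest.approx(np.sqrt(np.pi * 100) / 2, rel=0.02)
        assert sd == pytest.approx(np.sqrt((4 - np.pi) * 100 / 4), rel=0.02)

    def test_save_load_round_trip(self, table_set, tmp_path):
        from popcode.error_dist import load_table, save_table
        tab = table_set.table(7)
        path = tmp_path / "walk_m7.tsv"
        save_table(tab, path)
        back = load_table(path)
        assert back.m == 7 and back.n_sim == tab.n_sim
        assert np.allclose(back.density, tab.density, atol=1e-10)

    def test_density_normalised_and_supported(self, table_set):
        for m in (1, 7, 60):
            tab = table_set.table(m)
            assert tab.density.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(tab.bin_centers <= m)


class TestVmWalkTilting:
    def test_zero_kappa_identity(self, table_set):
        tab = table_set.table(5)
        assert np.allclose(vm_walk_resultant(5, 0.0, tab), tab.density)

    def test_mean_resultant_vs_brute_force(self, table_set, rng):
        tab = table_set.table(5)
        w = vm_walk_resultant(5, 2.0, tab)
        mean_tilt = (tab.bin_centers * w).sum()
        steps = rng.vonmises(0.0, 2.0, size=(200_000, 5))
        mean_mc = np.abs(np.exp(1j * steps).sum(axis=1)).mean()
        assert mean_tilt == pytest.approx(mean_mc, rel=0.01)

    def test_mass_shifts_out_with_kappa(self, table_set):
        tab = table_set.table(8)
        means = [(tab.bin_centers * vm_walk_resultant(8, k, tab)).sum()
                 for k in (0.0, 1.0, 4.0)]
        assert means[0] < means[1] < means[2]


class TestConditionalDensity:
    def test_one_spike_exact_vm(self, table_set):
        grid = default_grid(512)
        d = error_density_given_m(1, 2.4, grid, table_set)
        assert np.allclose(d, vm_pdf(grid, 0.0, 2.4))

    def test_zero_kappa_uniform(self, table_set):
        grid = default_grid(128)
        for m in (1, 5, 40):
            assert np.allclose(error_density_given_m(m, 0.0, grid, table_set),
                               1 / (2 * np.pi))

    def test_ten_spikes_matches_conditioned_simulation(self, table_set, rng):
        """Conditional density at m=10 vs decoded errors of simulated
        10-spike trials (encode/decode pipeline conditioned on m)."""
        from popcode.decoder import decode_resultant_many
        from popcode.encoder import PopulationParams, sample_spike_matrix

        p = PopulationParams(M=100, kappa=2.0, gamma=100.0, beta=0.0)
        th = rng.uniform(-np.pi, np.pi, 60_000)
        counts = sample_spike_matrix(th, 10.0, p, 60_000, rng)
        sel = counts.sum(axis=1) == 10
        theta_map, _, _, _ = decode_resultant_many(counts[sel], p, rng)
        err = np.angle(np.exp(1j * (theta_map - th[sel])))
        grid = default_grid(1024)
        dens = ErrorDensity(grid, error_density_given_m(10, 2.0, grid,
                                                        table_set), 10, 2.0)
        assert dens.tv_distance_hist(err) < 0.02

    def test_projected_normal_agrees_with_tilted_table_at_handover(
            self, table_set):
        """Continuity across the tilted-table -> projected-normal switch."""
        kappa = 2.4
        m_sw = tilt_cutoff_m(kappa)
        grid = default_grid(1024)
        tilt = error_density_given_m(m_sw, kappa, grid, table_set)
        from popcode.error_dist import _projected_normal_pdf_rows
        pn = _projected_normal_pdf_rows([m_sw], kappa, grid)[0]
        step = 2 * np.pi / grid.size
        # both routes are within ~1% TV of the truth at the switch point
        assert 0.5 * np.abs(tilt - pn).sum() * step < 0.02

    def test_projected_normal_logpdf_normalised(self):
        grid = default_grid(4096)
        for mean_len, vc, vs in [(5.0, 2.0, 3.0), (50.0, 10.0, 12.0)]:
            lp = projected_normal_logpdf(grid, mean_len, vc, vs)
            total = np.exp(lp).sum() * (2 * np.pi / grid.size)
            assert total == pytest.approx(1.0, abs=1e-3)


class TestMarginalDensity:
    def test_zero_gain_uniform(self, table_set):
        d = error_density(0.0, 2.4, table_set=table_set)
        assert np.allclose(d.density, 1 / (2 * np.pi))

    def test_normalisation(self, table_set):
        for xi in (0.3, 2.0, 14.5, 120.0):
            d = error_density(xi, 2.4, beta=-0.05, table_set=table_set)
            assert d.density.sum() * d.step == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_without_bias(self, table_set):
        d = error_density(3.0, 2.4, table_set=table_set)
        assert np.abs(d.density - d.density[::-1]).max() < 1e-4

    def test_beta_shifts_mode(self, table_set):
        d = error_density(50.0, 2.4, beta=0.3, table_set=table_set)
        mode = d.grid[np.argmax(d.density)]
        assert mode == pytest.approx(0.3, abs=0.02)

    def test_mixture_consistency(self, table_set):
        """Poisson-weighted sum of conditionals reproduces the marginal."""
        from scipy import stats
        xi, kappa = 6.0, 2.4
        grid = default_grid(512)
        m_hi = int(stats.poisson.ppf(1 - 1e-8, xi)) + 1
        pmf = stats.poisson.pmf(np.arange(m_hi + 1), xi)
        F = conditional_matrix(kappa, grid, m_hi, table_set)
        manual = pmf @ F
        manual /= manual.sum() * (2 * np.pi / grid.size)
        d = error_density(xi, kappa, grid=grid, table_set=table_set)
        assert np.abs(manual - d.density).max() < 1e-12

    def test_high_gain_approaches_single_vm(self, table_set):
        d = error_density(200.0, 2.4, table_set=table_set)
        # matched VM: concentration giving the same circular variance
        z1, _ = d.circ_moments()
        from popcode.circular import kappa_from_rbar
        ref = vm_pdf(d.grid, 0.0, kappa_from_rbar(abs(z1)))
        assert 0.5 * np.abs(d.density - ref).sum() * d.step < 0.01
        assert abs(d.circ_kurtosis_excess()) < 0.05

    def test_walk_simulation_oracle(self, table_set, rng):
        for xi in (0.7, 14.5):
            d = error_density(xi, 2.4, table_set=table_set)
            s = simulate_error_sample(xi, 2.4, 0.0, 80_000, rng)
            assert d.tv_distance_hist(s) < 0.02

    def test_compressed_density_close_to_full(self, table_set):
        grid = default_grid(512)
        full = error_density(14.5, 2.4, grid=grid, table_set=table_set)
        comp = error_density(14.5, 2.4, grid=grid, table_set=table_set,
                             max_components=80)
        assert 0.5 * np.abs(full.density - comp.density).sum() * full.step \
            < 2e-3

    def test_kurtosis_progression(self, table_set):
        """Non-normality signature: ~0 at high gain, positive at
        intermediate gain, -> 0 towards the uniform limit."""
        excesses = {xi: error_density(xi, 2.4,
                                      table_set=table_set).circ_kurtosis_excess()
                    for xi in (0.05, np.log(2), 14.5, 100.0)}
        assert abs(excesses[100.0]) < 0.1
        assert excesses[np.log(2)] > 0.1
        assert excesses[14.5] > excesses[100.0]
        assert abs(excesses[0.05]) < 0.1  # near-uniform regime

    def test_vm_fit_worse_than_own_density(self, table_set, rng):
        """At threshold-regime gain the error distribution is genuinely
        non-normal: the best VM's log likelihood falls short."""
        from scipy import optimize
        xi = np.log(2)
        d = error_density(xi, 2.4, table_set=table_set)
        s = simulate_error_sample(xi, 2.4, 0.0, 20_000, rng)
        ll_model = d.loglik(s)

        def nll_vm(logk):
            return -np.log(np.maximum(vm_pdf(s, 0.0, np.exp(logk[0])),
                                      1e-300)).sum()
        res = optimize.minimize(nll_vm, [0.0], method="Nelder-Mead")
        assert ll_model > -res.fun + 50  # decisively better
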