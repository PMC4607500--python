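"""Magnitude noise densities, coil simulation and signal combination."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gamma
from scipy.stats import kstest, ncx2

from rumbasd.noise import (
    CoilConfig,
    NoiseModel,
    combine_smf,
    combine_sos,
    contaminate,
    make_sensitivity_maps,
    ncchi_pdf,
    rician_pdf,
    simulate_coil_signals,
)


class TestDensities:
    def test_zero_below_origin(self):
        s = np.array([-2.0, -1e-9, 0.0])
        assert np.all(rician_pdf(s, 1.0, 0.5) == 0.0)
        assert np.all(ncchi_pdf(s, 1.0, 0.5, 8.0) == 0.0)

    def test_rician_equals_ncchi_order_one(self):
        s = np.linspace(0.0, 6.0, 10)
        sbar = np.linspace(0.0, 3.0, 10)[:, None]
        sig2 = np.array([0.04, 0.5, 2.0])[:, None, None]
        a = rician_pdf(s, sbar, sig2)
        b = ncchi_pdf(s, sbar, sig2, n=1.0)
        assert np.allclose(a, b, atol=1e-12, rtol=0)

    @pytest.mark.parametrize("n", [1.0, 2.0, 4.5, 8.0])
    @pytest.mark.parametrize("sbar", [0.0, 0.8])
    def test_normalization(self, n, sbar):
        sig2 = 0.09
        upper = sbar + 10.0 * np.sqrt(sig2) * max(1.0, np.sqrt(n))
        val, _ = quad(lambda s: ncchi_pdf(s, sbar, sig2, n), 0.0, upper, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_central_chi_mean_order_eight(self):
        # E[S | Sbar=0] = sigma * sqrt(2) * Gamma(n + 1/2) / Gamma(n)
        sigma = 0.35
        mean, _ = quad(
            lambda s: s * ncchi_pdf(s, 0.0, sigma**2, 8.0), 0.0, 10.0 * sigma
        )
        assert mean == pytest.approx(
            sigma * np.sqrt(2.0) * gamma(8.5) / gamma(8.0), rel=1e-8
        )

    def test_finite_at_central_limit(self):
        val = ncchi_pdf(1.0, 0.0, 0.5, 4.5)
        assert np.isfinite(val) and val > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ncchi_pdf(1.0, 1.0, -0.1, 2.0)
        with pytest.raises(ValueError):
            ncchi_pdf(1.0, 1.0, 0.1, 0.5)


class TestSensitivityMaps:
    def test_single_coil_uniform(self):
        assert np.array_equal(make_sensitivity_maps(1, (4, 5, 6)), np.ones((1, 4, 5, 6)))

    @pytest.mark.parametrize("n", [2, 8, 16])
    def test_sum_of_squares_normalized(self, n):
        maps = make_sensitivity_maps(n, (8, 8, 8))
        assert np.allclose(np.sum(maps**2, axis=0), 1.0, atol=1e-6)
        assert np.all(maps >= 0) and np.all(maps <= 1.0)


class TestCoilSimulation:
    def test_noise_free_is_exact(self):
        maps = make_sensitivity_maps(4, (3, 3, 3))
        cfg = CoilConfig(4, maps, sigma=0.0)
        true = np.arange(27.0).reshape(3, 3, 3)
        out = simulate_coil_signals(true, cfg, seed=0)
        assert np.array_equal(out.real, true[None] * maps)
        assert np.all(out.imag == 0)

    def test_deterministic_for_fixed_seed(self):
        maps = make_sensitivity_maps(4, (3, 3, 3))
        cfg = CoilConfig(4, maps, sigma=0.2, rho=0.1)
        true = np.ones((3, 3, 3))
        a = simulate_coil_signals(true, cfg, seed=7)
        b = simulate_coil_signals(true, cfg, seed=7)
        assert np.array_equal(a, b)

    def test_noise_covariance_recovered(self):
        sigma, rho, n = 0.5, 0.3, 4
        draws = 100_000
        maps = make_sensitivity_maps(n, (1, 1, 1))
        cfg = CoilConfig(n, maps, sigma=sigma, rho=rho)
        out = simulate_coil_signals(np.zeros((1, 1, 1, draws)), cfg, seed=5)
        e = out.real.reshape(n, draws)
        cov = np.cov(e)
        se_var = sigma**2 * np.sqrt(2.0 / draws)
        se_cov = sigma**2 * np.sqrt((1 + rho**2) / draws)
        assert np.all(np.abs(cov.diagonal() - sigma**2) < 3 * se_var)
        off = cov[~np.eye(n, dtype=bool)]
        assert np.all(np.abs(off - rho * sigma**2) < 3 * se_cov + 3 * se_cov)

    def test_bad_rho_rejected(self):
        maps = make_sensitivity_maps(2, (2, 2, 2))
        with pytest.raises(ValueError):
            CoilConfig(2, maps, sigma=0.1, rho=1.0)


class TestCombiners:
    def test_noiseless_sos_equals_smf(self, rng):
        maps = make_sensitivity_maps(8, (4, 4, 4))
        cfg = CoilConfig(8, maps, sigma=0.0)
        true = rng.random((4, 4, 4, 5))
        coils = simulate_coil_signals(true, cfg, seed=1)
        assert np.allclose(combine_sos(coils), combine_smf(coils, maps), atol=1e-12)
        assert np.allclose(combine_sos(coils), true, atol=1e-12)

    def test_single_coil_sos_equals_smf(self):
        maps = make_sensitivity_maps(1, (2, 2, 2))
        cfg = CoilConfig(1, maps, sigma=0.3)
        coils = simulate_coil_signals(np.ones((2, 2, 2, 100)), cfg, seed=2)
        assert np.allclose(combine_sos(coils), combine_smf(coils, maps), atol=1e-12)

    def test_sos_noise_floor_mean(self):
        # zero signal: nc-chi mean = sigma sqrt(2) Gamma(n+1/2)/Gamma(n)
        sigma, n, draws = 0.2, 8, 100_000
        maps = make_sensitivity_maps(n, (1, 1, 1))
        cfg = CoilConfig(n, maps, sigma=sigma, rho=0.0)
        coils = simulate_coil_signals(np.zeros((1, 1, 1, draws)), cfg, seed=3)
        samples = combine_sos(coils).ravel()
        expected = sigma * np.sqrt(2.0) * gamma(n + 0.5) / gamma(n)
        se = samples.std() / np.sqrt(draws)
        assert abs(samples.mean() - expected) < 3 * se

    def test_smf_noise_floor_mean(self):
        # zero signal: Rician (Rayleigh) mean = sigma sqrt(pi/2)
        sigma, draws = 0.2, 100_000
        maps = make_sensitivity_maps(8, (1, 1, 1))
        cfg = CoilConfig(8, maps, sigma=sigma, rho=0.0)
        coils = simulate_coil_signals(np.zeros((1, 1, 1, draws)), cfg, seed=4)
        samples = combine_smf(coils, maps).ravel()
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = samples.std() / np.sqrt(draws)
        assert abs(samples.mean() - expected) < 3 * se

    def test_sos_distribution_matches_noncentral_chi(self):
        # S^2/sigma^2 ~ noncentral chi^2 with 2n dof and nc = Sbar^2/sigma^2
        sigma, n, sbar, draws = 0.1, 8, 0.6, 100_000
        maps = make_sensitivity_maps(n, (1, 1, 1))
        cfg = CoilConfig(n, maps, sigma=sigma, rho=0.0)
        coils = simulate_coil_signals(np.full((1, 1, 1, draws), sbar), cfg, seed=6)
        samples = combine_sos(coils).ravel()
        stat = kstest(
            samples**2 / sigma**2, lambda q: ncx2.cdf(q, 2 * n, sbar**2 / sigma**2)
        )
        assert stat.pvalue > 0.01

    def test_correlated_sos_matches_fitted_effective_ncchi(self):
        # with rho > 0 the SoS magnitude stays nc-chi to good approximation
        # once effective (n_eff < n, sigma_eff^2 > sigma^2) parameters are used
        from scipy.optimize import minimize

        sigma, n, rho, sbar, draws = 0.1, 8, 0.2, 0.5, 20_000
        maps = make_sensitivity_maps(n, (1, 1, 1))
        cfg = CoilConfig(n, maps, sigma=sigma, rho=rho)
        coils = simulate_coil_signals(np.full((1, 1, 1, draws), sbar), cfg, seed=8)
        samples = np.sort(combine_sos(coils).ravel())

        def nll(p):
            n_eff, s2_eff = p
            if n_eff < 1 or s2_eff <= 0:
                return np.inf
            pdf = ncchi_pdf(samples, sbar, s2_eff, n_eff)
            return -np.sum(np.log(np.maximum(pdf, 1e-300)))

        fit = minimize(nll, x0=[n, sigma**2], method="Nelder-Mead")
        n_eff, s2_eff = fit.x
        assert 1.0 <= n_eff < n
        assert s2_eff > sigma**2
        grid = np.linspace(0, samples.max() * 1.2, 4000)
        pdf = ncchi_pdf(grid, sbar, s2_eff, n_eff)
        cdf = np.cumsum(pdf) * (grid[1] - grid[0])
        emp = np.searchsorted(samples, grid) / draws
        ks = np.max(np.abs(emp - cdf))
        critical_1pct = 1.63 / np.sqrt(draws)
        assert ks < critical_1pct


class TestContaminate:
    def test_vanishing_noise_limit(self, rng):
        true = rng.random((4, 4, 4, 3))
        noisy, prov = contaminate(true, snr=1e12, combiner="sos", seed=0)
        assert np.allclose(noisy, true, atol=1e-9)

    def test_sigma_recorded(self, rng):
        true = rng.random((4, 4, 4, 3))
        _, prov = contaminate(true, snr=15.0, combiner="smf", seed=0)
        assert prov["sigma"] == pytest.approx(1.0 / 15.0)
        assert prov["rho"] == 0.05 and prov["n_coils"] == 8

    def test_paired_realizations_across_combiners(self, rng):
        # single uniform coil: both combiners reduce to |S + e|, so matched
        # seeds must give bit-identical volumes
        true = rng.random((3, 3, 3, 4))
        a, _ = contaminate(true, snr=10.0, combiner="sos", n_coils=1, rho=0.0, seed=9)
        b, _ = contaminate(true, snr=10.0, combiner="smf", n_coils=1, rho=0.0, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_snr_rejected(self, rng):
        with pytest.raises(ValueError):
            contaminate(np.ones((2, 2, 2, 2)), snr=0.0, seed=0)


def test_noise_model_validation():
    NoiseModel("ncchi", n_coils=4.5, sigma2=0.1)
    with pytest.raises(ValueError):
        NoiseModel("rician", n_coils=2.0)
    with pytest.raises(ValueError):
        NoiseModel("ncchi", n_coils=0.5)
    with pytest.raises(ValueError):
        NoiseModel("gaussian", sigma2=-1.0)
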