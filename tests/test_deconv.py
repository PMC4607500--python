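"""Fixed points, conservation laws and equivalences of the RL solvers."""

import numpy as np
import pytest

from rumbasd.deconv import (
    DampingOptions,
    SolverOptions,
    drl_sd,
    estimate_sigma2,
    initialize_fodf,
    rumba_sd,
    rumba_update,
    tv_factor,
)
from rumbasd.noise import contaminate
from rumbasd.phantoms import crossing_angle_phantom


def gaussian_rl_step(f, s, h):
    """Reference undamped Gaussian Richardson-Lucy update."""
    return f * (h.T @ s) / np.maximum(h.T @ (h @ f), 1e-12)


class TestRumbaUpdate:
    def test_zero_entries_stay_zero(self, small_dictionary, rng):
        h = small_dictionary.H
        f = rng.random(h.shape[1])
        f[::3] = 0.0
        s = h @ np.full(h.shape[1], 1.0 / h.shape[1])
        out = rumba_update(f, s, h, sigma2=0.01)
        assert np.all(out[::3] == 0.0)
        assert np.all(out >= 0.0)

    def test_exact_data_fixed_point_at_small_variance(self, small_dictionary):
        h = small_dictionary.H
        f_star = np.zeros(h.shape[1])
        f_star[20] = 1.0
        s = h @ f_star
        out = rumba_update(f_star, s, h, sigma2=1e-8)
        rel = np.abs(out - f_star).max() / f_star.max()
        assert rel < 1e-6

    def test_matches_gaussian_rl_at_small_variance(self, small_dictionary):
        # dual route: 50 Rician RL steps at tiny sigma^2 against 50 steps of
        # the independent Gaussian RL recursion
        h = small_dictionary.H
        f_true = np.zeros(h.shape[1])
        f_true[[5, 40]] = [0.6, 0.4]
        s = h @ f_true
        f_a = initialize_fodf(small_dictionary.grid.m)
        f_b = f_a.copy()
        for _ in range(50):
            f_a = rumba_update(f_a, s, h, sigma2=1e-10)
            f_b = gaussian_rl_step(f_b, s, h)
        assert np.max(np.abs(f_a - f_b)) / np.max(f_b) < 1e-4


class TestSigmaEstimate:
    def test_zero_fodf_closed_form(self, small_dictionary, rng):
        h = small_dictionary.H
        s = rng.random(h.shape[0])
        out = estimate_sigma2(np.zeros(h.shape[1]), s, h, n=4.0, alpha_prev=0.1)
        assert out == pytest.approx(float(s @ s) / (2.0 * 4.0 * h.shape[0]), rel=1e-12)

    def test_pure_noise_recovers_variance(self, rng):
        # central nc-chi samples, n = 8: the fixed point with f = 0 is the
        # Monte-Carlo estimate of sigma^2
        sigma, n, draws = 0.25, 8, 10_000
        e = rng.normal(0, sigma, (2 * n, draws))
        s = np.sqrt(np.sum(e**2, axis=0))
        h = np.ones((draws, 4))
        out = estimate_sigma2(np.zeros(4), s, h, n=float(n), alpha_prev=1.0)
        assert abs(out - sigma**2) / sigma**2 < 0.05

    def test_noiseless_iterates_decrease_to_zero(self, small_dictionary):
        h = small_dictionary.H
        f = np.zeros(h.shape[1])
        f[10] = 1.0
        s = h @ f
        alpha = 1e-3
        values = []
        for _ in range(30):
            alpha = estimate_sigma2(f, s, h, n=1.0, alpha_prev=alpha)
            values.append(alpha)
        assert values[-1] < 1e-8
        assert all(b <= a * (1 + 1e-12) for a, b in zip(values, values[1:]))


class TestTvFactor:
    def test_zero_weight_gives_ones(self, rng):
        field = rng.random((4, 4, 4, 3))
        assert np.array_equal(tv_factor(field, 0.0), np.ones_like(field))

    def test_constant_field_gives_ones(self):
        field = np.full((5, 5, 5, 2), 0.7)
        assert np.allclose(tv_factor(field, 0.05), 1.0, atol=1e-12)

    def test_strictly_positive(self, rng):
        field = rng.random((6, 6, 6, 4))
        r = tv_factor(field, 5.0)          # huge weight to force sign flips
        assert np.all(r > 0)


class TestInitialFodf:
    def test_uniform_positive_unit_sum(self):
        f = initialize_fodf(100)
        assert f.shape == (102,)
        assert np.all(f > 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.ptp(f) == 0.0


class TestRumbaSolver:
    def test_on_grid_single_fiber_recovery(self, small_dictionary):
        j = 33
        s = small_dictionary.H[:, j]
        res = rumba_sd(
            s, small_dictionary, SolverOptions(iterations=200, log_every=50)
        )
        f = res.fodf.coefficients[0, 0, 0]
        m = small_dictionary.grid.m
        top = np.argmax(f[:m])
        anti = small_dictionary.grid.antipode_index[j]
        assert top in (j, anti)
        assert f[:m].sum() > 0.9          # WM dominates GM/CSF columns

    def test_deterministic(self, small_dictionary, rng):
        data = rng.random((3, 3, 3, small_dictionary.H.shape[0])) * 0.5 + 0.1
        opts = SolverOptions(iterations=20, log_every=5)
        a = rumba_sd(data, small_dictionary, opts)
        b = rumba_sd(data, small_dictionary, opts)
        assert np.array_equal(a.fodf.coefficients, b.fodf.coefficients)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_rician_equals_ncchi_order_one(self, small_dictionary, rng):
        data = rng.random((2, 2, 2, small_dictionary.H.shape[0])) * 0.5 + 0.1
        a = rumba_sd(
            data, small_dictionary,
            SolverOptions(noise_family="rician", iterations=15),
        )
        b = rumba_sd(
            data, small_dictionary,
            SolverOptions(noise_family="ncchi", n_coils=1.0, iterations=15),
        )
        assert np.array_equal(a.fodf.coefficients, b.fodf.coefficients)

    def test_tv_none_equals_zero_weight_global(self, small_dictionary, rng):
        data = rng.random((3, 3, 3, small_dictionary.H.shape[0])) * 0.5 + 0.1
        a = rumba_sd(data, small_dictionary, SolverOptions(iterations=15))
        b = rumba_sd(
            data, small_dictionary,
            SolverOptions(iterations=15, tv_mode="global", tv_weight=0.0),
        )
        assert np.array_equal(a.fodf.coefficients, b.fodf.coefficients)

    def test_negative_log_likelihood_non_increasing(self, small_dictionary):
        phantom = crossing_angle_phantom(70.0, shape=(6, 6, 6))
        noisy, _ = contaminate(phantom.signal, snr=15.0, combiner="smf",
                               n_coils=1, rho=0.0, seed=3)
        res = rumba_sd(
            noisy, small_dictionary,
            SolverOptions(noise_family="rician", iterations=60, log_every=1),
        )
        nll = np.array([entry["nll"] for entry in res.log])
        tol = 1e-8 * max(1.0, abs(nll[0]))
        assert np.all(np.diff(nll) <= tol)

    def test_nonnegative_and_gaussian_rejected(self, small_dictionary, rng):
        data = rng.random((2, 2, 2, small_dictionary.H.shape[0])) * 0.5 + 0.1
        res = rumba_sd(data, small_dictionary, SolverOptions(iterations=10))
        assert np.all(res.fodf.coefficients >= 0)
        assert np.all(res.sigma2[res.mask] > 0)
        with pytest.raises(ValueError):
            rumba_sd(data, small_dictionary, SolverOptions(noise_family="gaussian"))

    def test_nonfinite_data_rejected(self, small_dictionary):
        data = np.full((1, 1, 1, small_dictionary.H.shape[0]), np.nan)
        with pytest.raises(ValueError):
            rumba_sd(data, small_dictionary)


class TestDrlSolver:
    def test_undamped_limit_matches_reference_rl(self, small_dictionary):
        h = small_dictionary.H
        f_true = np.zeros(h.shape[1])
        f_true[[7, 80]] = [0.5, 0.5]
        s = h @ f_true
        res = drl_sd(
            s, small_dictionary, damping=None,
            options=SolverOptions(noise_family="gaussian", iterations=25,
                                  log_every=25),
        )
        f_ref = initialize_fodf(small_dictionary.grid.m)
        for _ in range(25):
            f_ref = gaussian_rl_step(f_ref, s, h)
        assert np.allclose(res.fodf.coefficients[0, 0, 0], f_ref, atol=1e-10)

    def test_uniform_fixed_point(self, small_dictionary):
        # data generated by the uniform start is stationary: H^T S / H^T H f = 1
        f0 = initialize_fodf(small_dictionary.grid.m)
        s = small_dictionary.H @ f0
        res = drl_sd(
            s, small_dictionary,
            options=SolverOptions(noise_family="gaussian", iterations=30,
                                  log_every=30),
        )
        assert np.allclose(res.fodf.coefficients[0, 0, 0], f0, atol=1e-9)

    def test_noiseless_single_fiber_top_peak(self, small_dictionary, profile, scheme):
        from rumbasd.kernel import multi_tensor_signal

        d = np.array([np.cos(0.4), np.sin(0.4), 0.3])
        d /= np.linalg.norm(d)
        s = multi_tensor_signal([d], [1.0], scheme, profile)
        res = drl_sd(
            s, small_dictionary,
            options=SolverOptions(noise_family="gaussian", iterations=150,
                                  log_every=150),
        )
        f = res.fodf.coefficients[0, 0, 0]
        m = small_dictionary.grid.m
        top = small_dictionary.grid.vertices[np.argmax(f[:m])]
        angle = np.degrees(np.arccos(min(1.0, abs(top @ d))))
        assert angle < 20.0               # within ~one spacing of the coarse grid

    def test_nonnegativity_preserved(self, small_dictionary, rng):
        data = rng.random((3, 3, 3, small_dictionary.H.shape[0])) * 0.5 + 0.1
        res = drl_sd(
            data, small_dictionary,
            options=SolverOptions(noise_family="gaussian", iterations=40,
                                  log_every=10),
        )
        assert np.all(res.fodf.coefficients >= 0)


def test_damping_options_validation():
    DampingOptions(nu=8.0, eta=0.06)
    with pytest.raises(ValueError):
        DampingOptions(nu=0.0, eta=0.06)
    with pytest.raises(ValueError):
        DampingOptions(nu=8.0, eta=1.5)


def test_solver_options_validation():
    with pytest.raises(ValueError):
        SolverOptions(noise_family="poisson")
    with pytest.raises(ValueError):
        SolverOptions(iterations=0)
    with pytest.raises(ValueError):
        SolverOptions(tv_mode="local")
    assert SolverOptions(noise_family="ncchi", n_coils=4.5).order() == 4.5
    assert SolverOptions(noise_family="rician", n_coils=8).order() == 1.0
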