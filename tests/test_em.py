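"""EM-REML variance components and the fixed-residual per-marker (RMLV) stage."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

import gwpredict as gw
from gwpredict import FitConfig
from gwpredict.em import ConvergenceWarning, em_homoscedastic_reml, fit_rmlv, restricted_log_likelihood


def simulate_linear(rng, N, m, sigma_u2, sigma_e2, beta0=2.0):
    Z = rng.integers(0, 3, size=(N, m)).astype(float)
    u = rng.normal(0, np.sqrt(sigma_u2), m) if sigma_u2 > 0 else np.zeros(m)
    y = beta0 + Z @ u + rng.normal(0, np.sqrt(sigma_e2), N)
    return y, Z


class TestRestrictedLogLikelihood:
    def test_translation_invariance(self, toy_data):
        y, Z = toy_data
        a = restricted_log_likelihood(y, Z, 0.2, 1.0)
        b = restricted_log_likelihood(y + 123.4, Z, 0.2, 1.0)
        assert a == pytest.approx(b, abs=1e-8)

    def test_em_limit_is_a_local_maximum(self, rng):
        y, Z = simulate_linear(rng, 80, 12, 0.3, 1.0)
        vc, _ = em_homoscedastic_reml(y, Z, FitConfig(em_tol=1e-12, em_max_iter=5000))
        ll0 = restricted_log_likelihood(y, Z, vc.sigma_u2, vc.sigma_e2)
        for fu in (0.9, 1.1):
            for fe in (0.9, 1.1):
                ll = restricted_log_likelihood(y, Z, fu * vc.sigma_u2, fe * vc.sigma_e2)
                assert ll <= ll0 + 1e-10


class TestHomoscedasticEM:
    def test_likelihood_is_nondecreasing_along_iterations(self, rng):
        y, Z = simulate_linear(rng, 60, 15, 0.3, 1.0)
        _, _, trace = em_homoscedastic_reml(y, Z, FitConfig(), keep_trace=True)
        lls = [
            restricted_log_likelihood(y, Z, float(s.sigma_l2[0]), s.sigma_e2)
            for s in trace[:60]
        ]
        assert np.all(np.diff(lls) >= -1e-10)

    def test_matches_direct_reml_maximizer(self, rng):
        """Converged EM equals a Nelder-Mead REML maximizer to 3 significant figures."""
        y, Z = simulate_linear(rng, 50, 10, 0.3, 1.0)
        vc, _ = em_homoscedastic_reml(y, Z, FitConfig(em_tol=1e-12, em_max_iter=10000))
        nll = lambda p: -restricted_log_likelihood(y, Z, np.exp(p[0]), np.exp(p[1]))
        res = minimize(
            nll,
            [np.log(np.var(y) / (2 * Z.shape[1])), np.log(np.var(y) / 2)],
            method="Nelder-Mead",
            options=dict(xatol=1e-12, fatol=1e-14, maxiter=10000, maxfev=10000),
        )
        su, se = np.exp(res.x)
        assert vc.sigma_u2 == pytest.approx(su, rel=1e-3)
        assert vc.sigma_e2 == pytest.approx(se, rel=1e-3)

    def test_null_simulation_estimates_near_zero_marker_variance(self):
        rng = np.random.default_rng(77)
        ratios = []
        for _ in range(20):
            y, Z = simulate_linear(rng, 500, 50, 0.0, 2.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                vc, _ = em_homoscedastic_reml(y, Z)
            ratios.append(vc.sigma_u2 / vc.sigma_e2)
        assert np.mean(ratios) < 0.05

    def test_parameter_recovery_within_20_percent(self):
        rng = np.random.default_rng(101)
        su_true, se_true = 0.1, 5.0
        su, se = [], []
        for _ in range(20):
            y, Z = simulate_linear(rng, 500, 50, su_true, se_true)
            vc, _ = em_homoscedastic_reml(y, Z)
            su.append(vc.sigma_u2)
            se.append(vc.sigma_e2)
        assert abs(np.mean(su) - su_true) / su_true < 0.20
        assert abs(np.mean(se) - se_true) / se_true < 0.20

    def test_determinism(self, rng):
        y, Z = simulate_linear(rng, 50, 10, 0.3, 1.0)
        _, _, t1 = em_homoscedastic_reml(y, Z, keep_trace=True)
        _, _, t2 = em_homoscedastic_reml(y, Z, keep_trace=True)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            assert a.sigma_e2 == b.sigma_e2 and a.sigma_l2[0] == b.sigma_l2[0]

    def test_blup_fit_at_converged_penalty(self, rng):
        y, Z = simulate_linear(rng, 60, 10, 0.3, 1.0)
        vc, fit = em_homoscedastic_reml(y, Z)
        lam = vc.sigma_e2 / vc.sigma_u2
        ref = gw.solve_mme(y, Z, np.full(10, lam))
        np.testing.assert_allclose(fit.u_hat, ref.u_hat, atol=1e-8)
        assert vc.sigma_g2 == pytest.approx(10 * vc.sigma_u2)


def rmlv_scalar_oracle(y, z, sigma_e2, sigma_init, n_iter, tol):
    """Fixed-point iteration of the single-marker fixed-residual update."""
    zc = z - z.mean()
    yc = y - y.mean()
    G = zc @ zc
    zy = zc @ yc
    s = sigma_init
    for _ in range(n_iter):
        lam = sigma_e2 / s
        u = zy / (G + lam)
        c = 1.0 / (G + lam)
        new = u * u + sigma_e2 * c
        if abs(new - s) / (s + 1e-12) < tol:
            return new
        s = new
    return s


class TestRMLV:
    def test_single_marker_matches_scalar_fixed_point(self, rng):
        N = 80
        z = rng.integers(0, 3, N).astype(float)
        y = 1.0 + 0.8 * z + rng.normal(0, 1.0, N)
        cfg = FitConfig(rmlv_tol=1e-10, rmlv_max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc, fit = fit_rmlv(y, z[:, None], cfg)
        oracle = rmlv_scalar_oracle(
            y, z, vc.sigma_e2, vc.sigma_u2, cfg.rmlv_max_iter, cfg.rmlv_tol
        )
        assert vc.sigma_l2[0] == pytest.approx(oracle, rel=1e-8)

    def test_qtl_marker_gets_much_larger_variance_than_null(self):
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(10):
            N, m = 300, 51
            Z = rng.integers(0, 3, size=(N, m)).astype(float)
            y = Z[:, 0] * 1.5 + rng.normal(0, 1.0, N)  # QTL at marker 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                vc, _ = fit_rmlv(y, Z)
            if vc.sigma_l2[0] >= 10 * np.median(vc.sigma_l2[1:]):
                hits += 1
        assert hits >= 9

    def test_null_data_variances_concentrate_near_floor(self):
        """With no signal, most per-marker variances shrink towards zero."""
        rng = np.random.default_rng(9)
        N, m = 300, 50
        Z = rng.integers(0, 3, size=(N, m)).astype(float)
        y = rng.normal(0, 1.0, N)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc, _ = fit_rmlv(y, Z)
        assert np.median(vc.sigma_l2) < 0.01 * vc.sigma_e2

    def test_plus_update_keeps_variances_positive(self, rng):
        y, Z = simulate_linear(rng, 60, 20, 0.2, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, _, trace = fit_rmlv(y, Z, keep_trace=True)
        floor = 1e-12 * trace[0].sigma_e2
        for state in trace:
            assert np.all(state.sigma_l2 >= floor * (1 - 1e-15))

    def test_constrained_updates_reproduce_homoscedastic_fixed_point(self, rng):
        """Forcing equal per-marker updates recovers the sigma_u2 fixed point."""
        y, Z = simulate_linear(rng, 100, 20, 0.3, 1.0)
        cfg = FitConfig(em_tol=1e-12, em_max_iter=5000, rmlv_tol=1e-10, rmlv_max_iter=5000)
        vc_h, _ = em_homoscedastic_reml(y, Z, cfg)
        vc_c, _ = fit_rmlv(y, Z, cfg, constrain_equal=True)
        assert np.allclose(vc_c.sigma_l2, vc_c.sigma_l2[0])
        assert vc_c.sigma_l2[0] == pytest.approx(vc_h.sigma_u2, rel=1e-6)

    def test_dual_path_matches_primal(self, rng):
        """m > N triggers the Woodbury path; results agree with the primal path."""
        y, Z = simulate_linear(rng, 30, 80, 0.2, 1.0)
        cfg = FitConfig(rmlv_max_iter=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc_dual, fit_dual = fit_rmlv(y, Z, cfg)  # m > N exercises the dual path
        assert vc_dual.sigma_l2.size == 80 and np.all(vc_dual.sigma_l2 > 0)
        # direct cross-check: one dual iteration equals one primal iteration
        from gwpredict.em import _chol_solve_and_inverse_diag

        zbar = Z.mean(axis=0)
        Zc = Z - zbar
        yc = y - y.mean()
        lam = vc_dual.sigma_e2 / np.full(80, vc_dual.sigma_u2)
        A = Zc.T @ Zc + np.diag(lam)
        u_p, d_p = _chol_solve_and_inverse_diag(A, Zc.T @ yc)
        dinv = 1.0 / lam
        K = (Zc * dinv) @ Zc.T + np.eye(30)
        u_d = dinv * (Zc.T @ np.linalg.solve(K, yc))
        S = np.linalg.solve(K, Zc)
        d_d = dinv - dinv**2 * np.einsum("ij,ij->j", Zc, S)
        np.testing.assert_allclose(u_d, u_p, atol=1e-10)
        np.testing.assert_allclose(d_d, d_p, atol=1e-10)

    def test_first_iteration_residual_option(self, rng):
        y, Z = simulate_linear(rng, 60, 10, 0.3, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc_a, _ = fit_rmlv(y, Z, FitConfig(rmlv_residual="converged"))
            vc_b, _ = fit_rmlv(y, Z, FitConfig(rmlv_residual="first_iteration"))
        assert vc_a.sigma_e2 != vc_b.sigma_e2

    def test_minus_update_is_floored(self, rng):
        y, Z = simulate_linear(rng, 60, 10, 0.0, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            vc, _ = fit_rmlv(y, Z, FitConfig(em_update="minus", rmlv_max_iter=50))
        assert np.all(vc.sigma_l2 > 0)
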