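"""Variational inference: closed-form factor updates, the sparse-GP update
against a dense brute-force oracle, ELBO behaviour, and posterior evaluation."""

import numpy as np
import pytest
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma

from nhgps.kernels import AggregatedKernel, KernelParams, safe_cholesky
from nhgps.pg import sigmoid, tilted_pg_mean
from nhgps.simulate import EventSequence
from nhgps.vi import (
    VIConfig,
    compute_elbo,
    fit_vi,
    gauss_legendre,
    lambda_expectations,
    posterior_phi,
    update_q2,
    update_q_lambda,
    update_q_phi,
    hyperparameter_step,
    elbo_gradient,
)


class TestLambdaUpdate:
    def test_plug_in(self):
        shape, rate = update_q_lambda(10, 0.0, 1.0, 1.0, 1.0)
        assert (shape, rate) == (11.0, 2.0)
        assert shape / rate == pytest.approx(5.5)

    def test_no_data_shifts_only_rate(self):
        shape, rate = update_q_lambda(0, 0.0, 3.0, 0.5, 2.0)
        assert shape == 3.0 and rate == 2.5

    def test_log_expectation_against_monte_carlo(self, rng):
        _, lnlam = lambda_expectations(11.0, 2.0)
        assert lnlam == pytest.approx(digamma(11.0) - np.log(2.0), rel=1e-12)
        draws = np.log(rng.gamma(11.0, size=1_000_000) / 2.0)
        assert lnlam == pytest.approx(draws.mean(), abs=3 * draws.std() / 1000.0)

    def test_negative_latent_mass_rejected(self):
        with pytest.raises(ValueError):
            update_q_lambda(5, -0.1, 1.0, 1.0, 1.0)


class TestQ2Update:
    def test_flat_posterior_gives_half_bound_rate(self):
        lam0 = 12.0
        tilt, rate = update_q2(np.zeros(4), np.zeros(4), np.log(lam0))
        assert np.allclose(tilt, 0.0)
        assert np.allclose(rate, lam0 / 2.0)

    def test_saturated_intensity_kills_latent_rate(self):
        _, rate = update_q2(np.array([40.0]), np.array([0.0]), np.log(10.0))
        assert rate[0] < 1e-15

    def test_tilted_rate_identity(self):
        """With var = 0 the rate is lambda0 * sigma(-mean)."""
        _, rate = update_q2(np.array([1.0]), np.array([0.0]), np.log(10.0))
        assert rate[0] == pytest.approx(10.0 * sigmoid(-1.0), rel=1e-12)

    def test_cosh_sigmoid_identity_machine_precision(self):
        x = np.linspace(-20, 20, 101)
        lhs = np.exp(-x / 2.0) / (2.0 * np.cosh(x / 2.0))
        assert np.allclose(lhs, sigmoid(-x), rtol=1e-14, atol=1e-300)


def _toy_problem(n_events=5, n_quad=24, n_inducing=3, seed=0):
    rng = np.random.default_rng(seed)
    events = np.sort(rng.uniform(0.05, 0.95, n_events))
    params = KernelParams(1.0, 0.3, 1.0, 0.2, 8.0)
    op = AggregatedKernel.univariate(events, params)
    inducing = np.linspace(0.0, 1.0, n_inducing)
    quad_nodes, quad_weights = gauss_legendre(n_quad, 0.0, 1.0)
    return events, params, op, inducing, quad_nodes, quad_weights, rng


class TestPhiUpdate:
    def test_prior_recovered_without_data(self):
        _, params, op, inducing, qn, qw, _ = _toy_problem()
        kc = op.gram(inducing, jitter=1e-6)
        kc_chol = (safe_cholesky(kc, params.amplitude_s, jitter=0.0), True)
        kappa_q = cho_solve(kc_chol, op.gram(qn, inducing).T).T
        mu, sigma = update_q_phi(
            np.empty((0, 3)), kappa_q, np.empty(0), np.zeros(qn.size),
            np.zeros(qn.size), qw, kc_chol,
        )
        assert np.allclose(mu, 0.0, atol=1e-12)
        assert np.allclose(sigma, kc, rtol=1e-8)

    def test_dense_oracle(self):
        """The kappa-factorised update reproduces a dense implementation that
        assembles the full Gram over events + quadrature nodes directly."""
        events, params, op, inducing, qn, qw, rng = _toy_problem()
        kc = op.gram(inducing, jitter=1e-6)
        kc_chol = (safe_cholesky(kc, params.amplitude_s, jitter=0.0), True)
        k_ev = op.gram(events, inducing)
        k_qd = op.gram(qn, inducing)
        kappa_ev = cho_solve(kc_chol, k_ev.T).T
        kappa_qd = cho_solve(kc_chol, k_qd.T).T
        c_ev = rng.uniform(0.5, 2.0, events.size)
        c_qd = rng.uniform(0.5, 2.0, qn.size)
        rate = rng.uniform(0.0, 5.0, qn.size)
        mu, sigma = update_q_phi(kappa_ev, kappa_qd, c_ev, c_qd, rate, qw, kc_chol)

        # dense route: no kappa shortcut, explicit matrices
        kc_inv = np.linalg.inv(kc)
        all_kappa = np.vstack([k_ev, k_qd]) @ kc_inv
        a_diag = np.concatenate(
            [tilted_pg_mean(c_ev), tilted_pg_mean(c_qd) * rate * qw]
        )
        prec_dense = kc_inv + all_kappa.T @ np.diag(a_diag) @ all_kappa
        sigma_dense = np.linalg.inv(prec_dense)
        b_vec = np.concatenate([np.full(events.size, 0.5), -0.5 * rate * qw])
        mu_dense = sigma_dense @ (all_kappa.T @ b_vec)
        assert np.allclose(mu, mu_dense, atol=1e-6)
        assert np.allclose(sigma, sigma_dense, atol=1e-6)

    def test_covariance_positive_definite(self):
        events, params, op, inducing, qn, qw, rng = _toy_problem(seed=3)
        kc_chol = (safe_cholesky(op.gram(inducing, jitter=1e-6), params.amplitude_s, jitter=0.0), True)
        kappa_ev = cho_solve(kc_chol, op.gram(events, inducing).T).T
        kappa_qd = cho_solve(kc_chol, op.gram(qn, inducing).T).T
        for _ in range(5):
            _, sigma = update_q_phi(
                kappa_ev, kappa_qd,
                rng.uniform(0, 3, events.size), rng.uniform(0, 3, qn.size),
                rng.uniform(0, 50, qn.size), qw, kc_chol,
            )
            assert np.all(np.linalg.eigvalsh(sigma) > 0)


class TestPosteriorPhi:
    def test_prior_state_returns_prior_moments(self, fixture_data):
        truth, seq = fixture_data
        state = fit_vi(seq, VIConfig(params=truth.params, max_iter=1, tol=0.0))
        import copy

        prior = copy.copy(state)
        prior.mu_c = np.zeros_like(state.mu_c)
        prior.sigma_c = state.cache.kc.copy()
        ts = np.linspace(0.1, 0.9, 7)
        mean, var = posterior_phi(prior, ts)
        assert np.allclose(mean, 0.0, atol=1e-10)
        assert np.allclose(var, prior.cache.op.gram_diag(ts), rtol=1e-4)

    def test_single_inducing_point_closed_form(self):
        events = np.array([0.4])
        params = KernelParams(1.0, 0.3, 1.0, 0.2, 8.0)
        state = fit_vi(
            EventSequence(events, 1.0),
            VIConfig(params=params, n_inducing=1, n_quad=20, max_iter=3, tol=0.0),
        )
        u = state.inducing[0]
        kc = state.cache.kc[0, 0]
        op = state.cache.op
        mean, _ = posterior_phi(state, np.array([u]))
        assert mean[0] == pytest.approx(op(u, u) / kc * state.mu_c[0], rel=1e-8)

    def test_variance_nonnegative_everywhere(self, vi_state, rng):
        ts = rng.uniform(0.0, 1.0, 1000)
        _, var = posterior_phi(vi_state, ts)
        assert np.all(var >= 0)

    def test_domain_error(self, vi_state):
        with pytest.raises(ValueError):
            posterior_phi(vi_state, np.array([1.5]))


class TestElbo:
    def test_trace_finite_and_monotone(self, vi_state):
        trace = vi_state.elbo_trace
        assert np.all(np.isfinite(trace))
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_lambda_kl_zero_when_posterior_equals_prior(self, vi_state):
        import copy

        from nhgps.vi import _gamma_kl

        assert _gamma_kl(2.0, 0.02, 2.0, 0.02) == pytest.approx(0.0, abs=1e-12)
        assert _gamma_kl(5.0, 1.0, 2.0, 0.02) > 0

    def test_gauss_kl_nonnegative(self, vi_state):
        from nhgps.vi import _gauss_kl

        assert _gauss_kl(vi_state.mu_c, vi_state.sigma_c, vi_state.cache.kc_chol) >= 0

    def test_empty_events_posterior_intensity_near_zero(self):
        state = fit_vi(
            EventSequence(np.empty(0), 1.0),
            VIConfig(max_iter=30),
        )
        ts = np.linspace(0, 1, 11)
        intens = state.expected_intensity(ts)
        # prior mean bound is 100; with zero observed counts the posterior
        # intensity collapses to the order of alpha0 / (beta0 + T)
        assert np.all(intens < 3.0)


class TestSparseToDenseConsistency:
    def test_inducing_at_all_nodes_matches_dense_gp(self):
        """With inducing points at every event and quadrature node, the sparse
        posterior equals the dense full-rank construction on those points."""
        events, params, op, _, qn, qw, rng = _toy_problem(n_events=5, n_quad=16)
        pts = np.unique(np.concatenate([events, qn]))
        kc = op.gram(pts, jitter=1e-8)
        kc_chol = (safe_cholesky(kc, params.amplitude_s, jitter=0.0), True)
        k_ev = op.gram(events, pts)
        k_qd = op.gram(qn, pts)
        kappa_ev = cho_solve(kc_chol, k_ev.T).T
        kappa_qd = cho_solve(kc_chol, k_qd.T).T
        c_ev = rng.uniform(0.2, 1.5, events.size)
        c_qd = rng.uniform(0.2, 1.5, qn.size)
        rate = rng.uniform(0, 4, qn.size)
        mu, sigma = update_q_phi(kappa_ev, kappa_qd, c_ev, c_qd, rate, qw, kc_chol)

        # dense full-rank: treat phi at pts directly, precision = K^-1 + A at points
        a_pt = np.zeros(pts.size)
        b_pt = np.zeros(pts.size)
        idx_ev = np.searchsorted(pts, events)
        idx_qd = np.searchsorted(pts, qn)
        np.add.at(a_pt, idx_ev, tilted_pg_mean(c_ev))
        np.add.at(a_pt, idx_qd, tilted_pg_mean(c_qd) * rate * qw)
        np.add.at(b_pt, idx_ev, 0.5)
        np.add.at(b_pt, idx_qd, -0.5 * rate * qw)
        prec = np.linalg.inv(kc) + np.diag(a_pt)
        sigma_dense = np.linalg.inv(prec)
        mu_dense = sigma_dense @ b_pt
        assert np.allclose(mu, mu_dense, atol=1e-4)
        assert np.allclose(sigma, sigma_dense, atol=1e-4)


class TestHyperparameterStep:
    def test_zero_learning_rate_is_identity(self, fixture_data):
        truth, seq = fixture_data
        state = fit_vi(seq, VIConfig(params=truth.params, max_iter=2, tol=0.0))
        assert hyperparameter_step(state, 0.0) == state.params

    def test_gradient_step_halving_consistency(self):
        """Richardson-style check: halving the FD step changes the gradient
        only at higher order."""
        events, params, op, _, _, _, _ = _toy_problem()
        state = fit_vi(
            EventSequence(events, 1.0),
            VIConfig(params=params, n_inducing=5, n_quad=16, max_iter=3, tol=0.0),
        )
        g1 = elbo_gradient(state, step=2e-4)
        g2 = elbo_gradient(state, step=1e-4)
        assert np.allclose(g1, g2, rtol=1e-3, atol=1e-6)

    def test_step_preserves_positivity(self):
        events, params, *_ = _toy_problem()
        state = fit_vi(
            EventSequence(events, 1.0),
            VIConfig(params=params, n_inducing=5, n_quad=16, max_iter=3, tol=0.0),
        )
        new = hyperparameter_step(state, 0.5)
        assert np.all(new.as_array() > 0)
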