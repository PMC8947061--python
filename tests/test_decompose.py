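"""Posterior decomposition: exact mean reconstruction, covariance structure,
no-data limits, and the sampling-oracle check of the marginal covariances."""

import copy

import numpy as np
import pytest

from nhgps.decompose import (
    decompose,
    decompose_chain,
    influence_matrix,
    mu_tilde_and_b,
    phi_from_components,
    posterior_cov_gtilde,
    posterior_cov_s,
    posterior_mean_g,
    posterior_mean_g_undecayed,
    posterior_mean_s,
    sample_component_functions,
)
from nhgps.kernels import rbf_kernel
from nhgps.simulate import EventSequence
from nhgps.vi import VIConfig, fit_vi, posterior_phi


class TestMeans:
    def test_zero_mu_gives_zero_components(self, vi_state):
        state = copy.copy(vi_state)
        state.mu_c = np.zeros_like(vi_state.mu_c)
        ts = np.linspace(0, 1, 9)
        assert np.allclose(posterior_mean_s(ts, state), 0.0, atol=1e-12)
        assert np.allclose(posterior_mean_g(ts, state), 0.0, atol=1e-12)

    def test_no_events_background_equals_phi(self):
        """With an empty training history the whole posterior mean is background."""
        state = fit_vi(EventSequence(np.empty(0), 1.0), VIConfig(max_iter=20))
        ts = np.linspace(0.05, 0.95, 11)
        mean, _ = posterior_phi(state, ts)
        assert np.allclose(posterior_mean_s(ts, state), mean, atol=1e-10)

    def test_mean_reconstruction_identity(self, vi_state, rng):
        """<phi(t)> = <s(t)> + sum_{ti<t} <gtilde(t - ti)> at machine precision."""
        ts = rng.uniform(0, 1, 50)
        mean, _ = posterior_phi(vi_state, ts)
        mu_tilde, _ = mu_tilde_and_b(vi_state)
        events = vi_state.events
        rec = posterior_mean_s(ts, vi_state, mu_tilde).copy()
        for k, t in enumerate(ts):
            past = events[events < t]
            if past.size:
                rec[k] += posterior_mean_g(t - past, vi_state, 0, mu_tilde).sum()
        assert np.abs(rec - mean).max() < 1e-10

    def test_long_lag_decay_to_zero(self, vi_state):
        assert abs(posterior_mean_g(50.0, vi_state)) < 1e-12

    def test_negative_lag_rejected(self, vi_state):
        with pytest.raises(ValueError):
            posterior_mean_g(-0.1, vi_state)

    def test_undecayed_reinflation(self, vi_state):
        lag = 0.15
        alpha = vi_state.streams[0][1].decay
        assert posterior_mean_g_undecayed(lag, vi_state) == pytest.approx(
            posterior_mean_g(lag, vi_state) * np.exp(alpha * lag), rel=1e-12
        )


class TestCovariances:
    def test_no_data_limit_recovers_priors(self):
        # a small, well-conditioned state: Sigma_c = K_c forces B = 0
        state = fit_vi(
            EventSequence(np.array([0.3, 0.7]), 1.0),
            VIConfig(n_inducing=8, n_quad=16, max_iter=2, tol=0.0),
        )
        state = copy.copy(state)
        state.mu_c = np.zeros_like(state.mu_c)
        state.sigma_c = state.cache.kc.copy()
        _, b = mu_tilde_and_b(state)
        assert np.abs(b).max() < 1e-6
        t1, t2 = 0.3, 0.5
        prior = float(rbf_kernel(t1 - t2, state.amplitude_s, state.lengthscale_s))
        assert posterior_cov_s(t1, t2, state, b) == pytest.approx(prior, abs=1e-6)
        lag1, lag2 = 0.05, 0.1
        eff = state.streams[0][1]
        prior_g = float(
            rbf_kernel(lag1 - lag2, eff.amplitude, eff.lengthscale)
            * np.exp(-eff.decay * (lag1 + lag2))
        )
        assert posterior_cov_gtilde(lag1, lag2, state) == pytest.approx(prior_g, abs=1e-6)

    def test_b_symmetric(self, vi_state):
        _, b = mu_tilde_and_b(vi_state)
        assert np.allclose(b, b.T)

    def test_diagonals_nonnegative(self, vi_state):
        grid = np.linspace(0, 1, 50)
        assert np.all(np.diag(posterior_cov_s(grid, grid, vi_state)) > -1e-10)
        lags = np.linspace(0, 0.5, 50)
        assert np.all(np.diag(posterior_cov_gtilde(lags, lags, vi_state)) > -1e-10)

    def test_sampling_oracle(self, vi_state, rng):
        """Empirical covariance of projected q(phi_c) draws equals the
        marginal covariance minus the phi_c-independent conditional-prior
        term, within Monte-Carlo error."""
        ts = np.array([0.25, 0.6, 0.85])
        lags = np.array([0.02, 0.08, 0.2])
        lam, s_draws, g_draws = sample_component_functions(
            vi_state, ts, lags, 10_000, rng
        )
        _, b = mu_tilde_and_b(vi_state)
        from nhgps.decompose import _g_features, _s_features
        from scipy.linalg import cho_solve

        cache = vi_state.cache
        kinv = cho_solve(cache.kc_chol, np.eye(vi_state.mu_c.size))
        proj_cov_expected_s = (
            _s_features(ts, vi_state.inducing, vi_state.amplitude_s,
                        vi_state.lengthscale_s, vi_state.half_exponent)
            @ kinv @ vi_state.sigma_c @ kinv
            @ _s_features(ts, vi_state.inducing, vi_state.amplitude_s,
                          vi_state.lengthscale_s, vi_state.half_exponent).T
        )
        emp = np.cov(s_draws.T)
        assert np.allclose(emp, proj_cov_expected_s, atol=4 * np.abs(proj_cov_expected_s).max() / np.sqrt(10_000) + 1e-4)
        # and the full marginal covariance exceeds the projected one by the
        # conditional prior (positive semidefinite difference)
        full = posterior_cov_s(ts, ts, vi_state, b)
        gap = full - proj_cov_expected_s
        assert np.all(np.linalg.eigvalsh(0.5 * (gap + gap.T)) > -1e-8)

    def test_covariance_reconstruction_four_terms(self, vi_state, rng):
        """cov(phi(t), phi(t')) assembles exactly from the s/g feature split
        (background, aggregate self-effect, and the two cross blocks)."""
        from nhgps.decompose import _g_features, _s_features

        _, b = mu_tilde_and_b(vi_state)
        events = vi_state.events
        eff = vi_state.streams[0][1]
        ts = rng.uniform(0.2, 1.0, 4)
        ks = _s_features(ts, vi_state.inducing, vi_state.amplitude_s,
                         vi_state.lengthscale_s, vi_state.half_exponent)
        # aggregate g features of evaluation points: sum over own history
        kg = np.zeros_like(ks)
        prior_g_agg = np.zeros((ts.size, ts.size))
        for i, t in enumerate(ts):
            hi = events[events < t]
            if hi.size == 0:
                continue
            kg[i] = _g_features(t - hi, vi_state.inducing, events, eff,
                                vi_state.half_exponent).sum(axis=0)
            for j, t2 in enumerate(ts):
                hj = events[events < t2]
                if hj.size == 0:
                    continue
                l1 = (t - hi)[:, None]
                l2 = (t2 - hj)[None, :]
                prior_g_agg[i, j] = float(np.sum(
                    rbf_kernel(l1 - l2, eff.amplitude, eff.lengthscale,
                               vi_state.half_exponent)
                    * np.exp(-eff.decay * (l1 + l2))
                ))
        prior_s = rbf_kernel(ts[:, None] - ts[None, :], vi_state.amplitude_s,
                             vi_state.lengthscale_s, vi_state.half_exponent)
        four_terms = (
            prior_s + prior_g_agg - ks @ b @ ks.T - ks @ b @ kg.T - kg @ b @ ks.T - kg @ b @ kg.T
        )
        # reference: full aggregated kernel route
        cache = vi_state.cache
        k_t = cache.op.gram(ts, vi_state.inducing)
        full = cache.op.gram(ts, ts) - k_t @ b @ k_t.T
        assert np.allclose(four_terms, full, atol=1e-8)


class TestInfluence:
    def test_univariate_reduces_to_posterior_mean_g(self, vi_state):
        infl = influence_matrix([vi_state], n_grid=20)
        lag, mean, sd = infl[0][0]
        assert np.allclose(mean, posterior_mean_g(lag, vi_state))
        assert np.all(sd >= 0)

    def test_dimension_mismatch_rejected(self, vi_state):
        with pytest.raises(ValueError):
            influence_matrix([vi_state, vi_state])


class TestChainDecomposition:
    def test_gibbs_and_vi_background_agree(self, gibbs_chain, vi_state):
        """Posterior-mean backgrounds from the two inference routes correlate
        strongly on the same data."""
        t_grid = np.linspace(0, 1, 100)
        lag_grid = np.linspace(0, 0.5, 100)
        _, s_draws, g_draws = decompose_chain(gibbs_chain, t_grid, lag_grid)
        dec = decompose(vi_state, n_grid=100, lag_max=0.5)
        assert np.corrcoef(s_draws.mean(axis=0), dec.s_mean)[0, 1] > 0.9


class TestPhiFromComponents:
    def test_matches_direct_reconstruction(self, vi_state, rng):
        dec = decompose(vi_state, n_grid=400)
        ts = rng.uniform(0.1, 1.0, 20)
        direct, _ = posterior_phi(vi_state, ts)
        rebuilt = phi_from_components(
            ts, vi_state.events, dec.t_grid, dec.s_mean, dec.lag_grid, dec.g_mean
        )
        # interpolation on 400-node grids is accurate to ~1e-3 here
        assert np.abs(rebuilt - direct).max() < 5e-2
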