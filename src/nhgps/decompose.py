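"""Recovering the background rate and self-effect function from a fitted phi.

Inference is carried out on the aggregated linear intensity phi, but its
components are identifiable afterwards: because the kernel of phi against
any representer point p_l splits into a background part Ks(t, p_l) and a
self-effect part sum_{t_j < p_l} Kgtilde(lag, p_l - t_j), the posterior mean

    <phi(t)> = k_c(t)^T mu_tilde,   mu_tilde = K_c^{-1} mu_c,

splits exactly as <phi(t)> = <s(t)> + sum_{t_i < t} <gtilde(t - t_i)> with

    <s(t)>        = k_c^s(t)^T mu_tilde,
    <gtilde(tau)> = sum_l [ sum_{t_j < p_l} Kgtilde(tau, p_l - t_j) ] mu_tilde_l,

where gtilde(tau) = g(tau) exp(-alpha tau) is the decayed self-effect (the
reported object; it vanishes at long lags).  Marginal covariances follow
from B = K_c^{-1} - K_c^{-1} Sigma_c K_c^{-1}:

    cov(s(t), s(t'))            = Ks(t,t') - k_c^s(t)^T B k_c^s(t'),
    cov(gtilde(l), gtilde(l'))  = Kgtilde(l,l') - G(l)^T B G(l').

The same representer formulas post-process Gibbs samples, with the active
points playing the role of inducing points and mu_tilde = K_act^{-1} phi_act.
In the multivariate model each source stream m yields its own influence
function gtilde_{r,m}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve

from .kernels import SelfEffectParams, rbf_kernel
from .vi import VariationalState

__all__ = [
    "DecomposedPosterior",
    "mu_tilde_and_b",
    "posterior_mean_s",
    "posterior_mean_g",
    "posterior_mean_g_undecayed",
    "posterior_cov_s",
    "posterior_cov_gtilde",
    "decompose",
    "influence_matrix",
    "sample_component_functions",
    "decompose_chain",
    "phi_from_components",
]


def _g_features(lags, locations, stream_events, effect: SelfEffectParams, half_exponent):
    """Matrix G[k, l] = sum_{t_j < p_l} Kgtilde(lag_k, p_l - t_j)."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags < 0):
        raise ValueError("self-effect lags must be non-negative")
    locations = np.asarray(locations, dtype=float)
    events = np.asarray(stream_events, dtype=float)
    out = np.zeros((lags.size, locations.size))
    if events.size == 0:
        return out
    wk = np.exp(-effect.decay * lags)
    for l, p in enumerate(locations):
        h = events[: np.searchsorted(events, p, side="left")]
        if h.size == 0:
            continue
        loc_lags = p - h
        base = rbf_kernel(
            lags[:, None] - loc_lags[None, :], effect.amplitude, effect.lengthscale, half_exponent
        )
        out[:, l] = wk * (base @ np.exp(-effect.decay * loc_lags))
    return out


def _s_features(t, locations, amplitude_s, lengthscale_s, half_exponent):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    locations = np.asarray(locations, dtype=float)
    return rbf_kernel(t[:, None] - locations[None, :], amplitude_s, lengthscale_s, half_exponent)


def mu_tilde_and_b(state: VariationalState):
    """Representer weights mu_tilde = K_c^{-1} mu_c and B = K_c^{-1} - K_c^{-1} Sigma_c K_c^{-1}."""
    chol = state.cache.kc_chol
    mu_tilde = cho_solve(chol, state.mu_c)
    kinv = cho_solve(chol, np.eye(state.mu_c.size))
    b = kinv - kinv @ state.sigma_c @ kinv
    return mu_tilde, 0.5 * (b + b.T)


def posterior_mean_s(t, state: VariationalState, mu_tilde=None):
    """Posterior mean of the background rate s at time(s) t."""
    if mu_tilde is None:
        mu_tilde, _ = mu_tilde_and_b(state)
    ks = _s_features(t, state.inducing, state.amplitude_s, state.lengthscale_s, state.half_exponent)
    out = ks @ mu_tilde
    return out if np.ndim(t) else float(out[0])


def posterior_mean_g(lag, state: VariationalState, stream: int = 0, mu_tilde=None):
    """Posterior mean of the decayed self-effect gtilde at non-negative lag(s)."""
    if mu_tilde is None:
        mu_tilde, _ = mu_tilde_and_b(state)
    events, effect = state.streams[stream]
    g = _g_features(np.atleast_1d(lag), state.inducing, events, effect, state.half_exponent)
    out = g @ mu_tilde
    return out if np.ndim(lag) else float(out[0])


def posterior_mean_g_undecayed(lag, state: VariationalState, stream: int = 0):
    """Posterior mean of the raw self-effect g(tau) = gtilde(tau) exp(+alpha tau).

    The exponential re-inflation also inflates the posterior uncertainty at
    large lags, where gtilde carries essentially no data constraint; treat
    values beyond a few memory timescales with caution.
    """
    effect = state.streams[stream][1]
    lag_arr = np.atleast_1d(np.asarray(lag, dtype=float))
    out = posterior_mean_g(lag_arr, state, stream) * np.exp(effect.decay * lag_arr)
    return out if np.ndim(lag) else float(out[0])


def posterior_cov_s(t1, t2, state: VariationalState, b=None):
    """Posterior covariance of s between two sets of times."""
    if b is None:
        _, b = mu_tilde_and_b(state)
    k1 = _s_features(t1, state.inducing, state.amplitude_s, state.lengthscale_s, state.half_exponent)
    k2 = _s_features(t2, state.inducing, state.amplitude_s, state.lengthscale_s, state.half_exponent)
    prior = rbf_kernel(
        np.atleast_1d(t1)[:, None] - np.atleast_1d(t2)[None, :],
        state.amplitude_s,
        state.lengthscale_s,
        state.half_exponent,
    )
    out = prior - k1 @ b @ k2.T
    return out if (np.ndim(t1) or np.ndim(t2)) else float(out[0, 0])


def posterior_cov_gtilde(lag1, lag2, state: VariationalState, stream: int = 0, b=None):
    """Posterior covariance of gtilde between two sets of non-negative lags."""
    if b is None:
        _, b = mu_tilde_and_b(state)
    events, effect = state.streams[stream]
    l1 = np.atleast_1d(np.asarray(lag1, dtype=float))
    l2 = np.atleast_1d(np.asarray(lag2, dtype=float))
    if np.any(l1 < 0) or np.any(l2 < 0):
        raise ValueError("self-effect lags must be non-negative")
    g1 = _g_features(l1, state.inducing, events, effect, state.half_exponent)
    g2 = _g_features(l2, state.inducing, events, effect, state.half_exponent)
    prior = rbf_kernel(
        l1[:, None] - l2[None, :], effect.amplitude, effect.lengthscale, state.half_exponent
    ) * np.exp(-effect.decay * (l1[:, None] + l2[None, :]))
    out = prior - g1 @ b @ g2.T
    return out if (np.ndim(lag1) or np.ndim(lag2)) else float(out[0, 0])


@dataclass
class DecomposedPosterior:
    """Tabulated posterior mean/sd of s and gtilde plus the representer pieces."""

    t_grid: np.ndarray
    s_mean: np.ndarray
    s_sd: np.ndarray
    lag_grid: np.ndarray
    g_mean: np.ndarray
    g_sd: np.ndarray
    mu_tilde: np.ndarray
    b_matrix: np.ndarray
    stream: int = 0


def _default_lag_max(state: VariationalState, stream: int) -> float:
    decay = state.streams[stream][1].decay
    return state.window_end if decay == 0 else min(state.window_end, 5.0 / decay)


def decompose(
    state: VariationalState, n_grid: int = 200, lag_max: float | None = None, stream: int = 0
) -> DecomposedPosterior:
    """Tabulate the posterior of s over the window and of gtilde over lags."""
    mu_tilde, b = mu_tilde_and_b(state)
    t_grid = np.linspace(0.0, state.window_end, n_grid)
    if lag_max is None:
        lag_max = _default_lag_max(state, stream)
    lag_grid = np.linspace(0.0, lag_max, n_grid)
    s_mean = posterior_mean_s(t_grid, state, mu_tilde)
    g_mean = posterior_mean_g(lag_grid, state, stream, mu_tilde)
    s_var = np.diag(posterior_cov_s(t_grid, t_grid, state, b))
    g_var = np.diag(posterior_cov_gtilde(lag_grid, lag_grid, state, stream, b))
    return DecomposedPosterior(
        t_grid,
        s_mean,
        np.sqrt(np.maximum(s_var, 0.0)),
        lag_grid,
        g_mean,
        np.sqrt(np.maximum(g_var, 0.0)),
        mu_tilde,
        b,
        stream,
    )


def influence_matrix(states, n_grid: int = 100, lag_max: float | None = None):
    """Per-pair influence functions <gtilde_{r,m}> of a multivariate fit.

    ``states`` is the list of per-dimension fitted states (one per target r).
    Returns an R x R nested list of (lag_grid, mean, sd) triples; entry
    [r][m] is the recovered influence of source m on target r.
    """
    R = len(states)
    out = []
    for r, state in enumerate(states):
        if len(state.streams) != R:
            raise ValueError(
                f"state {r} has {len(state.streams)} source streams, expected {R}"
            )
        mu_tilde, b = mu_tilde_and_b(state)
        row = []
        for m in range(R):
            lm = lag_max if lag_max is not None else _default_lag_max(state, m)
            lag_grid = np.linspace(0.0, lm, n_grid)
            mean = posterior_mean_g(lag_grid, state, m, mu_tilde)
            var = np.diag(posterior_cov_gtilde(lag_grid, lag_grid, state, m, b))
            row.append((lag_grid, mean, np.sqrt(np.maximum(var, 0.0))))
        out.append(row)
    return out


def sample_component_functions(state: VariationalState, t_grid, lag_grid, n_samples, rng, stream: int = 0):
    """Joint draws of (lambda, s on t_grid, gtilde on lag_grid) from the fitted posterior.

    phi_c is drawn from q(phi_c) and mapped through the representer formulas
    (the conditional means of s and gtilde given phi_c), lambda from its
    Gamma factor.  Used for Monte-Carlo test log-likelihoods.
    """
    from .kernels import safe_cholesky

    cache = state.cache
    chol_s = safe_cholesky(state.sigma_c, state.amplitude_s, jitter=1e-10)
    events, effect = state.streams[stream]
    ks = _s_features(t_grid, state.inducing, state.amplitude_s, state.lengthscale_s, state.half_exponent)
    gf = _g_features(lag_grid, state.inducing, events, effect, state.half_exponent)
    lam = rng.gamma(state.lambda_shape, size=n_samples) / state.lambda_rate
    s_draws = np.empty((n_samples, len(t_grid)))
    g_draws = np.empty((n_samples, len(lag_grid)))
    for i in range(n_samples):
        phi_c = state.mu_c + chol_s @ rng.standard_normal(state.mu_c.size)
        mt = cho_solve(cache.kc_chol, phi_c)
        s_draws[i] = ks @ mt
        g_draws[i] = gf @ mt
    return lam, s_draws, g_draws


def decompose_chain(chain, t_grid, lag_grid, jitter: float = 1e-6):
    """Representer decomposition of every stored Gibbs sample.

    Returns (lambda_samples, s_draws, g_draws) with s/g rows tabulated on the
    supplied grids; active points act as the representers of each sample.
    """
    from .kernels import AggregatedKernel, safe_cholesky

    params = chain.params
    op = AggregatedKernel.univariate(chain.events, params)
    effect = params.self_effect
    n = len(chain.phi_active)
    s_draws = np.empty((n, len(t_grid)))
    g_draws = np.empty((n, len(lag_grid)))
    for i in range(n):
        pts = chain.active_times[i]
        if chain.active_idx is not None:
            k_act = chain.k_full[np.ix_(chain.active_idx[i], chain.active_idx[i])]
        else:
            k_act = op.gram(pts, jitter=jitter)
        chol = safe_cholesky(k_act, params.amplitude_s, jitter=0.0)
        mt = cho_solve((chol, True), chain.phi_active[i])
        ks = _s_features(t_grid, pts, params.amplitude_s, params.lengthscale_s, params.half_exponent)
        gf = _g_features(lag_grid, pts, chain.events, effect, params.half_exponent)
        s_draws[i] = ks @ mt
        g_draws[i] = gf @ mt
    return chain.lambda_samples, s_draws, g_draws


def fitted_ground_truth(state: VariationalState, n_grid: int = 200):
    """Plug-in generative model from a fitted univariate posterior.

    Uses the posterior means of s and gtilde and the posterior-mean intensity
    bound, so the fit can be re-simulated and compared with the training
    data.  The returned truth works directly on the decayed scale (its
    tabulated g is gtilde and its decay is zero), avoiding the exponential
    re-inflation of posterior noise at long lags.
    """
    from .kernels import KernelParams
    from .simulate import GroundTruth

    dec = decompose(state, n_grid=n_grid)
    effect = state.streams[0][1]
    params = KernelParams(
        state.amplitude_s, state.lengthscale_s, effect.amplitude,
        effect.lengthscale, 0.0, half_exponent=state.half_exponent,
    )
    return GroundTruth(
        dec.t_grid, dec.s_mean, dec.lag_grid, dec.g_mean,
        state.lambda_mean, params, "fitted", state.window_end,
    )


def phi_from_components(t, history, t_grid, s_values, lag_grid, g_values):
    """Rebuild phi(t) = s(t) + sum_{t_i < t} gtilde(t - t_i) from tabulated components.

    ``history`` holds the event times of the sequence being evaluated (e.g. a
    held-out test window); components are linearly interpolated and gtilde is
    clamped to zero beyond its grid.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    h = np.asarray(getattr(history, "times", history), dtype=float)
    out = np.interp(t, t_grid, s_values)
    for k, tk in enumerate(t):
        past = h[h < tk]
        if past.size:
            out[k] += np.interp(tk - past, lag_grid, g_values, right=0.0).sum()
    return out
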