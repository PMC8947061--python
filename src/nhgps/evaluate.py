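"""Model assessment: point-process likelihoods, time rescaling, KS uniformity.

The log-likelihood of events {t_n} under a conditional intensity Lambda is

    sum_n ln Lambda(t_n) - integral_0^T Lambda(t) dt,

with the survival integral evaluated by Gauss-Legendre quadrature.  For
goodness of fit, the random time change tau_k = integral_{t_{k-1}}^{t_k}
Lambda(u) du maps the events of the true process to a unit-rate Poisson
process, so z_k = 1 - exp(-tau_k) are i.i.d. Uniform(0, 1); the one-sample
Kolmogorov-Smirnov statistic against the uniform distribution, with its 95%
quantile band 1.36 / sqrt(n), quantifies the departure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstwo, kstwobign

from .vi import gauss_legendre

__all__ = [
    "GoodnessOfFit",
    "point_process_loglik",
    "test_loglik_per_event",
    "time_rescale",
    "ks_uniform_test",
]


@dataclass
class GoodnessOfFit:
    rescaled_values: np.ndarray
    ks_statistic: float
    p_value: float
    ci_95_band: float

    @property
    def passed(self) -> bool:
        return self.p_value > 0.05


def point_process_loglik(events, intensity, window_end: float, n_quad: int = 200) -> float:
    """Log-likelihood sum_n ln Lambda(t_n) - integral of Lambda over [0, T].

    ``intensity`` is a vectorised evaluator of the conditional intensity over
    the window (it must already condition on the appropriate history).  Zero
    intensity at an observed event yields -inf with a warning-free clamp at
    the log level.
    """
    times = np.asarray(getattr(events, "times", events), dtype=float)
    nodes, weights = gauss_legendre(n_quad, 0.0, window_end)
    vals = np.asarray(intensity(nodes), dtype=float)
    if np.any(vals < 0):
        raise ValueError("intensity must be non-negative over the window")
    integral = float(weights @ vals)
    if times.size == 0:
        return -integral
    at_events = np.asarray(intensity(times), dtype=float)
    with np.errstate(divide="ignore"):
        log_terms = np.log(at_events)
    return float(log_terms.sum() - integral)


def test_loglik_per_event(
    posterior_sampler,
    test_events,
    window_end: float,
    n_mc: int = 200,
    n_quad: int = 200,
) -> float:
    """Monte-Carlo posterior-averaged log-likelihood per test event.

    ``posterior_sampler(n)`` must return ``n`` triples as arrays
    ``(lambda, s_on_grid, gtilde_on_grid)`` together with the grids, i.e. a
    tuple ``(lam, t_grid, s_draws, lag_grid, g_draws)``; each draw defines an
    intensity lambda_i sigma(phi_i(t)) on the test history and the average
    log-likelihood is divided by the number of test events.
    """
    from .decompose import phi_from_components
    from .pg import sigmoid

    times = np.asarray(getattr(test_events, "times", test_events), dtype=float)
    if times.size == 0:
        raise ValueError("test log-likelihood per event needs a non-empty test set")
    lam, t_grid, s_draws, lag_grid, g_draws = posterior_sampler(n_mc)
    nodes, _ = gauss_legendre(n_quad, 0.0, window_end)
    total = 0.0
    n_used = lam.size
    for i in range(n_used):
        def intensity(t, i=i):
            phi = phi_from_components(t, times, t_grid, s_draws[i], lag_grid, g_draws[i])
            return lam[i] * sigmoid(phi)

        total += point_process_loglik(times, intensity, window_end, n_quad)
    return total / (n_used * times.size)


def time_rescale(events, intensity, window_end: float, n_quad: int = 64) -> np.ndarray:
    """Uniformised time-rescaling transform of an event sequence.

    tau_k = integral_{t_{k-1}}^{t_k} Lambda(u) du (t_0 = 0), z_k = 1 - exp(-tau_k).
    Under the true conditional intensity the z_k are i.i.d. Uniform(0, 1).
    """
    times = np.asarray(getattr(events, "times", events), dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("events must be sorted")
    bounds = np.concatenate([[0.0], times])
    taus = np.empty(times.size)
    base_nodes, base_weights = gauss_legendre(n_quad, 0.0, 1.0)
    for k in range(times.size):
        a, b = bounds[k], bounds[k + 1]
        nodes = a + (b - a) * base_nodes
        taus[k] = (b - a) * float(base_weights @ np.asarray(intensity(nodes), dtype=float))
    return -np.expm1(-taus)


def ks_uniform_test(values) -> GoodnessOfFit:
    """One-sample KS test of values in [0, 1] against Uniform(0, 1).

    Exact null distribution below n = 35, the asymptotic Kolmogorov
    distribution otherwise; the 95% band half-width for quantile plots is
    1.36 / sqrt(n).
    """
    z = np.sort(np.asarray(values, dtype=float))
    n = z.size
    if n < 5:
        raise ValueError("KS test needs at least 5 values")
    if z[0] < 0 or z[-1] > 1:
        raise ValueError("rescaled values must lie in [0, 1]")
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    stat = float(max(np.max(ecdf_hi - z), np.max(z - ecdf_lo)))
    if n < 35:
        p = float(kstwo.sf(stat, n))
    else:
        p = float(kstwobign.sf(stat * np.sqrt(n)))
    return GoodnessOfFit(z, stat, min(max(p, 0.0), 1.0), 1.36 / np.sqrt(n))
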