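"""Blocked Gibbs sampler for the sigmoid-link Hawkes model (MCMC baseline).

The augmented posterior factorises into four exact conditionals:

1. latent thinned points: a Poisson process with base rate lambda, keeping a
   candidate at t with probability sigma(-phi(t)), phi drawn from its GP
   conditional at the proposed locations;
2. PG variables: w ~ PG(1, |phi|) at every event and latent point;
3. phi at all active points: Gaussian with precision (prior aggregated-kernel
   precision + diag(w)) and linear term +1/2 at events, -1/2 at latent points;
4. intensity bound: lambda ~ Gamma(alpha0 + N + M, beta0 + T).

Latent points are re-proposed jointly each sweep by fresh thinning.  By
default candidate locations live on a fixed uniform lattice so that every
aggregated-kernel Gram block can be precomputed once, making sweeps cheap;
``latent_grid=None`` switches to exact continuous-location proposals (a
fresh Gram per sweep), which is practical only for small problems.
Hyperparameters are fixed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .kernels import AggregatedKernel, KernelParams, safe_cholesky
from .pg import sample_pg, sigmoid
from .simulate import EventSequence

__all__ = [
    "GibbsConfig",
    "GibbsState",
    "GibbsChain",
    "GibbsSampler",
    "gibbs_sweep",
    "run_gibbs",
    "autocorrelation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GibbsConfig:
    window_end: float = 1.0
    params: KernelParams | None = None
    prior_shape: float = 2.0
    prior_rate: float = 0.02
    n_sweeps: int = 5000
    burn_in: int = 1000
    thin: int = 10
    latent_grid: int | None = 250
    jitter: float = 1e-6


@dataclass
class GibbsState:
    """One MCMC configuration.

    ``latent_idx``/``latent_mult`` give the unique candidate-lattice indices
    of the latent points and their multiplicities (continuous mode stores the
    locations themselves in ``latent_times`` with unit multiplicities).
    """

    lambda_value: float
    phi_events: np.ndarray
    phi_latent: np.ndarray
    latent_times: np.ndarray
    latent_mult: np.ndarray
    latent_idx: np.ndarray | None = None

    @property
    def n_latent(self) -> int:
        return int(self.latent_mult.sum())


@dataclass
class GibbsChain:
    """Post-burn-in (thinned) samples plus what is needed to post-process them."""

    events: np.ndarray
    window_end: float
    params: KernelParams
    lambda_samples: np.ndarray
    latent_counts: np.ndarray
    phi_events: np.ndarray  # (S, N)
    active_times: list  # per stored sample: event times + latent times
    phi_active: list  # per stored sample: phi values at active_times
    prior_shape: float
    prior_rate: float
    # lattice mode only: precomputed support Gram for cheap post-processing
    support_times: np.ndarray | None = None
    k_full: np.ndarray | None = None
    active_idx: list | None = None

    @property
    def lambda_mean(self) -> float:
        return float(self.lambda_samples.mean())


class GibbsSampler:
    def __init__(self, events, config: GibbsConfig):
        times = np.asarray(getattr(events, "times", events), dtype=float)
        if config.params is None:
            from .simulate import default_fixture_params

            config = GibbsConfig(**{**config.__dict__, "params": default_fixture_params()})
        self.config = config
        self.events = times
        self.params = config.params
        self.op = AggregatedKernel.univariate(times, self.params)
        self.N = times.size
        T = config.window_end
        if config.latent_grid is not None:
            G = int(config.latent_grid)
            self.grid = (np.arange(G) + 0.5) * T / G
            pts = np.concatenate([times, self.grid])
            self.k_full = self.op.gram(pts, jitter=config.jitter)
        else:
            self.grid = None
            self.k_full = self.op.gram(times, jitter=config.jitter)
        self.k_ee_chol = (
            safe_cholesky(self.k_full[: self.N, : self.N], self.params.amplitude_s, jitter=0.0),
            True,
        )

    # -- helpers ------------------------------------------------------------

    def _conditional_phi(self, k_pp, k_pe, phi_events, rng):
        """Joint GP-conditional draw of phi at proposal points given phi at events."""
        if self.N == 0:
            cov = k_pp
            mean = np.zeros(k_pp.shape[0])
        else:
            w = cho_solve(self.k_ee_chol, k_pe.T)  # (N, P)
            mean = w.T @ phi_events
            cov = k_pp - k_pe @ w
        chol = safe_cholesky(cov, self.params.amplitude_s, jitter=1e-10)
        return mean + chol @ rng.standard_normal(mean.size)

    def init_state(self, rng) -> GibbsState:
        lam = rng.gamma(self.config.prior_shape) / self.config.prior_rate
        lam = max(lam, 1.0)
        phi_ev = np.zeros(self.N)
        return GibbsState(
            lambda_value=lam,
            phi_events=phi_ev,
            phi_latent=np.empty(0),
            latent_times=np.empty(0),
            latent_mult=np.empty(0, dtype=int),
            latent_idx=np.empty(0, dtype=int) if self.grid is not None else None,
        )

    # -- one sweep ----------------------------------------------------------

    def sweep(
        self,
        state: GibbsState,
        rng,
        blocks=("latent", "pg_phi", "lambda"),
    ) -> GibbsState:
        """One sweep; ``blocks`` restricts which conditionals are resampled
        (useful for exact-conditional checks with the others frozen)."""
        cfg = self.config
        T = cfg.window_end

        if "latent" in blocks:
            n_cand = rng.poisson(state.lambda_value * T)
            latent = self._propose_latents(state, n_cand, rng)
        else:
            latent = state

        if "pg_phi" not in blocks:
            m_total = int(latent.latent_mult.sum())
            lam = state.lambda_value
            if "lambda" in blocks:
                lam = rng.gamma(cfg.prior_shape + self.N + m_total) / (cfg.prior_rate + T)
            return GibbsState(
                lambda_value=lam,
                phi_events=latent.phi_events,
                phi_latent=latent.phi_latent,
                latent_times=latent.latent_times,
                latent_mult=latent.latent_mult,
                latent_idx=latent.latent_idx,
            )
        return self._update_pg_phi_lambda(latent, rng, "lambda" in blocks)

    def _propose_latents(self, state: GibbsState, n_cand: int, rng) -> GibbsState:
        cfg = self.config
        if self.grid is not None:
            cand_idx = rng.integers(0, self.grid.size, size=n_cand)
            uniq, inverse = np.unique(cand_idx, return_inverse=True)
            off = self.N
            k_pp = self.k_full[np.ix_(off + uniq, off + uniq)]
            k_pe = self.k_full[np.ix_(off + uniq, np.arange(self.N))]
            phi_uniq = self._conditional_phi(k_pp, k_pe, state.phi_events, rng)
            keep = rng.random(n_cand) < sigmoid(-phi_uniq[inverse])
            kept_idx = cand_idx[keep]
            lat_uniq, lat_mult = np.unique(kept_idx, return_counts=True)
            sel = np.searchsorted(uniq, lat_uniq)
            latent = GibbsState(
                lambda_value=state.lambda_value,
                phi_events=state.phi_events,
                phi_latent=phi_uniq[sel],
                latent_times=self.grid[lat_uniq],
                latent_mult=lat_mult,
                latent_idx=lat_uniq,
            )
            return latent
        cand = np.sort(rng.uniform(0.0, self.config.window_end, size=n_cand))
        k_pp = self.op.gram(cand, jitter=cfg.jitter)
        k_pe = self.op.gram(cand, self.events)
        phi_cand = self._conditional_phi(k_pp, k_pe, state.phi_events, rng)
        keep = rng.random(n_cand) < sigmoid(-phi_cand)
        return GibbsState(
            lambda_value=state.lambda_value,
            phi_events=state.phi_events,
            phi_latent=phi_cand[keep],
            latent_times=cand[keep],
            latent_mult=np.ones(int(keep.sum()), dtype=int),
            latent_idx=None,
        )

    def _update_pg_phi_lambda(self, latent: GibbsState, rng, draw_lambda: bool) -> GibbsState:
        cfg = self.config
        T = cfg.window_end
        state = latent
        # (ii) PG draws at events and latent points (one per latent multiplicity)
        phi_all_latent = np.repeat(latent.phi_latent, latent.latent_mult)
        w_events = (
            sample_pg(np.abs(state.phi_events), rng) if self.N else np.empty(0)
        )
        w_latent_each = (
            sample_pg(np.abs(phi_all_latent), rng) if phi_all_latent.size else np.empty(0)
        )
        # collapse multiplicities: duplicated locations share one phi entry
        w_latent = np.zeros(latent.latent_mult.size)
        np.add.at(w_latent, np.repeat(np.arange(latent.latent_mult.size), latent.latent_mult), w_latent_each)

        # (iii) Gaussian conditional of phi at all active points
        if self.grid is not None:
            act = np.concatenate([np.arange(self.N), self.N + latent.latent_idx])
            k_act = self.k_full[np.ix_(act, act)]
        else:
            pts = np.concatenate([self.events, latent.latent_times])
            k_act = self.op.gram(pts, jitter=cfg.jitter)
        w = np.concatenate([w_events, w_latent])
        b = np.concatenate([np.full(self.N, 0.5), -0.5 * latent.latent_mult.astype(float)])
        chol_k = safe_cholesky(k_act, self.params.amplitude_s, jitter=0.0)
        kinv = cho_solve((chol_k, True), np.eye(k_act.shape[0]))
        prec = kinv + np.diag(w)
        chol_p = safe_cholesky(0.5 * (prec + prec.T), max(w.max(initial=0.0), 1.0), jitter=0.0)
        mean = cho_solve((chol_p, True), b)
        phi_act = mean + solve_triangular(
            chol_p.T, rng.standard_normal(b.size), lower=False
        )

        # (iv) conjugate Gamma draw for the intensity bound
        m_total = int(latent.latent_mult.sum())
        lam = latent.lambda_value
        if draw_lambda:
            lam = rng.gamma(cfg.prior_shape + self.N + m_total) / (cfg.prior_rate + T)

        return GibbsState(
            lambda_value=lam,
            phi_events=phi_act[: self.N],
            phi_latent=phi_act[self.N :],
            latent_times=latent.latent_times,
            latent_mult=latent.latent_mult,
            latent_idx=latent.latent_idx,
        )


def gibbs_sweep(sampler: GibbsSampler, state: GibbsState, rng) -> GibbsState:
    """One full blocked sweep (latent points, PG draws, phi, lambda)."""
    return sampler.sweep(state, rng)


def run_gibbs(events, config: GibbsConfig, rng_seed=0) -> GibbsChain:
    """Run the sampler and return post-burn-in, thinned samples.

    Reproducible: the same seed yields an identical chain.
    """
    if config.n_sweeps <= config.burn_in:
        raise ValueError("n_sweeps must exceed burn_in")
    rng = np.random.default_rng(rng_seed)
    sampler = GibbsSampler(events, config)
    state = sampler.init_state(rng)
    lam, counts, phi_ev, act_times, phi_act = [], [], [], [], []
    act_idx: list | None = [] if sampler.grid is not None else None
    for it in range(config.n_sweeps):
        state = sampler.sweep(state, rng)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            lam.append(state.lambda_value)
            counts.append(state.n_latent)
            phi_ev.append(state.phi_events.copy())
            act_times.append(np.concatenate([sampler.events, state.latent_times]))
            phi_act.append(np.concatenate([state.phi_events, state.phi_latent]))
            if act_idx is not None:
                act_idx.append(
                    np.concatenate([np.arange(sampler.N), sampler.N + state.latent_idx])
                )
        if (it + 1) % 1000 == 0:
            logger.info("Gibbs sweep %d: lambda=%.2f, M=%d", it + 1, state.lambda_value, state.n_latent)
    return GibbsChain(
        events=sampler.events,
        window_end=config.window_end,
        params=sampler.params,
        lambda_samples=np.array(lam),
        latent_counts=np.array(counts),
        phi_events=np.array(phi_ev),
        active_times=act_times,
        phi_active=phi_act,
        prior_shape=config.prior_shape,
        prior_rate=config.prior_rate,
        support_times=(
            np.concatenate([sampler.events, sampler.grid]) if sampler.grid is not None else None
        ),
        k_full=sampler.k_full if sampler.grid is not None else None,
        active_idx=act_idx,
    )


def autocorrelation(chain, max_lag: int) -> np.ndarray:
    """Normalised autocorrelation of a scalar chain, acf[0] = 1."""
    x = np.asarray(chain, dtype=float)
    if x.size <= max_lag:
        raise ValueError("chain must be longer than max_lag")
    x = x - x.mean()
    var = float(x @ x)
    if var == 0:
        raise ValueError("autocorrelation of a constant chain is undefined")
    acf = np.array([x[: x.size - k] @ x[k:] for k in range(max_lag + 1)]) / var
    return acf
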