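"""Event-file I/O, run configuration, state archives, and the pipeline driver.

Events travel as plain CSV with a ``time`` column and an optional integer
``mark`` column (0-based dimension labels).  Times are real-valued seconds
in the half-open window [0, T).  Fitted variational states are archived as
NumPy ``.npz`` files carrying the arrays plus a JSON metadata blob (config
echo, seed, library versions) so every artifact is self-describing.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from .kernels import KernelParams, SelfEffectParams
from .simulate import EventSequence
from .vi import VariationalState, VIConfig

__all__ = [
    "RunConfig",
    "read_events",
    "write_events",
    "write_ground_truth",
    "save_state",
    "load_state",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat, JSON-compatible configuration of an end-to-end run."""

    window_end: float = 1.0
    amplitude_s: float = 1.0
    lengthscale_s: float = 0.3
    amplitude_g: float = 1.0
    lengthscale_g: float = 0.2
    decay: float = 10.0
    lambda_bound: float = 180.0
    prior_shape: float = 2.0
    prior_rate: float = 0.02
    n_inducing: int = 50
    n_quad: int = 100
    vi_tol: float = 1e-4
    vi_max_iter: int = 200
    tune_hyperparams: bool = False
    gibbs_sweeps: int = 0
    gibbs_burn_in: int = 0
    n_dims: int = 1
    seed: int = 0
    truth: str = "gp_draw"  # or "cosine"
    cosine: tuple = (1.0, 6.0, 1.0, 12.0)  # beta1, theta1, beta2, theta2

    def __post_init__(self) -> None:
        if self.window_end <= 0:
            raise ValueError("window_end must be positive")
        for name in ("n_inducing", "n_quad", "vi_max_iter", "n_dims"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.truth not in ("gp_draw", "cosine"):
            raise ValueError("truth must be 'gp_draw' or 'cosine'")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "cosine" in raw:
            raw["cosine"] = tuple(raw["cosine"])
        return cls(**raw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({**asdict(self), "cosine": list(self.cosine)}, fh, indent=2)

    @property
    def kernel_params(self) -> KernelParams:
        return KernelParams(
            self.amplitude_s,
            self.lengthscale_s,
            self.amplitude_g,
            self.lengthscale_g,
            self.decay,
        )

    @property
    def vi_config(self) -> VIConfig:
        return VIConfig(
            window_end=self.window_end,
            params=self.kernel_params,
            n_inducing=self.n_inducing,
            n_quad=self.n_quad,
            max_iter=self.vi_max_iter,
            tol=self.vi_tol,
            prior_shape=self.prior_shape,
            prior_rate=self.prior_rate,
            tune_hyperparams=self.tune_hyperparams,
        )


def read_events(path, window_end: float | None = None) -> EventSequence:
    """Read a ``time[,mark]`` CSV into a validated, sorted EventSequence.

    Duplicate timestamps are perturbed by 1e-9 * T with a warning; times
    outside [0, T) raise with the offending values listed.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: expected a 'time' column, got {list(df.columns)}")
    order = np.argsort(df["time"].to_numpy(), kind="stable")
    times = df["time"].to_numpy(dtype=float)[order]
    marks = df["mark"].to_numpy(dtype=int)[order] if "mark" in df.columns else None
    T = window_end if window_end is not None else (float(times[-1]) * (1 + 1e-12) + 1e-12 if times.size else 1.0)
    bad = times[(times < 0) | (times >= T)]
    if bad.size:
        raise ValueError(f"{path}: {bad.size} time(s) outside [0, {T}): {bad[:10]}")
    if times.size:
        dup = np.diff(times) == 0
        if dup.any():
            warnings.warn(
                f"{path}: {int(dup.sum())} duplicate timestamp(s) perturbed by 1e-9*T"
            )
            for i in np.flatnonzero(dup):
                times[i + 1] += 1e-9 * T * (i + 1)
            reorder = np.argsort(times, kind="stable")
            times = times[reorder]
            if marks is not None:
                marks = marks[reorder]
    return EventSequence(times, T, marks)


def write_events(seq: EventSequence, path) -> None:
    data = {"time": seq.times}
    if seq.marks is not None:
        data["mark"] = seq.marks
    pd.DataFrame(data).to_csv(path, index=False)


def write_ground_truth(truth, path_s, path_g) -> None:
    """Tabulated s and g grids as two CSVs for external comparison."""
    pd.DataFrame({"t": truth.s_grid, "s": truth.s_values}).to_csv(path_s, index=False)
    pd.DataFrame({"lag": truth.g_grid, "g": truth.g_values}).to_csv(path_g, index=False)


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"nhgps": __version__, "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}


def save_state(state: VariationalState, path, config: RunConfig | None = None) -> None:
    """Archive a fitted variational state (arrays + JSON metadata)."""
    meta = {
        "window_end": state.window_end,
        "amplitude_s": state.amplitude_s,
        "lengthscale_s": state.lengthscale_s,
        "prior_shape": state.prior_shape,
        "prior_rate": state.prior_rate,
        "jitter": state.jitter,
        "half_exponent": state.half_exponent,
        "effects": [
            {"amplitude": e.amplitude, "lengthscale": e.lengthscale, "decay": e.decay}
            for _, e in state.streams
        ],
        "versions": _versions(),
        "config": (json.loads(json.dumps({**asdict(config), "cosine": list(config.cosine)}))
                   if config else None),
    }
    arrays = {
        "inducing": state.inducing,
        "mu_c": state.mu_c,
        "sigma_c": state.sigma_c,
        "lambda_shape": np.array(state.lambda_shape),
        "lambda_rate": np.array(state.lambda_rate),
        "event_tilts": state.event_tilts,
        "quad_nodes": state.quad_nodes,
        "quad_weights": state.quad_weights,
        "quad_tilts": state.quad_tilts,
        "latent_rate": state.latent_rate,
        "elbo_trace": state.elbo_trace,
        "events": state.events,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    for m, (ev, _) in enumerate(state.streams):
        arrays[f"stream_{m}"] = ev
    np.savez(path, **arrays)


def load_state(path) -> VariationalState:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        streams = [
            (data[f"stream_{m}"], SelfEffectParams(**eff))
            for m, eff in enumerate(meta["effects"])
        ]
        return VariationalState(
            inducing=data["inducing"],
            mu_c=data["mu_c"],
            sigma_c=data["sigma_c"],
            lambda_shape=float(data["lambda_shape"]),
            lambda_rate=float(data["lambda_rate"]),
            event_tilts=data["event_tilts"],
            quad_nodes=data["quad_nodes"],
            quad_weights=data["quad_weights"],
            quad_tilts=data["quad_tilts"],
            latent_rate=data["latent_rate"],
            elbo_trace=data["elbo_trace"],
            events=data["events"],
            window_end=meta["window_end"],
            amplitude_s=meta["amplitude_s"],
            lengthscale_s=meta["lengthscale_s"],
            streams=streams,
            prior_shape=meta["prior_shape"],
            prior_rate=meta["prior_rate"],
            jitter=meta["jitter"],
            half_exponent=meta["half_exponent"],
        )


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> fit VI (-> Gibbs) -> decompose -> evaluate, writing artifacts.

    Returns the report dictionary; every artifact embeds the config and seed.
    Stage failures propagate with the stage name prefixed.
    """
    import os

    from .decompose import decompose, sample_component_functions
    from .evaluate import ks_uniform_test, test_loglik_per_event, time_rescale
    from .simulate import cosine_ground_truth, draw_ground_truth_gp, simulate_events
    from .vi import fit_vi

    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": {**asdict(config), "cosine": list(config.cosine)},
                    "versions": _versions()}
    stage = "simulate"
    try:
        params = config.kernel_params
        if config.truth == "cosine":
            b1, th1, b2, th2 = config.cosine
            truth = cosine_ground_truth(
                b1, th1, b2, th2, config.lambda_bound, config.window_end, params
            )
        else:
            truth = draw_ground_truth_gp(
                params, config.window_end, rng_seed=config.seed,
                lambda_bound=config.lambda_bound,
            )
        seq = simulate_events(truth, rng_seed=config.seed + 1)
        write_events(seq, os.path.join(outdir, "events.csv"))
        write_ground_truth(
            truth, os.path.join(outdir, "truth_s.csv"), os.path.join(outdir, "truth_g.csv")
        )
        report["n_events"] = len(seq)
        logger.info("simulated %d events over [0, %g)", len(seq), config.window_end)

        stage = "fit"
        state = fit_vi(seq, config.vi_config)
        save_state(state, os.path.join(outdir, "state.npz"), config)
        report["lambda_mean_vi"] = state.lambda_mean
        report["elbo_final"] = float(state.elbo_trace[-1])
        report["n_iterations"] = int(state.elbo_trace.size)

        if config.gibbs_sweeps > 0:
            from .gibbs import GibbsConfig, run_gibbs

            chain = run_gibbs(
                seq,
                GibbsConfig(
                    window_end=config.window_end,
                    params=params,
                    prior_shape=config.prior_shape,
                    prior_rate=config.prior_rate,
                    n_sweeps=config.gibbs_sweeps,
                    burn_in=config.gibbs_burn_in,
                ),
                rng_seed=config.seed + 2,
            )
            report["lambda_mean_gibbs"] = chain.lambda_mean

        stage = "decompose"
        dec = decompose(state)
        pd.DataFrame(
            {
                "x": np.concatenate([dec.t_grid, dec.lag_grid]),
                "mean": np.concatenate([dec.s_mean, dec.g_mean]),
                "sd": np.concatenate([dec.s_sd, dec.g_sd]),
                "component": ["s"] * dec.t_grid.size + ["g_tilde"] * dec.lag_grid.size,
            }
        ).to_csv(os.path.join(outdir, "decomposition.csv"), index=False)

        stage = "evaluate"
        test_seq = simulate_events(truth, rng_seed=config.seed + 3)
        t_grid = np.linspace(0.0, config.window_end, 200)
        lag_grid = dec.lag_grid
        rng = np.random.default_rng(config.seed + 4)

        def sampler(n):
            lam, s_draws, g_draws = sample_component_functions(
                state, t_grid, lag_grid, n, rng
            )
            return lam, t_grid, s_draws, lag_grid, g_draws

        if len(test_seq):
            report["test_loglik_per_event_vi"] = test_loglik_per_event(
                sampler, test_seq, config.window_end, n_mc=100
            )
        z = time_rescale(
            seq,
            lambda t: np.array(
                [truth.intensity(tk, seq.before(tk)) for tk in np.atleast_1d(t)]
            ),
            config.window_end,
        )
        gof = ks_uniform_test(z)
        report["ks_statistic_true_intensity"] = gof.ks_statistic
        report["ks_p_value_true_intensity"] = gof.p_value
    except Exception as exc:  # re-raise with the failing stage named
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
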