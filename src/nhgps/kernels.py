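"""Covariance functions for the aggregated linear intensity of a nonlinear
Hawkes process with Gaussian-process self-effects.

The linear intensity is

    phi(t) = s(t) + sum_{t_n < t} g(t - t_n) exp(-alpha (t - t_n)),

with independent zero-mean GP priors on the background rate ``s`` and the
self-effect function ``g``, both with RBF covariances

    K(t1, t2) = a * exp(-(t1 - t2)^2 / sigma^2).

Because phi is a sum of GPs it is itself a GP; conditioned on the event
history its covariance is the RBF kernel of ``s`` plus a double sum of
decayed ``g`` covariances over the two histories.  This module provides
that aggregated kernel, vectorised Gram builders (including cross-Grams
against inducing points), and a jitter-escalating Cholesky.

The exponent convention ``-(dt)^2 / sigma^2`` (no factor 2) is the default;
the conventional ``-(dt)^2 / (2 sigma^2)`` form is available through
``half_exponent=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelParams",
    "SelfEffectParams",
    "HistorySet",
    "rbf_kernel",
    "decayed_g_kernel",
    "aggregated_kernel",
    "gram_matrix",
    "AggregatedKernel",
    "safe_cholesky",
]


@dataclass(frozen=True)
class SelfEffectParams:
    """RBF amplitude/lengthscale of one self-effect GP plus its memory decay rate."""

    amplitude: float
    lengthscale: float
    decay: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.lengthscale <= 0:
            raise ValueError(f"lengthscale must be > 0, got {self.lengthscale}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the univariate model.

    Attributes
    ----------
    amplitude_s, lengthscale_s
        RBF amplitude (prior variance) and lengthscale of the background rate s.
    amplitude_g, lengthscale_g
        RBF amplitude and lengthscale of the self-effect function g.
    decay
        Exponential memory decay rate alpha (per unit time, >= 0).
    half_exponent
        If True use exp(-dt^2/(2 sigma^2)) instead of the default exp(-dt^2/sigma^2).
    """

    amplitude_s: float
    lengthscale_s: float
    amplitude_g: float
    lengthscale_g: float
    decay: float
    half_exponent: bool = False

    def __post_init__(self) -> None:
        for name in ("amplitude_s", "lengthscale_s", "amplitude_g", "lengthscale_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.decay < 0:
            raise ValueError(f"decay must be >= 0, got {self.decay}")

    @property
    def self_effect(self) -> SelfEffectParams:
        return SelfEffectParams(self.amplitude_g, self.lengthscale_g, self.decay)

    def as_array(self) -> np.ndarray:
        """(a_s, sigma_s, a_g, sigma_g, alpha) as a float vector."""
        return np.array(
            [
                self.amplitude_s,
                self.lengthscale_s,
                self.amplitude_g,
                self.lengthscale_g,
                self.decay,
            ]
        )

    @classmethod
    def from_array(cls, x, half_exponent: bool = False) -> "KernelParams":
        return cls(*(float(v) for v in x), half_exponent=half_exponent)


@dataclass(frozen=True)
class HistorySet:
    """Strictly increasing event times inside an observation window [0, T)."""

    event_times: np.ndarray
    window_end: float

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        object.__setattr__(self, "event_times", times)
        if self.window_end <= 0:
            raise ValueError("window_end must be positive")
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValueError("event times must be finite")
            if np.any(np.diff(times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] >= self.window_end:
                raise ValueError("event times must lie in [0, window_end)")

    def before(self, t: float) -> np.ndarray:
        """Events strictly before time t."""
        return self.event_times[: np.searchsorted(self.event_times, t, side="left")]


def rbf_kernel(dt, amplitude: float, lengthscale: float, half_exponent: bool = False):
    """RBF covariance a * exp(-dt^2 / sigma^2) of a time difference.

    ``half_exponent=True`` switches to the a * exp(-dt^2 / (2 sigma^2)) convention.
    Symmetric in the sign of ``dt`` and bounded by ``amplitude``.
    """
    if amplitude <= 0 or lengthscale <= 0:
        raise ValueError("amplitude and lengthscale must be strictly positive")
    dt = np.asarray(dt, dtype=float)
    denom = lengthscale**2 * (2.0 if half_exponent else 1.0)
    return amplitude * np.exp(-(dt**2) / denom)


def decayed_g_kernel(lag1, lag2, params: KernelParams):
    """Covariance of the decayed self-effect gtilde(tau) = g(tau) exp(-alpha tau).

    Kgtilde(l1, l2) = Kg(l1, l2) * exp(-alpha (l1 + l2)) for non-negative lags.
    """
    lag1 = np.asarray(lag1, dtype=float)
    lag2 = np.asarray(lag2, dtype=float)
    if np.any(lag1 < 0) or np.any(lag2 < 0):
        raise ValueError("lags must be non-negative (self-effects are causal)")
    base = rbf_kernel(
        lag1 - lag2, params.amplitude_g, params.lengthscale_g, params.half_exponent
    )
    return base * np.exp(-params.decay * (lag1 + lag2))


def _validate_history(t: float, history) -> np.ndarray:
    h = np.asarray(getattr(history, "event_times", history), dtype=float)
    if h.size and h.max() >= t:
        raise ValueError("history must contain only events strictly before the evaluation time")
    return h


def aggregated_kernel(t1: float, t2: float, history1, history2, params: KernelParams) -> float:
    """Covariance of phi between two times, each with its own event history.

    Ks(t1,t2) + sum_{ti<t1} sum_{tj<t2} Kg(t1-ti, t2-tj) exp(-alpha[(t1-ti)+(t2-tj)]).
    """
    h1 = _validate_history(t1, history1)
    h2 = _validate_history(t2, history2)
    val = float(
        rbf_kernel(t1 - t2, params.amplitude_s, params.lengthscale_s, params.half_exponent)
    )
    if h1.size and h2.size:
        l1 = t1 - h1
        l2 = t2 - h2
        val += float(np.sum(decayed_g_kernel(l1[:, None], l2[None, :], params)))
    return val


# ---------------------------------------------------------------------------
# Vectorised Gram machinery
# ---------------------------------------------------------------------------


def _lag_expansion(times: np.ndarray, events: np.ndarray, decay: float):
    """Flatten the causal lag sets of many evaluation times against one event stream.

    For each time t the history is the prefix of ``events`` strictly before t.
    Returns (lags, weights, offsets) where ``lags`` concatenates t - e over all
    valid (t, e) pairs, ``weights`` = exp(-decay * lag), and ``offsets`` is of
    length len(times)+1 delimiting each time's segment.
    """
    times = np.asarray(times, dtype=float)
    counts = np.searchsorted(events, times, side="left")
    offsets = np.concatenate([[0], np.cumsum(counts)])
    total = int(offsets[-1])
    lags = np.empty(total)
    for k, (t, c) in enumerate(zip(times, counts)):
        lags[offsets[k] : offsets[k + 1]] = t - events[:c]
    weights = np.exp(-decay * lags)
    return lags, weights, offsets


def _segment_sum(mat: np.ndarray, offsets: np.ndarray, axis: int) -> np.ndarray:
    """Sum contiguous segments (possibly empty) of ``mat`` along ``axis``."""
    csum = np.cumsum(mat, axis=axis)
    pad = np.zeros_like(np.take(csum, [0], axis=axis))
    csum = np.concatenate([pad, csum], axis=axis)
    upper = np.take(csum, offsets[1:], axis=axis)
    lower = np.take(csum, offsets[:-1], axis=axis)
    return upper - lower


class AggregatedKernel:
    """Aggregated-phi covariance operator for a fixed set of source event streams.

    Parameters
    ----------
    amplitude_s, lengthscale_s
        RBF hyperparameters of the background-rate GP.
    streams
        Sequence of (event_times, SelfEffectParams) pairs, one per source
        stream.  The univariate model has a single stream (the process' own
        events); the multivariate model passes one stream per source dimension
        with per-pair self-effect hyperparameters.
    half_exponent
        RBF exponent convention flag shared by all component kernels.

    Histories are causal prefixes: the history of an evaluation time t is the
    set of stream events strictly before t.
    """

    #: row-block size used when tiling large pairwise-lag matrices
    _BLOCK = 1024

    def __init__(self, amplitude_s, lengthscale_s, streams, half_exponent=False):
        if amplitude_s <= 0 or lengthscale_s <= 0:
            raise ValueError("background amplitude and lengthscale must be positive")
        self.amplitude_s = float(amplitude_s)
        self.lengthscale_s = float(lengthscale_s)
        self.half_exponent = bool(half_exponent)
        self.streams = []
        for events, effect in streams:
            events = np.asarray(events, dtype=float)
            if events.size and np.any(np.diff(events) < 0):
                raise ValueError("stream event times must be sorted")
            self.streams.append((events, effect))

    @classmethod
    def univariate(cls, events, params: KernelParams) -> "AggregatedKernel":
        return cls(
            params.amplitude_s,
            params.lengthscale_s,
            [(events, params.self_effect)],
            params.half_exponent,
        )

    # -- scalar interface ---------------------------------------------------

    def __call__(self, t1: float, t2: float) -> float:
        return float(self.gram(np.array([t1]), np.array([t2]))[0, 0])

    # -- vectorised Grams ---------------------------------------------------

    def _rbf(self, d, amplitude, lengthscale):
        denom = lengthscale**2 * (2.0 if self.half_exponent else 1.0)
        return amplitude * np.exp(-(d**2) / denom)

    def gram(self, ta, tb=None, jitter: float | None = None) -> np.ndarray:
        """Dense Gram matrix K[i, j] = cov(phi(ta_i), phi(tb_j)).

        When ``tb`` is omitted the square Gram of ``ta`` is built and
        ``jitter * amplitude_s`` (if given) is added to the diagonal.
        """
        ta = np.asarray(ta, dtype=float)
        symmetric = tb is None
        tb = ta if symmetric else np.asarray(tb, dtype=float)
        out = self._rbf(ta[:, None] - tb[None, :], self.amplitude_s, self.lengthscale_s)
        for events, eff in self.streams:
            if events.size == 0:
                continue
            la, wa, offa = _lag_expansion(ta, events, eff.decay)
            if symmetric:
                lb, wb, offb = la, wa, offa
            else:
                lb, wb, offb = _lag_expansion(tb, events, eff.decay)
            if la.size == 0 or lb.size == 0:
                continue
            wb_col = wb[None, :]
            acc = None
            for start in range(0, la.size, self._BLOCK):
                stop = min(start + self._BLOCK, la.size)
                block = self._rbf(
                    la[start:stop, None] - lb[None, :], eff.amplitude, eff.lengthscale
                )
                block *= wa[start:stop, None] * wb_col
                # collapse the row-lag axis into per-time segments
                acc_rows = _segment_sum(
                    block, np.clip(offa - start, 0, stop - start), axis=0
                )
                acc = acc_rows if acc is None else acc + acc_rows
            out += _segment_sum(acc, offb, axis=1)
        if symmetric:
            out = 0.5 * (out + out.T)
            if jitter is not None:
                out[np.diag_indices_from(out)] += jitter * self.amplitude_s
        return out

    def gram_diag(self, ta) -> np.ndarray:
        """Prior variances cov(phi(t), phi(t)) without building the full Gram."""
        ta = np.asarray(ta, dtype=float)
        out = np.full(ta.size, self.amplitude_s)
        for events, eff in self.streams:
            if events.size == 0:
                continue
            la, wa, offa = _lag_expansion(ta, events, eff.decay)
            for k in range(ta.size):
                seg = slice(offa[k], offa[k + 1])
                x, w = la[seg], wa[seg]
                if x.size:
                    m = self._rbf(x[:, None] - x[None, :], eff.amplitude, eff.lengthscale)
                    out[k] += float(w @ m @ w)
        return out


def gram_matrix(points_a, points_b, params: KernelParams, events=None, jitter: float = 1e-6):
    """Aggregated-kernel Gram between two sets of times sharing one event stream.

    ``events`` is the observed univariate event stream supplying every
    history (causal prefixes).  When ``points_b is None`` the square Gram is
    returned with ``jitter * amplitude_s`` on the diagonal.
    """
    events = np.empty(0) if events is None else np.asarray(events, dtype=float)
    op = AggregatedKernel.univariate(events, params)
    if points_b is None:
        return op.gram(points_a, jitter=jitter)
    return op.gram(points_a, np.asarray(points_b, dtype=float))


def safe_cholesky(mat: np.ndarray, scale: float, jitter: float = 1e-6, jitter_max: float = 1e-2):
    """Lower Cholesky with x10 jitter escalation (jitter measured relative to ``scale``).

    Raises ``np.linalg.LinAlgError`` with a diagnostic once ``jitter_max`` is exceeded.
    """
    j = jitter
    while True:
        try:
            return np.linalg.cholesky(mat + j * scale * np.eye(mat.shape[0]))
        except np.linalg.LinAlgError:
            j = 1e-10 if j == 0 else j * 10.0
            if j > jitter_max:
                raise np.linalg.LinAlgError(
                    f"Cholesky failed even with jitter {j / 10:.1e} * {scale:.3g}; "
                    "matrix is numerically indefinite"
                )
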