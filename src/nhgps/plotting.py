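"""Convenience figures (untested decoration; requires the ``plot`` extra)."""

from __future__ import annotations

import numpy as np


def plot_fit(state, truth=None, events=None, ax=None, n_grid=300):
    """Posterior linear intensity with a 2-sd band, events as a rug."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ts = np.linspace(0.0, state.window_end, n_grid)
    mean, var = state.posterior_phi(ts)
    sd = np.sqrt(var)
    ax.plot(ts, mean, label="posterior mean phi")
    ax.fill_between(ts, mean - 2 * sd, mean + 2 * sd, alpha=0.2)
    if truth is not None:
        seq = events if events is not None else state.events
        from .simulate import EventSequence

        hist = seq.times if isinstance(seq, EventSequence) else np.asarray(seq)
        ax.plot(ts, [truth.phi(t, hist[hist < t]) for t in ts], "k--", label="truth")
    ev = state.events
    ax.plot(ev, np.full(ev.size, ax.get_ylim()[0]), "|", color="tab:red", ms=10)
    ax.set_xlabel("time [s]")
    ax.set_ylabel("phi(t)")
    ax.legend()
    return ax


def plot_decomposition(dec, truth=None, axes=None):
    """Recovered background rate and decayed self-effect with 2-sd bands."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 3))
    ax_s, ax_g = axes
    ax_s.plot(dec.t_grid, dec.s_mean)
    ax_s.fill_between(dec.t_grid, dec.s_mean - 2 * dec.s_sd, dec.s_mean + 2 * dec.s_sd, alpha=0.2)
    ax_g.plot(dec.lag_grid, dec.g_mean)
    ax_g.fill_between(dec.lag_grid, dec.g_mean - 2 * dec.g_sd, dec.g_mean + 2 * dec.g_sd, alpha=0.2)
    if truth is not None:
        ax_s.plot(dec.t_grid, truth.s(dec.t_grid), "k--")
        decay = truth.params.decay
        ax_g.plot(dec.lag_grid, truth.g(dec.lag_grid) * np.exp(-decay * dec.lag_grid), "k--")
    ax_s.set_xlabel("time [s]")
    ax_s.set_ylabel("s(t)")
    ax_g.set_xlabel("lag [s]")
    ax_g.set_ylabel("g~(lag)")
    return axes


def plot_ks(gof, ax=None):
    """Uniform quantile plot of rescaled values with the 95% KS band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    z = np.sort(gof.rescaled_values)
    q = (np.arange(1, z.size + 1) - 0.5) / z.size
    ax.plot(q, z)
    ax.plot([0, 1], [0, 1], "k-", lw=0.8)
    ax.plot([0, 1], [gof.ci_95_band, 1 + gof.ci_95_band], "k--", lw=0.8)
    ax.plot([0, 1], [-gof.ci_95_band, 1 - gof.ci_95_band], "k--", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("uniform quantiles")
    ax.set_ylabel("empirical quantiles")
    ax.set_title(f"KS p = {gof.p_value:.3f}")
    return ax
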