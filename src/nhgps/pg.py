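"""Pólya–Gamma utilities for the sigmoid augmentation.

The sigmoid admits the Gaussian-scale-mixture representation

    sigma(phi) = integral_0^inf exp(f(w, phi)) PG(w; 1, 0) dw,
    f(w, phi)  = -phi^2 w / 2 + phi / 2 - ln 2,

which turns sigmoid likelihood terms into terms Gaussian in phi and makes
both the Gibbs conditionals and the mean-field updates tractable.  The
variational factors over the augmentation variables are *tilted* PG(1, c)
distributions, whose first moment is available in closed form; the Gibbs
sampler needs exact PG(1, c) draws, provided here by a Devroye-type
rejection sampler (with a truncated sum-of-Gammas route kept as an
independent cross-check and portability fallback).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "log_cosh",
    "f_augment",
    "tilted_pg_mean",
    "tilted_pg_kl",
    "sample_pg",
]


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def log_cosh(x):
    """log cosh(x) without overflow for large |x|."""
    x = np.abs(np.asarray(x, dtype=float))
    return x + np.log1p(np.exp(-2.0 * x)) - np.log(2.0)


def f_augment(w, phi):
    """Augmentation integrand f(w, phi) = -phi^2 w / 2 + phi / 2 - ln 2 (w > 0)."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("PG variables are strictly positive")
    phi = np.asarray(phi, dtype=float)
    res = -(phi**2) * w / 2.0 + phi / 2.0 - np.log(2.0)
    return res if res.ndim else float(res)


def tilted_pg_mean(c):
    """First moment of PG(1, c): tanh(c/2) / (2c), with the limit 1/4 at c = 0.

    Decreasing in |c|; this is the <w> entering every augmented Gaussian update.
    """
    c = np.abs(np.asarray(c, dtype=float))
    small = c < 1e-4
    safe = np.where(small, 1.0, c)
    out = np.where(small, 0.25 - c**2 / 48.0, np.tanh(safe / 2.0) / (2.0 * safe))
    return out if out.ndim else float(out)


def tilted_pg_kl(c):
    """KL( PG(1, c) || PG(1, 0) ) = log cosh(c/2) - c^2 <w>_c / 2 (closed form)."""
    c = np.asarray(c, dtype=float)
    out = log_cosh(c / 2.0) - c**2 * tilted_pg_mean(c) / 2.0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Exact PG(1, c) sampling (Devroye-type rejection for the Jacobi J*(1, z) law)
# ---------------------------------------------------------------------------

_T = 0.64  # crossover point between the two J* proposal branches


def _norm_cdf(x):
    from scipy.special import ndtr

    return ndtr(x)


def _trunc_ig_left(z, rng):
    """Draws from IG(1/z, 1) truncated to (0, t) for mu = 1/z > t (covers z = 0).

    Rejection from the one-sided-stable-style proposal X = t/(1 + t E1)^2 with
    (E1, E2) ~ Exp(1) accepted when E1^2 <= 2 E2 / t, thinned by exp(-z^2 X / 2).
    """
    n = z.size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        e1 = rng.exponential(size=todo.size)
        e2 = rng.exponential(size=todo.size)
        ok = e1**2 <= 2.0 * e2 / _T
        x = _T / (1.0 + _T * e1) ** 2
        ok &= rng.random(todo.size) <= np.exp(-(z[todo] ** 2) * x / 2.0)
        out[todo[ok]] = x[ok]
        todo = todo[~ok]
    return out


def _trunc_ig_right(z, rng):
    """Draws from IG(mu = 1/z, 1) truncated to (0, t) for mu <= t: sample-and-retry."""
    n = z.size
    mu = 1.0 / z
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        m = mu[todo]
        nu = rng.standard_normal(todo.size)
        y = nu**2
        x = m + 0.5 * m * (m * y - np.sqrt(4.0 * m * y + (m * y) ** 2))
        flip = rng.random(todo.size) > m / (m + x)
        x[flip] = m[flip] ** 2 / x[flip]
        ok = (x > 0) & (x < _T)
        out[todo[ok]] = x[ok]
        todo = todo[~ok]
    return out


def _jstar_coef(n, x):
    """Alternating-series coefficients a_n(x) of the J*(1, 0) density."""
    out = np.empty_like(x)
    left = x <= _T
    xl = x[left]
    out[left] = (
        np.pi
        * (n + 0.5)
        * (2.0 / (np.pi * xl)) ** 1.5
        * np.exp(-2.0 * (n + 0.5) ** 2 / xl)
    )
    xr = x[~left]
    out[~left] = np.pi * (n + 0.5) * np.exp(-((n + 0.5) ** 2) * np.pi**2 * xr / 2.0)
    return out


def _sample_jstar(z, rng):
    """Vectorised Devroye rejection sampler for J*(1, z), z >= 0 elementwise."""
    z = np.asarray(z, dtype=float)
    n = z.size
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        zt = z[todo]
        k = np.pi**2 / 8.0 + zt**2 / 2.0
        p = np.pi / (2.0 * k) * np.exp(-k * _T)
        # mass of the truncated inverse-Gaussian branch on (0, t); the second
        # term is assembled in log space to avoid exp overflow at large tilts
        from scipy.special import log_ndtr

        sqt = np.sqrt(1.0 / _T)
        q = 2.0 * (
            np.exp(-zt) * _norm_cdf(sqt * (_T * zt - 1.0))
            + np.exp(zt + log_ndtr(-sqt * (_T * zt + 1.0)))
        )
        # at very large tilts both masses underflow; the IG branch then holds
        # essentially all of the proposal mass
        with np.errstate(invalid="ignore"):
            ratio = np.where(p + q > 0, p / np.where(p + q > 0, p + q, 1.0), 0.0)
        right = rng.random(todo.size) < ratio
        x = np.empty(todo.size)
        x[right] = _T + rng.exponential(size=int(right.sum())) / k[right]
        left = ~right
        if left.any():
            zl = zt[left]
            xs = np.empty(int(left.sum()))
            big_mu = zl < 1.0 / _T
            if big_mu.any():
                xs[big_mu] = _trunc_ig_left(zl[big_mu], rng)
            if (~big_mu).any():
                xs[~big_mu] = _trunc_ig_right(zl[~big_mu], rng)
            x[left] = xs
        # alternating-series squeeze acceptance
        s = _jstar_coef(0, x)
        y = rng.random(todo.size) * s
        accepted = np.zeros(todo.size, dtype=bool)
        decided = np.zeros(todo.size, dtype=bool)
        nterm = 0
        while not decided.all():
            nterm += 1
            undec = ~decided
            a = _jstar_coef(nterm, x[undec])
            if nterm % 2 == 1:
                s[undec] -= a
                newly = undec.copy()
                newly[undec] = y[undec] <= s[undec]
                accepted |= newly
                decided |= newly
            else:
                s[undec] += a
                newly = undec.copy()
                newly[undec] = y[undec] > s[undec]
                decided |= newly
        out[todo[accepted]] = x[accepted]
        todo = todo[~accepted]
    return out


def _sample_pg_gamma(c, rng, n_terms=200):
    """Truncated sum-of-Gammas representation of PG(1, c) (portability fallback).

    w = (1 / 2 pi^2) sum_k g_k / ((k - 1/2)^2 + c^2 / (4 pi^2)), g_k ~ Exp(1).
    """
    c = np.asarray(c, dtype=float)
    k = np.arange(1, n_terms + 1) - 0.5
    denom = k[None, :] ** 2 + (c[:, None] / (2.0 * np.pi)) ** 2
    g = rng.exponential(size=(c.size, n_terms))
    return (g / denom).sum(axis=1) / (2.0 * np.pi**2)


def sample_pg(c, rng, size=None, method="devroye", n_terms=200):
    """Exact draws from the Pólya–Gamma distribution PG(1, c).

    Parameters
    ----------
    c
        Tilt parameter(s), c >= 0 (the distribution depends on |c| only).
    rng
        numpy Generator.
    size
        Number of draws when ``c`` is scalar; ignored for array ``c``.
    method
        "devroye" (exact rejection sampler) or "gamma" (truncated
        sum-of-Gammas with ``n_terms`` terms).
    """
    c = np.atleast_1d(np.abs(np.asarray(c, dtype=float)))
    if size is not None:
        if c.size != 1:
            raise ValueError("size may only be given for scalar c")
        c = np.full(int(size), c[0])
    if method == "devroye":
        out = _sample_jstar(c / 2.0, rng) / 4.0
    elif method == "gamma":
        out = _sample_pg_gamma(c, rng, n_terms=n_terms)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out
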