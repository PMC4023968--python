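"""Shared response-curve and likelihood primitives.

The Gaussian logistic response curve is the core of the whole package:

    logit p_ij = a_j - (x_i - opt_j)^2 / (2 tol_j^2) + eps_i

with ``opt_j`` the niche optimum of species j, ``tol_j > 0`` its tolerance
(niche width), ``a_j`` the logit of the occurrence probability at the
optimum, and ``eps_i`` a Gaussian random site effect. Both the synthetic
generator and the MCMC sampler evaluate the curve through this module, so
the generative and inferential definitions are one and the same function.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "response_logit",
    "inv_logit",
    "logit",
    "bernoulli_loglik",
    "deviance",
    "laplace_logpdf",
]


def inv_logit(z):
    """Numerically stable inverse logit (expit)."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def logit(p):
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = np.log(p) - np.log1p(-p)
    return out if out.ndim else float(out)


def response_logit(x, opt, tol, a, eps=0.0):
    """Logit of occurrence probability on an n-site x m-species grid.

    Parameters
    ----------
    x : (n,) site scores on the (possibly latent) gradient.
    opt, tol, a : (m,) per-species niche parameters; ``tol`` strictly positive.
    eps : scalar or (n,) random site effects.

    Returns
    -------
    (n, m) array of logits.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    opt = np.atleast_1d(np.asarray(opt, dtype=float))
    tol = np.atleast_1d(np.asarray(tol, dtype=float))
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if np.any(tol <= 0):
        raise ValueError("tolerance must be strictly positive")
    d = x[:, None] - opt[None, :]
    lin = a[None, :] - d * d / (2.0 * tol[None, :] ** 2)
    eps = np.asarray(eps, dtype=float)
    if eps.ndim == 0:
        return lin + float(eps)
    return lin + eps[:, None]


def bernoulli_loglik(y, logits):
    """Elementwise Bernoulli log-likelihood given logits.

    log p(y | l) = y*l - log(1 + e^l), computed stably.
    """
    y = np.asarray(y, dtype=float)
    logits = np.asarray(logits, dtype=float)
    return y * logits - np.logaddexp(0.0, logits)


def deviance(y, logits):
    """Model deviance -2 * sum log Bernoulli(y | p)."""
    return -2.0 * float(np.sum(bernoulli_loglik(y, logits)))


def laplace_logpdf(b, rate):
    """Log density of the double-exponential (Laplace) slab,
    (rate/2) * exp(-rate*|b|)."""
    return np.log(rate / 2.0) - rate * np.abs(b)
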