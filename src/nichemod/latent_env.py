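"""Latent environmental gradient: a sparse linear combination of the
measured environmental variables, estimated jointly with the niche model.

Instead of one measured gradient, the site score becomes

    x_i = sum_l c_l * e_il,    sum_l c_l^2 = 1,

with the same spike-and-slab machinery selecting which environmental
variables enter. The quadratic response (x - opt)^2 / (2 tol^2) is
invariant to jointly rescaling the weights, optima, and tolerances, so the
raw scale is unidentified; identifiability is restored by unit Euclidean
norm on the weights and a sign convention: the weight of a user-named
anchor variable (by default the first, falling back to the first non-zero
weight) is kept non-negative on every draw, so chains cannot mix over the
sign flip and summaries are free of label-switching artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import EnvTable, OccurrenceMatrix, TraitTable
from .glm_init import InitBundle, initial_values
from .inference import McmcOptions, PosteriorDraws, fit, _normalize

__all__ = ["LatentWeights", "latent_scores", "initial_weights", "fit_latent"]


@dataclass(frozen=True)
class LatentWeights:
    """Unit-norm weights of the latent gradient with inclusion indicators."""

    weights: np.ndarray   # (L,), sum of squares 1
    indicators: np.ndarray  # (L,) in {0, 1}
    var_names: tuple = None
    anchor: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        g = np.asarray(self.indicators, dtype=int)
        if w.shape != g.shape:
            raise ValueError("weights and indicators must have equal length")
        if np.any((g == 0) & (w != 0)):
            raise ValueError("excluded variables must have weight exactly 0")
        nrm = float(np.linalg.norm(w))
        if nrm == 0:
            raise ValueError("weights are all zero")
        if abs(nrm - 1.0) > 1e-8:
            w = w / nrm
        ref = w[self.anchor]
        if ref == 0:
            nz = np.nonzero(w)[0]
            ref = w[nz[0]]
        if ref < 0:
            w = -w
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "indicators", g)


def latent_scores(env: EnvTable, w) -> np.ndarray:
    """Site scores x_i = sum_l c_l e_il on the standardized environment."""
    values = env.values if isinstance(env, EnvTable) else np.asarray(env)
    c = w.weights if isinstance(w, LatentWeights) else _normalize(
        np.asarray(w, dtype=float))
    if values.shape[1] != c.shape[0]:
        raise ValueError("weight length must match number of environmental "
                         "variables")
    return values @ c


def initial_weights(occ: OccurrenceMatrix, env: EnvTable,
                    anchor: int = 0) -> np.ndarray:
    """Data-driven starting direction for the latent gradient.

    Species niche centroids (presence-weighted mean environment per
    species) are computed on the standardized environment table; the first
    principal axis of the centroid cloud is the direction along which
    species optima are most spread out, which is exactly what the latent
    gradient must capture.
    """
    y = np.asarray(occ.values, dtype=float)
    totals = y.sum(axis=0)
    totals = np.where(totals > 0, totals, 1.0)
    centroids = (y.T @ env.values) / totals[:, None]   # (m, L)
    centroids = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids, full_matrices=False)
    w = vt[0]
    ref = w[anchor] if w[anchor] != 0 else w[np.nonzero(w)[0][0]]
    if ref < 0:
        w = -w
    return _normalize(w)


def fit_latent(occ: OccurrenceMatrix, env: EnvTable,
               traits: TraitTable = None, opts: McmcOptions = None,
               inits: InitBundle = None,
               init_weights: np.ndarray = None) -> PosteriorDraws:
    """Joint MCMC over latent weights and all niche-model parameters.

    With a single environmental variable this reduces (up to the sign
    convention) to :func:`nichemod.inference.fit` on that variable. Default
    iteration counts should be raised relative to the single-gradient fit:
    the joint posterior over weights mixes slowly.
    """
    opts = opts or McmcOptions(n_iter=100000)
    if init_weights is None:
        init_weights = initial_weights(occ, env, anchor=opts.anchor)
    init_weights = np.asarray(init_weights, dtype=float)
    if inits is None:
        x0 = latent_scores(env, init_weights)
        inits = initial_values(occ, x0, traits)
    return fit(occ, None, traits, opts, inits,
               _env=np.asarray(env.values, dtype=float),
               _weights=init_weights)


def posterior_weights(draws: PosteriorDraws) -> LatentWeights:
    """Posterior-mean latent weights, renormalized, with majority-vote
    indicators."""
    if draws.mode != "latent":
        raise ValueError("not a latent-gradient fit")
    w = draws.stacked("weights").mean(axis=0)
    g = (draws.stacked("gamma_env").mean(axis=0) >= 0.5).astype(int)
    w = np.where(g == 1, w, 0.0)
    if not np.any(w != 0):
        # degenerate: no variable selected in the majority vote
        w = draws.stacked("weights").mean(axis=0)
        g = (w != 0).astype(int)
    return LatentWeights(w, g, anchor=draws.options.anchor)
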