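"""Posterior inference for the trait-modulated Gaussian logistic model.

Model
-----
Occurrences are Bernoulli with

    logit p_ij = a_j - (x_i - opt_j)^2 / (2 tol_j^2) + eps_i,
    eps_i ~ N(0, sigma2_site),

and each niche parameter is linearly modulated by the K species traits:

    opt_j     = mu_opt + sum_k beta_opt_k z_jk + e_j,   e_j ~ N(0, sigma2_opt)
    log tol_j = mu_tol + sum_k beta_tol_k z_jk + f_j,   f_j ~ N(0, sigma2_tol)
    a_j       = mu_a   + sum_k beta_a_k   z_jk + g_j,   g_j ~ N(0, sigma2_a)

The tolerance submodel acts on log tol by default so that tolerances stay
positive; ``tol_scale='identity'`` gives the literal linear submodel with
rejection of non-positive tolerances (a fidelity-check mode whose intercept
and variance updates ignore the truncation constant).

Priors: uniform on intercepts and on standard deviations; for the trait
slopes either the spike-and-slab mixture

    beta ~ (1 - gamma) * delta_0 + gamma * DoubleExp(lambda),
    gamma ~ Bernoulli(0.5),  lambda ~ Gamma(a0, b0)

with exact zeros when gamma = 0, or a plain Normal(0, sigma2_beta) slab
with sigma_beta uniform (the "normal prior" comparison mode).

Sampler
-------
Bespoke random-walk-within-Gibbs. Species niche parameters and site
effects are updated by vectorized random-walk Metropolis (tolerance on the
log scale); intercepts, residual variances, the slab rate, and the
(gamma, beta) pairs are updated by exact conditional draws — the
(gamma, beta) move integrates the double-exponential slab against the
Gaussian likelihood in closed form, so indicators are drawn from their
exact conditional and excluded slopes are exactly zero in every draw.
Proposal scales adapt during burn-in only and are frozen afterwards.

In latent mode the gradient is x = E c with unit-norm sparse weights c on
the standardized environment table; weights carry the same mixture prior
(applied pre-normalization) with their own slab rate, and the sign gauge is
fixed on every draw by making an anchor variable's weight non-negative.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

from .data_io import OccurrenceMatrix, TraitTable
from .glm_init import InitBundle, initial_values
from .model import bernoulli_loglik, laplace_logpdf, response_logit

__all__ = ["McmcOptions", "ModelState", "PosteriorDraws", "log_joint",
           "fit", "fit_without_traits"]

_SPECIES_BLOCKS = ("opt", "tol", "a")


@dataclass(frozen=True)
class McmcOptions:
    """Sampler configuration.

    ``fix`` names parameter blocks to hold at their initial values (useful
    for validation studies and reduced models); ``tol_scale`` selects the
    log-scale tolerance submodel (default) or the literal linear one.
    """

    n_iter: int = 10000
    burn_in: int = None  # defaults to n_iter // 2
    n_chains: int = 3
    thin: int = 1
    seed: int = 0
    prior: str = "spike_slab"  # or "normal"
    slab_hyper: tuple = (1.0, 1.0)  # Gamma(a0, b0) hyperprior on lambda
    fixed_lambda: float = None
    intercept_bound: float = 100.0
    sd_bound: float = 100.0
    tol_scale: str = "log"  # or "identity"
    fix: frozenset = frozenset()
    anchor: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.3
    jitter: float = 0.05

    def __post_init__(self):
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", self.n_iter // 2)
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.prior not in ("spike_slab", "normal"):
            raise ValueError("prior must be 'spike_slab' or 'normal'")
        if self.tol_scale not in ("log", "identity"):
            raise ValueError("tol_scale must be 'log' or 'identity'")
        object.__setattr__(self, "fix", frozenset(self.fix))


@dataclass
class ModelState:
    """One full parameter state of the model."""

    opt: np.ndarray          # (m,)
    tolp: np.ndarray         # (m,) log tol (log mode) or tol (identity mode)
    a: np.ndarray            # (m,)
    eps: np.ndarray          # (n,)
    mu: np.ndarray           # (3,) intercepts for (opt, tol-submodel, a)
    beta: np.ndarray         # (3, K)
    gamma: np.ndarray        # (3, K) in {0, 1}
    sigma2: np.ndarray       # (3,) submodel residual variances
    sigma2_site: float
    lam: float = 1.0
    sigma2_beta: np.ndarray = None   # (3,) normal-prior mode only
    weights: np.ndarray = None       # (L,) raw latent weights
    gamma_env: np.ndarray = None     # (L,)
    lam_env: float = 1.0

    def tol(self, opts: McmcOptions) -> np.ndarray:
        return np.exp(self.tolp) if opts.tol_scale == "log" else self.tolp

    def copy(self) -> "ModelState":
        return ModelState(
            self.opt.copy(), self.tolp.copy(), self.a.copy(), self.eps.copy(),
            self.mu.copy(), self.beta.copy(), self.gamma.copy(),
            self.sigma2.copy(), float(self.sigma2_site), float(self.lam),
            None if self.sigma2_beta is None else self.sigma2_beta.copy(),
            None if self.weights is None else self.weights.copy(),
            None if self.gamma_env is None else self.gamma_env.copy(),
            float(self.lam_env))


@dataclass
class PosteriorDraws:
    """Kept MCMC draws, one leading axis per chain, plus metadata.

    ``draws[name]`` has shape (n_chains, n_kept, ...). The data the model
    was fitted to is retained so diagnostics can recompute deviances, and a
    fingerprint guards against comparing fits on different data.
    """

    draws: dict
    options: McmcOptions
    inits: InitBundle
    acceptance: dict
    data: dict
    fingerprint: str
    mode: str = "single"  # or "latent"

    @property
    def n_chains(self) -> int:
        return self.draws["deviance"].shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws["deviance"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains concatenated."""
        d = self.draws[name]
        return d.reshape(d.shape[0] * d.shape[1], *d.shape[2:])

    def summary(self):
        """Posterior summary table (mean, sd, median, 2.5/97.5%)."""
        import pandas as pd

        rows = []
        for name, arr in self.draws.items():
            if arr.size == 0:
                continue
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            for idx in range(flat.shape[1]):
                col = flat[:, idx]
                label = name if flat.shape[1] == 1 else f"{name}[{idx}]"
                rows.append({
                    "parameter": label,
                    "mean": float(np.mean(col)),
                    "sd": float(np.std(col, ddof=1)),
                    "median": float(np.median(col)),
                    "q2.5": float(np.percentile(col, 2.5)),
                    "q97.5": float(np.percentile(col, 97.5)),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# helpers


def _fingerprint(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if a is None:
            h.update(b"none")
        else:
            h.update(np.ascontiguousarray(np.asarray(a, dtype=float)).tobytes())
    return h.hexdigest()


def _normalize(w: np.ndarray) -> np.ndarray:
    nrm = float(np.linalg.norm(w))
    if nrm == 0:
        raise ValueError("latent weights are all zero")
    return w / nrm


def _scores(env: np.ndarray, w: np.ndarray) -> np.ndarray:
    return env @ _normalize(w)


def _one_sided_std(rng, a):
    """Standard normal truncated to (a, inf), robust far into the tail."""
    if a < 5.0:
        fa = special.ndtr(a)
        u = rng.uniform()
        z = special.ndtri(fa + u * (1.0 - fa))
    else:
        # work with the accurate upper-tail probability
        qa = special.ndtr(-a)
        u = rng.uniform()
        z = -special.ndtri(max(u * qa, 5e-324))
    return float(np.clip(z, a, a + 40.0))


def _trunc_norm(rng, loc, scale, lo, hi):
    """Normal(loc, scale) truncated to (lo, hi) by inverse-CDF sampling."""
    a = -np.inf if lo == -np.inf else (lo - loc) / scale
    b = np.inf if hi == np.inf else (hi - loc) / scale
    if a == -np.inf and b == np.inf:
        z = rng.standard_normal()
    elif b == np.inf:
        z = _one_sided_std(rng, a)
    elif a == -np.inf:
        z = -_one_sided_std(rng, -b)
    else:
        fa, fb = special.ndtr(a), special.ndtr(b)
        if fb - fa > 1e-12:
            z = float(np.clip(special.ndtri(fa + rng.uniform() * (fb - fa)),
                              a, b))
        elif a > 0:  # both bounds deep in the upper tail
            qa, qb = special.ndtr(-a), special.ndtr(-b)
            z = float(np.clip(-special.ndtri(qb + rng.uniform() * (qa - qb)),
                              a, b))
        else:        # both deep in the lower tail
            fa2, fb2 = special.ndtr(a), special.ndtr(b)
            z = float(np.clip(special.ndtri(
                max(fa2 + rng.uniform() * (fb2 - fa2), 5e-324)), a, b))
    return loc + scale * z


def _trunc_invgamma(rng, shape, ss, sd_bound):
    """Draw tau from p(tau) ∝ tau^{-(shape+1)} exp(-ss/(2 tau)) truncated to
    sqrt(tau) < sd_bound, via the precision parameterization."""
    ss = max(ss, 1e-300)
    rate = ss / 2.0
    lo_prec = 1.0 / sd_bound ** 2
    cdf_lo = float(special.gammainc(shape, lo_prec * rate))
    if cdf_lo < 1e-8:
        # truncation point carries negligible mass: plain draw, rare retry
        for _ in range(100):
            prec = rng.gamma(shape) / rate
            if prec >= lo_prec:
                return 1.0 / prec
        return 1.0 / lo_prec
    u = rng.uniform(cdf_lo, 1.0)
    u = min(max(u, 1e-15), 1.0 - 1e-16)
    prec = float(special.gammaincinv(shape, u)) / rate
    return 1.0 / max(prec, lo_prec)


# ---------------------------------------------------------------------------
# joint density


def log_joint(state: ModelState, data: dict, opts: McmcOptions) -> float:
    """Log joint density (likelihood + all priors) of a full state.

    Returns -inf for states outside the support (non-positive tolerances,
    parameters beyond the uniform bounds, non-zero slopes with a zero
    indicator).
    """
    y = data["y"]
    Z = data.get("Z")
    if data.get("env") is not None:
        if state.weights is None:
            raise ValueError("latent data requires weights in the state")
        x = _scores(data["env"], state.weights)
    else:
        x = data["x"]
    tol = state.tol(opts)
    if np.any(tol <= 0):
        return -np.inf
    B, Bs = opts.intercept_bound, opts.sd_bound
    if np.any(np.abs(state.mu) >= B):
        return -np.inf
    sds = np.sqrt(np.concatenate([state.sigma2, [state.sigma2_site]]))
    if np.any(sds >= Bs) or np.any(sds <= 0):
        return -np.inf

    lp = float(np.sum(bernoulli_loglik(
        y, response_logit(x, state.opt, tol, state.a, state.eps))))

    # species-level Gaussians around their trait-linear means
    K = 0 if Z is None else Z.shape[1]
    pred = (np.zeros((3, len(state.opt))) if K == 0
            else state.mu[:, None] + state.beta @ Z.T)
    if K == 0:
        pred = pred + state.mu[:, None]
    for t, th in enumerate((state.opt, state.tolp, state.a)):
        lp += float(np.sum(stats.norm.logpdf(
            th, pred[t], np.sqrt(state.sigma2[t]))))
    lp += float(np.sum(stats.norm.logpdf(
        state.eps, 0.0, np.sqrt(state.sigma2_site))))

    # uniform hyperpriors: intercepts on (-B, B), sds on (0, Bs); the sd
    # prior is expressed on the variance scale with its Jacobian
    lp += -3.0 * np.log(2 * B)
    lp += float(np.sum(-np.log(Bs) - np.log(2.0 * sds)))

    # slopes
    if K > 0:
        if opts.prior == "spike_slab":
            lp += 3 * K * np.log(0.5)  # Bernoulli(0.5) indicators
            on = state.gamma == 1
            if np.any(state.beta[~on] != 0):
                return -np.inf
            lp += float(np.sum(laplace_logpdf(state.beta[on], state.lam)))
            a0, b0 = opts.slab_hyper
            if opts.fixed_lambda is None:
                lp += float(stats.gamma.logpdf(state.lam, a0, scale=1.0 / b0))
        else:
            sb = np.sqrt(state.sigma2_beta)
            if np.any(sb >= Bs) or np.any(sb <= 0):
                return -np.inf
            for t in range(3):
                lp += float(np.sum(stats.norm.logpdf(
                    state.beta[t], 0.0, sb[t])))
            lp += float(np.sum(-np.log(Bs) - np.log(2.0 * sb)))

    # latent weights
    if state.weights is not None:
        L = len(state.weights)
        lp += L * np.log(0.5)
        on = state.gamma_env == 1
        if np.any(state.weights[~on] != 0) or not np.any(on):
            return -np.inf
        lp += float(np.sum(laplace_logpdf(state.weights[on], state.lam_env)))
        a0, b0 = opts.slab_hyper
        lp += float(stats.gamma.logpdf(state.lam_env, a0, scale=1.0 / b0))
    return lp


# ---------------------------------------------------------------------------
# sampler internals


class _Chain:
    def __init__(self, y, x, env, Z, state: ModelState, opts: McmcOptions,
                 rng: np.random.Generator):
        self.y = y
        self.env = env
        self.Z = Z
        self.opts = opts
        self.rng = rng
        self.state = state
        self.n, self.m = y.shape
        self.K = 0 if Z is None else Z.shape[1]
        if env is not None:
            x = _scores(env, state.weights)
        self.x = x
        self.scales = {"opt": 0.5, "tol": 0.3, "a": 0.5, "eps": 0.3, "w": 0.3}
        self.acc = {k: [0, 0] for k in
                    ("opt", "tol", "a", "eps", "w", "w_flip")}
        self._refresh_loglik()

    # -- likelihood bookkeeping -------------------------------------------

    def _refresh_loglik(self):
        s = self.state
        self.logit = response_logit(self.x, s.opt, s.tol(self.opts), s.a,
                                    s.eps)
        self.ll = bernoulli_loglik(self.y, self.logit)

    def total_ll(self) -> float:
        return float(self.ll.sum())

    def deviance(self) -> float:
        return -2.0 * self.total_ll()

    # -- conditional pieces ------------------------------------------------

    def _theta(self, t: int) -> np.ndarray:
        return (self.state.opt, self.state.tolp, self.state.a)[t]

    def _pred(self, t: int) -> np.ndarray:
        s = self.state
        if self.K == 0:
            return np.full(self.m, s.mu[t])
        return s.mu[t] + self.Z @ s.beta[t]

    # -- species-level random-walk updates --------------------------------

    def update_species(self, which: str):
        s, opts, rng = self.state, self.opts, self.rng
        t = _SPECIES_BLOCKS.index(which)
        cur = self._theta(t)
        prop = cur + self.scales[which] * rng.standard_normal(self.m)
        if which == "tol" and opts.tol_scale == "identity":
            valid = prop > 0
        else:
            valid = np.ones(self.m, dtype=bool)
        # proposed niche parameter vectors
        opt = s.opt if which != "opt" else prop
        tolp = s.tolp if which != "tol" else prop
        a = s.a if which != "a" else prop
        tol = np.exp(tolp) if opts.tol_scale == "log" else tolp
        tol_safe = np.where(tol > 0, tol, 1.0)
        new_logit = response_logit(self.x, opt, tol_safe, a, s.eps)
        new_ll = bernoulli_loglik(self.y, new_logit)
        d_ll = new_ll.sum(axis=0) - self.ll.sum(axis=0)
        pred = self._pred(t)
        d_prior = ((cur - pred) ** 2 - (prop - pred) ** 2) / (2 * s.sigma2[t])
        log_r = np.where(valid, d_ll + d_prior, -np.inf)
        accept = np.log(rng.uniform(size=self.m)) < log_r
        if accept.any():
            cur[accept] = prop[accept]
            self.logit[:, accept] = new_logit[:, accept]
            self.ll[:, accept] = new_ll[:, accept]
        self.acc[which][0] += int(accept.sum())
        self.acc[which][1] += self.m

    def update_eps(self):
        s, rng = self.state, self.rng
        delta = self.scales["eps"] * rng.standard_normal(self.n)
        prop = s.eps + delta
        new_logit = self.logit + delta[:, None]
        new_ll = bernoulli_loglik(self.y, new_logit)
        d_ll = new_ll.sum(axis=1) - self.ll.sum(axis=1)
        d_prior = (s.eps ** 2 - prop ** 2) / (2 * s.sigma2_site)
        accept = np.log(rng.uniform(size=self.n)) < d_ll + d_prior
        if accept.any():
            s.eps[accept] = prop[accept]
            self.logit[accept] = new_logit[accept]
            self.ll[accept] = new_ll[accept]
        self.acc["eps"][0] += int(accept.sum())
        self.acc["eps"][1] += self.n

    # -- submodel (hyper)parameter updates --------------------------------

    def update_mu(self):
        s, opts, rng = self.state, self.opts, self.rng
        B = opts.intercept_bound
        for t in range(3):
            resid = self._theta(t) if self.K == 0 else \
                self._theta(t) - self.Z @ s.beta[t]
            loc = float(np.mean(resid))
            scale = float(np.sqrt(s.sigma2[t] / self.m))
            s.mu[t] = _trunc_norm(rng, loc, scale, -B, B)

    def update_slopes(self):
        if self.K == 0:
            return
        if self.opts.prior == "spike_slab":
            self._update_slopes_ss()
        else:
            self._update_slopes_normal()

    def _update_slopes_ss(self):
        """Exact conditional (gamma, beta) draw per coefficient.

        Integrating the double-exponential slab against the Gaussian
        residual likelihood gives the marginal inclusion odds in closed
        form; given inclusion, beta is a two-piece truncated normal.
        """
        s, rng = self.state, self.rng
        for t in range(3):
            th = self._theta(t)
            sig2 = float(s.sigma2[t])
            lam = float(s.lam)
            for k in range(self.K):
                z = self.Z[:, k]
                r = th - s.mu[t] - self.Z @ s.beta[t] + z * s.beta[t, k]
                S = float(z @ z)
                T = float(r @ z)
                bhat = T / S
                v = sig2 / S
                sd = np.sqrt(v)
                base = (np.log(lam / 2) + 0.5 * np.log(2 * np.pi * v)
                        + bhat ** 2 / (2 * v) + lam ** 2 * v / 2)
                wp = base - lam * bhat + special.log_ndtr((bhat - lam * v) / sd)
                wm = base + lam * bhat + special.log_ndtr(-(bhat + lam * v) / sd)
                log_bf = np.logaddexp(wp, wm)
                p1 = special.expit(log_bf)  # Bernoulli(0.5) prior on gamma
                if rng.uniform() < p1:
                    s.gamma[t, k] = 1
                    if np.log(rng.uniform()) < wp - log_bf:
                        s.beta[t, k] = _trunc_norm(rng, bhat - lam * v, sd,
                                                   0.0, np.inf)
                    else:
                        s.beta[t, k] = _trunc_norm(rng, bhat + lam * v, sd,
                                                   -np.inf, 0.0)
                else:
                    s.gamma[t, k] = 0
                    s.beta[t, k] = 0.0

    def _update_slopes_normal(self):
        s, rng = self.state, self.rng
        for t in range(3):
            th = self._theta(t)
            sig2 = float(s.sigma2[t])
            for k in range(self.K):
                z = self.Z[:, k]
                r = th - s.mu[t] - self.Z @ s.beta[t] + z * s.beta[t, k]
                S = float(z @ z)
                T = float(r @ z)
                v = 1.0 / (S / sig2 + 1.0 / s.sigma2_beta[t])
                loc = v * T / sig2
                s.beta[t, k] = loc + np.sqrt(v) * rng.standard_normal()
            s.gamma[t] = 1
        # sigma2_beta: random-walk MH on the log scale against the exact
        # conditional (uniform prior on sigma_beta)
        Bs = self.opts.sd_bound
        for t in range(3):
            ss_beta = float(np.sum(s.beta[t] ** 2))
            cur = float(s.sigma2_beta[t])
            prop = float(np.exp(np.log(cur) + 0.5 * rng.standard_normal()))
            if np.sqrt(prop) >= Bs:
                continue

            def _logp(tau):
                # K Gaussian slopes + uniform-on-sd prior + log-scale Jacobian
                return (-0.5 * self.K * np.log(tau) - ss_beta / (2 * tau)
                        - 0.5 * np.log(tau) + np.log(tau))

            if np.log(rng.uniform()) < _logp(prop) - _logp(cur):
                s.sigma2_beta[t] = prop

    def update_variances(self):
        s, opts, rng = self.state, self.opts, self.rng
        for t in range(3):
            resid = self._theta(t) - self._pred(t)
            ss = float(resid @ resid)
            s.sigma2[t] = _trunc_invgamma(rng, (self.m - 1) / 2.0, ss,
                                          opts.sd_bound)

    def update_site_variance(self):
        s = self.state
        ss = float(s.eps @ s.eps)
        s.sigma2_site = _trunc_invgamma(self.rng, (self.n - 1) / 2.0, ss,
                                        self.opts.sd_bound)

    def update_lambda(self):
        s, opts, rng = self.state, self.opts, self.rng
        if opts.fixed_lambda is not None:
            return
        a0, b0 = opts.slab_hyper
        on = s.gamma == 1
        n_on = int(on.sum())
        s.lam = float(rng.gamma(a0 + n_on,
                                1.0 / (b0 + float(np.sum(np.abs(s.beta[on]))))))

    # -- latent weight updates --------------------------------------------

    def update_weights(self):
        s, rng = self.state, self.rng
        L = len(s.weights)
        lam = float(s.lam_env)
        cur_total = self.total_ll()
        for ell in range(L):
            # random-walk move on active weights
            if s.gamma_env[ell] == 1:
                prop = s.weights.copy()
                prop[ell] += self.scales["w"] * rng.standard_normal()
                ok, new_total, new_logit, new_ll = self._try_weights(prop)
                if ok:
                    d_prior = lam * (abs(s.weights[ell]) - abs(prop[ell]))
                    if np.log(rng.uniform()) < new_total - cur_total + d_prior:
                        s.weights = prop
                        self._commit_weights(new_logit, new_ll)
                        cur_total = new_total
                        self.acc["w"][0] += 1
                self.acc["w"][1] += 1
            # add/delete move; the slab doubles as the proposal so the
            # acceptance ratio reduces to the likelihood ratio
            prop = s.weights.copy()
            if s.gamma_env[ell] == 1:
                prop[ell] = 0.0
                new_gamma = 0
            else:
                prop[ell] = float(rng.laplace(0.0, 1.0 / lam))
                new_gamma = 1
            if np.any(prop != 0):
                ok, new_total, new_logit, new_ll = self._try_weights(prop)
                if ok and np.log(rng.uniform()) < new_total - cur_total:
                    s.weights = prop
                    s.gamma_env[ell] = new_gamma
                    self._commit_weights(new_logit, new_ll)
                    cur_total = new_total
                    self.acc["w_flip"][0] += 1
            self.acc["w_flip"][1] += 1
        # slab rate for the weights
        a0, b0 = self.opts.slab_hyper
        on = s.gamma_env == 1
        s.lam_env = float(rng.gamma(
            a0 + int(on.sum()),
            1.0 / (b0 + float(np.sum(np.abs(s.weights[on]))))))
        self._enforce_gauge()

    def _try_weights(self, w):
        if not np.any(w != 0):
            return False, None, None, None
        s = self.state
        x = _scores(self.env, w)
        logit = response_logit(x, s.opt, s.tol(self.opts), s.a, s.eps)
        ll = bernoulli_loglik(self.y, logit)
        return True, float(ll.sum()), logit, ll

    def _commit_weights(self, logit, ll):
        self.x = _scores(self.env, self.state.weights)
        self.logit = logit
        self.ll = ll

    def _enforce_gauge(self):
        """Fix the sign gauge: the anchor variable's weight (or the first
        non-zero weight if the anchor is excluded) must be non-negative."""
        s = self.state
        w = s.weights
        ref = w[self.opts.anchor]
        if ref == 0:
            nz = np.nonzero(w)[0]
            ref = w[nz[0]] if nz.size else 1.0
        if ref < 0:
            s.weights = -s.weights
            s.opt = -s.opt
            s.mu[0] = -s.mu[0]
            s.beta[0] = -s.beta[0]
            self.x = -self.x
            # likelihood is invariant under this joint flip

    # -- adaptation --------------------------------------------------------

    def adapt(self):
        for key in ("opt", "tol", "a", "eps", "w"):
            accepted, tried = self.acc.get(key, (0, 0))
            if tried == 0:
                continue
            rate = accepted / tried
            self.scales[key] = float(np.clip(
                self.scales[key] * np.exp(0.8 * (rate - self.opts.target_accept)),
                1e-4, 50.0))
            self.acc[key] = [0, 0]


def _init_state(inits: InitBundle, opts: McmcOptions, K: int,
                weights=None) -> ModelState:
    tolp = np.log(inits.tol) if opts.tol_scale == "log" else inits.tol.copy()
    beta = np.asarray(inits.beta, dtype=float).reshape(3, -1)[:, :K] \
        if K > 0 else np.zeros((3, 0))
    if beta.shape[1] != K:
        beta = np.zeros((3, K))
    state = ModelState(
        opt=np.asarray(inits.opt, dtype=float).copy(),
        tolp=tolp,
        a=np.asarray(inits.a, dtype=float).copy(),
        eps=np.asarray(inits.eps, dtype=float).copy(),
        mu=np.asarray(inits.mu, dtype=float).copy(),
        beta=beta.copy(),
        gamma=np.ones((3, K), dtype=int),
        sigma2=np.asarray(inits.sigma2, dtype=float).copy(),
        sigma2_site=float(inits.sigma2_site),
        lam=opts.fixed_lambda if opts.fixed_lambda is not None else 1.0,
        sigma2_beta=np.ones(3) if opts.prior == "normal" else None,
    )
    if weights is not None:
        w = np.asarray(weights, dtype=float).copy()
        state.weights = w
        state.gamma_env = (w != 0).astype(int)
    return state


def _run_chain(y, x, env, Z, inits, opts, rng, chain_index, weights=None):
    state = _init_state(inits, opts, 0 if Z is None else Z.shape[1], weights)
    if chain_index > 0 and opts.jitter > 0:
        # over-dispersed starts for later chains
        state.opt = state.opt + opts.jitter * rng.standard_normal(len(state.opt))
        state.a = state.a + opts.jitter * rng.standard_normal(len(state.a))
        state.tolp = state.tolp + opts.jitter * rng.standard_normal(len(state.tolp))
    ch = _Chain(y, x, env, Z, state, opts, rng)
    fix = opts.fix
    kept = []
    n_kept = (opts.n_iter - opts.burn_in) // opts.thin
    rec = {name: [] for name in
           ("opt", "tol", "a", "eps", "mu", "beta", "gamma", "sigma2",
            "sigma2_site", "lam", "deviance")}
    if opts.prior == "normal":
        rec["sigma2_beta"] = []
    if env is not None:
        rec["weights"] = []
        rec["gamma_env"] = []
        rec["lam_env"] = []
    for it in range(opts.n_iter):
        if "opt" not in fix:
            ch.update_species("opt")
        if "tol" not in fix:
            ch.update_species("tol")
        if "a" not in fix:
            ch.update_species("a")
        if "eps" not in fix:
            ch.update_eps()
        if "mu" not in fix:
            ch.update_mu()
        if "beta" not in fix:
            ch.update_slopes()
        if "sigma2" not in fix:
            ch.update_variances()
        if "sigma2_site" not in fix:
            ch.update_site_variance()
        if "lam" not in fix and opts.prior == "spike_slab" and ch.K > 0:
            ch.update_lambda()
        if env is not None and "weights" not in fix:
            ch.update_weights()
        if it < opts.burn_in and (it + 1) % opts.adapt_interval == 0:
            ch.adapt()
        if (it + 1) % 500 == 0:
            ch._refresh_loglik()  # cap incremental round-off drift
        if it >= opts.burn_in and (it - opts.burn_in) % opts.thin == 0:
            s = ch.state
            dev = ch.deviance()
            if not np.isfinite(dev):
                raise FloatingPointError(
                    f"non-finite deviance at iteration {it}")
            rec["opt"].append(s.opt.copy())
            rec["tol"].append(s.tol(opts).copy())
            rec["a"].append(s.a.copy())
            rec["eps"].append(s.eps.copy())
            rec["mu"].append(s.mu.copy())
            rec["beta"].append(s.beta.copy())
            rec["gamma"].append(s.gamma.copy())
            rec["sigma2"].append(s.sigma2.copy())
            rec["sigma2_site"].append(s.sigma2_site)
            rec["lam"].append(s.lam)
            rec["deviance"].append(dev)
            if opts.prior == "normal":
                rec["sigma2_beta"].append(s.sigma2_beta.copy())
            if env is not None:
                rec["weights"].append(_normalize(s.weights)
                                      if np.any(s.weights != 0)
                                      else s.weights.copy())
                rec["gamma_env"].append(s.gamma_env.copy())
                rec["lam_env"].append(s.lam_env)
    out = {name: np.asarray(vals) for name, vals in rec.items()}
    acc_rates = {k: (v[0] / v[1] if v[1] else np.nan)
                 for k, v in ch.acc.items()}
    return out, acc_rates


def _prepare(occ: OccurrenceMatrix, traits):
    y = np.asarray(occ.values, dtype=float)
    if traits is None:
        return y, None
    Z = np.asarray(traits.values, dtype=float)
    if Z.shape[0] != y.shape[1]:
        raise ValueError("trait table rows must match occurrence columns")
    return y, (Z if Z.shape[1] > 0 else None)


def fit(occ: OccurrenceMatrix, x, traits: TraitTable = None,
        opts: McmcOptions = None, inits: InitBundle = None,
        _env=None, _weights=None) -> PosteriorDraws:
    """Run the MCMC on a single measured gradient ``x``.

    ``traits=None`` (or a zero-column trait table) fits the no-traits
    reference model. Identical seeds and inputs give bit-identical draws.
    """
    opts = opts or McmcOptions()
    y, Z = _prepare(occ, traits)
    x = None if x is None else np.asarray(x, dtype=float)
    if inits is None:
        base_x = x if _env is None else _scores(_env, _weights)
        inits = initial_values(occ, base_x, traits)
    ss = np.random.SeedSequence(opts.seed)
    chains = [np.random.default_rng(s) for s in ss.spawn(opts.n_chains)]
    all_draws, all_acc = [], []
    for c, rng in enumerate(chains):
        draws, acc = _run_chain(y, x, _env, Z, inits, opts, rng, c,
                                weights=_weights)
        all_draws.append(draws)
        all_acc.append(acc)
    stacked = {name: np.stack([d[name] for d in all_draws])
               for name in all_draws[0]}
    data = {"y": y, "x": x, "Z": Z}
    mode = "single"
    if _env is not None:
        data["env"] = _env
        mode = "latent"
    fp = _fingerprint(y, x if _env is None else _env, Z)
    return PosteriorDraws(draws=stacked, options=opts, inits=inits,
                          acceptance={"per_chain": all_acc}, data=data,
                          fingerprint=fp, mode=mode)


def fit_without_traits(occ: OccurrenceMatrix, x, opts: McmcOptions = None,
                       inits: InitBundle = None) -> PosteriorDraws:
    """The no-traits reference model (all slopes structurally zero)."""
    return fit(occ, x, None, opts, inits)
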