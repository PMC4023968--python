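"""Synthetic presence-absence communities from the generative niche model.

Data are drawn from exactly the model the sampler fits: traits (standard
normal continuous columns, Bernoulli binary columns, both standardized like
the real pipeline), niche parameters from the linear trait submodels with
Gaussian residuals (tolerance generated on the log scale, matching the
inference parameterization), Gaussian site effects, and occurrences from
Bernoulli trials on the Gaussian logistic curve. The response curve is
evaluated through :mod:`nichemod.model`, the same code path the sampler
uses, so the generative and inferential models cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import EnvTable, OccurrenceMatrix, TraitTable
from .inference import _normalize
from .model import inv_logit, response_logit

__all__ = ["SyntheticConfig", "SyntheticTruth", "simulate_community",
           "case_study_preset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings; the seed is mandatory."""

    n: int = 200
    m: int = 30
    k_continuous: int = 2
    k_binary: int = 2
    mu_opt: float = 0.0
    mu_log_tol: float = 0.0
    mu_a: float = 0.5
    beta_opt: tuple = ()
    beta_log_tol: tuple = ()
    beta_a: tuple = ()
    sigma_opt: float = 0.5
    sigma_log_tol: float = 0.2
    sigma_a: float = 0.3
    sigma_site: float = 0.5
    latent_weights: tuple = None  # if set, L env vars with these true weights
    gradient: str = "normal"      # or "uniform"
    binary_prevalence: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for s in (self.sigma_opt, self.sigma_log_tol, self.sigma_a,
                  self.sigma_site):
            if s < 0:
                raise ValueError("standard deviations must be non-negative")
        if not (0.0 < self.binary_prevalence < 1.0):
            raise ValueError("binary trait prevalence must be in (0, 1)")
        if self.gradient not in ("normal", "uniform"):
            raise ValueError("gradient must be 'normal' or 'uniform'")
        K = self.k_continuous + self.k_binary
        for name in ("beta_opt", "beta_log_tol", "beta_a"):
            b = tuple(float(v) for v in (getattr(self, name) or ()))
            if len(b) == 0:
                b = (0.0,) * K
            if len(b) != K:
                raise ValueError(f"{name} must have length {K}")
            object.__setattr__(self, name, b)

    @property
    def K(self) -> int:
        return self.k_continuous + self.k_binary

    @property
    def L(self) -> int:
        return 1 if self.latent_weights is None else len(self.latent_weights)


@dataclass
class SyntheticTruth:
    """The realized latent quantities behind a simulated community."""

    opt: np.ndarray
    tol: np.ndarray
    a: np.ndarray
    eps: np.ndarray
    traits: np.ndarray        # standardized trait matrix used in submodels
    scores: np.ndarray        # realized gradient / latent site scores
    weights: np.ndarray       # unit-norm latent weights (L,)
    config: SyntheticConfig


def _standardize_columns(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (v - v.mean(axis=0)) / sd


def simulate_community(cfg: SyntheticConfig):
    """Draw one community dataset; identical seed gives identical outputs.

    Returns ``(OccurrenceMatrix, EnvTable, TraitTable, SyntheticTruth)``.
    The returned environment and trait tables are already standardized.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m, K, L = cfg.n, cfg.m, cfg.K, cfg.L

    # traits: raw draws, then standardized exactly like the real pipeline
    cols = []
    kinds = []
    for _ in range(cfg.k_continuous):
        cols.append(rng.standard_normal(m))
        kinds.append("continuous")
    for _ in range(cfg.k_binary):
        col = (rng.uniform(size=m) < cfg.binary_prevalence).astype(float)
        if col.std() == 0:  # force both levels present
            col[0] = 1.0 - col[0]
        cols.append(col)
        kinds.append("binary")
    if K > 0:
        raw = np.column_stack(cols)
        Z = _standardize_columns(raw)
    else:
        Z = np.zeros((m, 0))

    # environment and site scores
    if cfg.latent_weights is not None:
        w = _normalize(np.asarray(cfg.latent_weights, dtype=float))
        env_raw = rng.standard_normal((n, L))
        env = _standardize_columns(env_raw)
        x = env @ w
    else:
        w = np.ones(1)
        if cfg.gradient == "normal":
            g = rng.standard_normal(n)
        else:
            g = rng.uniform(-2.0, 2.0, size=n)
        env = _standardize_columns(g[:, None])
        x = env[:, 0]

    # niche parameters from the trait submodels
    opt = (cfg.mu_opt + Z @ np.asarray(cfg.beta_opt)
           + cfg.sigma_opt * rng.standard_normal(m))
    log_tol = (cfg.mu_log_tol + Z @ np.asarray(cfg.beta_log_tol)
               + cfg.sigma_log_tol * rng.standard_normal(m))
    a = (cfg.mu_a + Z @ np.asarray(cfg.beta_a)
         + cfg.sigma_a * rng.standard_normal(m))
    tol = np.exp(log_tol)
    eps = cfg.sigma_site * rng.standard_normal(n)

    p = inv_logit(response_logit(x, opt, tol, a, eps))
    y = (rng.uniform(size=(n, m)) < p).astype(int)

    occ = OccurrenceMatrix(y, tuple(f"site{i+1}" for i in range(n)),
                           tuple(f"sp{j+1}" for j in range(m)))
    env_table = EnvTable(env, tuple(f"env{l+1}" for l in range(env.shape[1])),
                         standardized=True,
                         site_ids=occ.site_ids)
    trait_table = TraitTable(Z, tuple(f"trait{k+1}" for k in range(K)),
                             kinds=tuple(kinds), standardized=True,
                             species_ids=occ.species_ids)
    truth = SyntheticTruth(opt=opt, tol=tol, a=a, eps=eps, traits=Z,
                           scores=x, weights=w, config=cfg)
    return occ, env_table, trait_table, truth


def case_study_preset(seed: int = 0) -> SyntheticConfig:
    """A community shaped like the phytoplankton case study: 203 sites,
    60 species, 11 environmental variables, 6 traits (3 continuous,
    3 binary).

    One binary trait splits the species pool into two niche groups on
    opposite sides of the latent gradient (its slope on the optimum is the
    dominant effect), mimicking the two observed clusters of response
    curves; the latent gradient loads on five of the eleven environmental
    variables with alternating signs.
    """
    weights = (0.55, -0.55, 0.45, -0.30, 0.30, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return SyntheticConfig(
        n=203, m=60, k_continuous=3, k_binary=3,
        mu_opt=0.0, mu_log_tol=0.1, mu_a=0.8,
        beta_opt=(0.5, 0.0, 0.0, 1.2, 0.0, -0.4),
        beta_log_tol=(0.0,) * 6,
        beta_a=(0.0, 0.2, 0.0, 0.0, 0.0, 0.0),
        sigma_opt=0.4, sigma_log_tol=0.15, sigma_a=0.3, sigma_site=0.4,
        latent_weights=weights, binary_prevalence=0.4, seed=seed)
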