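"""Starting values via per-species quadratic logistic GLM fits.

The Gaussian logistic curve, logit p = a - (x - opt)^2 / (2 tol^2), is a
reparametrization of a quadratic logit predictor b0 + b1 x + b2 x^2.  When
the fitted b2 is negative the maximum-likelihood niche parameters follow in
closed form:

    opt = -b1 / (2 b2),   tol = 1 / sqrt(-2 b2),   a = b0 - b1^2 / (4 b2)

and equal the direct nonlinear ML estimates of the Gaussian logistic curve.
Species whose optimum sits at or beyond the edge of the sampled gradient
often yield b2 >= 0 (a truncated, apparently monotone curve); augmenting
the data with many absences outside the observed range restores an interior
optimum. Augmentation is used for initialization only — the Bayesian fit
always runs on the raw data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import statsmodels.api as sm

from .data_io import OccurrenceMatrix, TraitTable
from .model import inv_logit, logit

__all__ = [
    "PolyCoefficients",
    "GaussianNiche",
    "AugmentPolicy",
    "InitBundle",
    "augment_absences",
    "fit_species_glm",
    "poly_to_niche",
    "niche_to_poly",
    "initial_values",
]


@dataclass(frozen=True)
class PolyCoefficients:
    """Coefficients of the quadratic logit predictor b0 + b1 x + b2 x^2."""

    b0: float
    b1: float
    b2: float
    converged: bool = True
    separation: bool = False


@dataclass(frozen=True)
class GaussianNiche:
    """Niche parameters of one species' Gaussian logistic response."""

    opt: float
    tol: float
    a: float

    def __post_init__(self):
        if not self.tol > 0:
            raise ValueError("tolerance must be strictly positive")

    @property
    def p_max(self) -> float:
        """Occurrence probability at the optimum, inverse-logit(a)."""
        return float(inv_logit(self.a))


@dataclass(frozen=True)
class AugmentPolicy:
    """How to pad a species' data with artificial absences.

    ``n_aug`` zeros are appended on each side of the observed gradient
    range, on uniform grids extending the range by ``extend`` range-widths
    per side.
    """

    n_aug: int = 25
    extend: float = 1.0


def augment_absences(y, x, policy: AugmentPolicy = AugmentPolicy()):
    """Append absences strictly outside the observed gradient range.

    Original observations are returned unchanged and first in order.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("gradient values are constant")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("response must be binary")
    if policy.n_aug == 0:
        return y.copy(), x.copy()
    lo, hi = float(np.min(x)), float(np.max(x))
    width = (hi - lo) * policy.extend
    # open grids: endpoints strictly outside [lo, hi]
    step = width / policy.n_aug
    left = lo - step * np.arange(1, policy.n_aug + 1)
    right = hi + step * np.arange(1, policy.n_aug + 1)
    x_new = np.concatenate([x, left, right])
    y_new = np.concatenate([y, np.zeros(2 * policy.n_aug)])
    return y_new, x_new


def fit_species_glm(y, x) -> PolyCoefficients:
    """Maximum-likelihood logistic regression of y on (1, x, x^2).

    Perfect separation or non-convergence is not silent: the fit is
    stabilized by a tiny ridge on refit and flagged in the result.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate response: all-0 or all-1")
    X = np.column_stack([np.ones_like(x), x, x * x])
    model = sm.GLM(y, X, family=sm.families.Binomial())
    converged, separation = True, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(maxiter=200)
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.converged)
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e4:
                separation = True
    except (sm.tools.sm_exceptions.PerfectSeparationWarning,
            sm.tools.sm_exceptions.PerfectSeparationError,
            np.linalg.LinAlgError, ValueError):
        separation = True
    if separation:
        # ridge-stabilized refit: small L2 penalty keeps estimates finite
        res = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = np.asarray(res.params, dtype=float)
        converged = True
    return PolyCoefficients(float(params[0]), float(params[1]),
                            float(params[2]), converged=converged,
                            separation=separation)


def poly_to_niche(b: PolyCoefficients) -> GaussianNiche:
    """Closed-form reparametrization of the quadratic logit into niche
    parameters; valid only for b2 < 0 (interior optimum)."""
    if not b.b2 < 0:
        raise ValueError("no interior optimum: quadratic coefficient must be "
                         "negative")
    opt = -b.b1 / (2.0 * b.b2)
    tol = 1.0 / np.sqrt(-2.0 * b.b2)
    a = b.b0 - b.b1 ** 2 / (4.0 * b.b2)
    return GaussianNiche(float(opt), float(tol), float(a))


def niche_to_poly(n: GaussianNiche) -> PolyCoefficients:
    """Inverse reparametrization: expand the Gaussian logistic curve into
    its quadratic logit coefficients."""
    b2 = -1.0 / (2.0 * n.tol ** 2)
    b1 = n.opt / (n.tol ** 2)
    b0 = n.a - n.opt ** 2 / (2.0 * n.tol ** 2)
    return PolyCoefficients(float(b0), float(b1), float(b2))


@dataclass
class InitBundle:
    """Starting values for the MCMC, derived from augmented GLM fits and
    OLS regressions of the niche estimates on the traits."""

    opt: np.ndarray          # (m,)
    tol: np.ndarray          # (m,) natural scale
    a: np.ndarray            # (m,)
    eps: np.ndarray          # (n,) site effects
    mu: np.ndarray           # (3,) submodel intercepts for (opt, log tol, a)
    beta: np.ndarray         # (3, K) submodel slopes
    sigma2: np.ndarray       # (3,) submodel residual variances
    sigma2_site: float
    fallback_species: list = field(default_factory=list)
    augment: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        d = asdict(self)
        for k in ("opt", "tol", "a", "eps", "mu", "beta", "sigma2"):
            d[k] = np.asarray(d[k]).tolist()
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "InitBundle":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        for k in ("opt", "tol", "a", "eps", "mu", "beta", "sigma2"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _fit_one_species(y, x, policy: AugmentPolicy):
    """Augmented GLM fit for one species; returns a niche or None."""
    try:
        ya, xa = augment_absences(y, x, policy)
        coef = fit_species_glm(ya, xa)
        if coef.b2 < 0:
            return poly_to_niche(coef)
    except ValueError:
        pass
    return None


def initial_values(occ: OccurrenceMatrix, x, traits: TraitTable = None,
                   policy: AugmentPolicy = AugmentPolicy(),
                   sigma2_site: float = 0.1) -> InitBundle:
    """Starting values for all model parameters.

    Per-species niches come from augmented GLM fits; trait-submodel
    intercepts, slopes, and residual variances come from OLS of each niche
    parameter (optimum, log tolerance, maximum coefficient) on the trait
    matrix. Species that cannot be fitted even after augmentation fall back
    to a neutral niche (opt 0, tol 1, a at the logit of their prevalence)
    and are recorded in ``fallback_species``.
    """
    x = np.asarray(x, dtype=float)
    n, m = occ.values.shape
    opt = np.zeros(m)
    tol = np.ones(m)
    a = np.zeros(m)
    fallback = []
    for j in range(m):
        y = occ.values[:, j].astype(float)
        niche = _fit_one_species(y, x, policy)
        if niche is None:
            prev = float(np.clip(y.mean(), 1.0 / (2 * n), 1 - 1.0 / (2 * n)))
            opt[j], tol[j], a[j] = 0.0, 1.0, logit(prev)
            fallback.append(occ.species_ids[j])
        else:
            opt[j], tol[j], a[j] = niche.opt, niche.tol, niche.a

    K = 0 if traits is None else traits.values.shape[1]
    mu = np.zeros(3)
    beta = np.zeros((3, K))
    sigma2 = np.ones(3)
    targets = [opt, np.log(tol), a]
    if K > 0:
        Z = sm.add_constant(np.asarray(traits.values, dtype=float),
                            has_constant="add")
        for t, th in enumerate(targets):
            ols = sm.OLS(th, Z).fit()
            mu[t] = float(ols.params[0])
            beta[t] = np.asarray(ols.params[1:], dtype=float)
            dof = max(m - K - 1, 1)
            sigma2[t] = max(float(np.sum(ols.resid ** 2) / dof), 1e-4)
    else:
        for t, th in enumerate(targets):
            mu[t] = float(np.mean(th))
            sigma2[t] = max(float(np.var(th, ddof=1)) if m > 1 else 1.0, 1e-4)
    return InitBundle(opt=opt, tol=tol, a=a, eps=np.zeros(n), mu=mu,
                      beta=beta, sigma2=sigma2, sigma2_site=float(sigma2_site),
                      fallback_species=fallback,
                      augment={"n_aug": policy.n_aug, "extend": policy.extend})
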