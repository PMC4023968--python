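"""Model comparison and explained-variance statistics.

DIC is reported in two flavours. With D the deviance,
-2 sum log Bernoulli(y | p):

    p_D(classic) = Dbar - Dhat            DIC(classic) = Dhat + 2 p_D
    p_D(var)     = Var(D) / 2             DIC(var)     = Dbar + p_D(var)

where Dbar is the posterior mean deviance, Dhat the deviance at the
posterior mean of the parameters, and Var(D) the within-chain sample
variance of the deviance averaged over chains.
p_D(var) is non-negative by construction; p_D(classic) can go negative and
is flagged, never truncated.

The contribution of traits to a niche parameter is the drop in its
residual variance when traits enter the submodel:

    100 * (sigma2_without - sigma2_with) / sigma2_without

with both variances estimated by their posterior medians. The fraction can
be negative when traits do not help.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws, _scores
from .model import deviance as model_deviance
from .model import response_logit

__all__ = ["DicReport", "VarianceExplained", "dic_from_deviance",
           "compute_dic", "variance_explained", "convergence_report",
           "inclusion_probabilities"]

_PARAMS = ("opt", "tol", "a")


@dataclass(frozen=True)
class DicReport:
    d_bar: float
    d_hat: float
    p_d_classic: float
    p_d_var: float
    dic_classic: float
    dic_var: float
    flag_negative_pd: bool

    def __str__(self):
        flag = "  (! negative p_D)" if self.flag_negative_pd else ""
        return (f"Dbar={self.d_bar:.2f} Dhat={self.d_hat:.2f} "
                f"pD={self.p_d_classic:.2f}/{self.p_d_var:.2f} "
                f"DIC={self.dic_classic:.2f}/{self.dic_var:.2f}{flag}")


@dataclass(frozen=True)
class VarianceExplained:
    """Per niche parameter: residual variances without/with traits and the
    percentage of variance explained by the traits."""

    sigma2_without: dict
    sigma2_with: dict
    fraction_pct: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "without_traits": self.sigma2_without,
            "with_traits": self.sigma2_with,
            "fraction_pct": self.fraction_pct,
        })


def dic_from_deviance(dev: np.ndarray, d_hat: float) -> DicReport:
    """DIC report from per-chain deviance draws (chains x draws) and the
    deviance at the posterior mean."""
    dev = np.atleast_2d(np.asarray(dev, dtype=float))
    if dev.shape[1] < 2:
        raise ValueError("need at least two kept draws per chain")
    if not np.all(np.isfinite(dev)) or not np.isfinite(d_hat):
        raise ValueError("non-finite deviance")
    d_bar = float(dev.mean())
    var_within = float(np.mean(np.var(dev, axis=1, ddof=1)))
    p_classic = d_bar - float(d_hat)
    p_var = var_within / 2.0
    return DicReport(
        d_bar=d_bar, d_hat=float(d_hat),
        p_d_classic=p_classic, p_d_var=p_var,
        dic_classic=float(d_hat) + 2.0 * p_classic,
        dic_var=d_bar + p_var,
        flag_negative_pd=p_classic < 0,
    )


def _posterior_mean_deviance(draws: PosteriorDraws) -> float:
    """Deviance at the posterior mean of the natural-scale parameters.

    Tolerances are averaged on the log scale and back-transformed, matching
    the sampling parameterization.
    """
    y = draws.data["y"]
    opt = draws.stacked("opt").mean(axis=0)
    tol = np.exp(np.mean(np.log(draws.stacked("tol")), axis=0))
    a = draws.stacked("a").mean(axis=0)
    eps = draws.stacked("eps").mean(axis=0)
    if draws.mode == "latent":
        w = draws.stacked("weights").mean(axis=0)
        x = _scores(draws.data["env"], w)
    else:
        x = draws.data["x"]
    return model_deviance(y, response_logit(x, opt, tol, a, eps))


def compute_dic(draws: PosteriorDraws) -> DicReport:
    """Both DIC variants from a fit, recomputing Dhat from the stored data."""
    return dic_from_deviance(draws.draws["deviance"],
                             _posterior_mean_deviance(draws))


def variance_explained(with_traits: PosteriorDraws,
                       without_traits: PosteriorDraws) -> VarianceExplained:
    """Percentage of niche-parameter variance explained by traits.

    Both fits must be on identical data and gradient (checked by
    fingerprint).
    """
    fp_with = _data_only_fingerprint(with_traits)
    fp_without = _data_only_fingerprint(without_traits)
    if fp_with != fp_without:
        raise ValueError("data fingerprints do not match between fits")
    s_with = np.median(with_traits.stacked("sigma2"), axis=0)
    s_without = np.median(without_traits.stacked("sigma2"), axis=0)
    frac = 100.0 * (s_without - s_with) / s_without
    return VarianceExplained(
        sigma2_without=dict(zip(_PARAMS, map(float, s_without))),
        sigma2_with=dict(zip(_PARAMS, map(float, s_with))),
        fraction_pct=dict(zip(_PARAMS, map(float, frac))),
    )


def _data_only_fingerprint(draws: PosteriorDraws) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(draws.data["y"]).tobytes())
    grad = draws.data.get("env") if draws.mode == "latent" \
        else draws.data.get("x")
    if grad is not None:
        h.update(np.ascontiguousarray(grad).tobytes())
    return h.hexdigest()


def convergence_report(draws: PosteriorDraws,
                       parameters=("mu", "sigma2", "sigma2_site",
                                   "deviance")) -> pd.DataFrame:
    """Split-Rhat and effective sample size per scalar parameter.

    With a single chain Rhat is omitted (NaN) with a notice column. Rows
    with Rhat > 1.1 are flagged.
    """
    import arviz as az

    rows = []
    single = draws.n_chains < 2
    for name in parameters:
        if name not in draws.draws:
            continue
        arr = draws.draws[name]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for idx in range(flat.shape[2]):
            chain_draws = flat[:, :, idx]
            label = name if flat.shape[2] == 1 else f"{name}[{idx}]"
            ds = az.convert_to_dataset(chain_draws)
            ess = float(np.asarray(az.ess(ds)["x"].values))
            if single:
                rhat = np.nan
            else:
                rhat = float(np.asarray(az.rhat(ds)["x"].values))
            rows.append({"parameter": label, "rhat": rhat, "ess": ess,
                         "flagged": bool(rhat > 1.1) if not single else False})
    out = pd.DataFrame(rows)
    if single:
        out.attrs["notice"] = "single chain: Rhat omitted"
    return out


def inclusion_probabilities(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior means of the inclusion indicators.

    Reported per trait slope for each niche-parameter submodel, and per
    environmental variable for latent-gradient fits.
    """
    if draws.options.prior != "spike_slab":
        raise ValueError("no indicators in this model (normal-prior fit)")
    rows = []
    gamma = draws.stacked("gamma")  # (draws, 3, K)
    K = gamma.shape[2] if gamma.ndim == 3 else 0
    for t, pname in enumerate(_PARAMS):
        for k in range(K):
            rows.append({"target": pname, "coefficient": f"trait_{k}",
                         "probability": float(gamma[:, t, k].mean())})
    if draws.mode == "latent":
        ge = draws.stacked("gamma_env")
        for ell in range(ge.shape[1]):
            rows.append({"target": "gradient", "coefficient": f"env_{ell}",
                         "probability": float(ge[:, ell].mean())})
    return pd.DataFrame(rows)
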