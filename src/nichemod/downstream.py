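"""Post-fit ecology utilities: response-curve prediction, optimum-sign
species grouping, and between-group trait comparisons.

Grouping follows the case-study convention: species whose posterior-mean
optimum on the (standardized or latent) gradient is negative form group 1,
the rest group 2. Group differences in traits are tested with two-sided
Wilcoxon rank-sum tests for quantitative traits (exact enumeration for
small tie-free groups, normal approximation with tie correction otherwise)
and 2x2 chi-square tests for binary traits (no continuity correction by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import TraitTable
from .glm_init import GaussianNiche
from .model import inv_logit, response_logit

__all__ = ["SpeciesGroups", "predict_curve", "classify_groups",
           "trait_difference_tests"]

_EXACT_MAX = 6


@dataclass(frozen=True)
class SpeciesGroups:
    labels: np.ndarray          # (m,) in {1, 2}
    gradient_name: str = "gradient"
    threshold: float = 0.0
    species_ids: tuple = None

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        if not np.all((lab == 1) | (lab == 2)):
            raise ValueError("group labels must be 1 or 2")
        object.__setattr__(self, "labels", lab)

    def members(self, group: int) -> np.ndarray:
        return np.nonzero(self.labels == group)[0]


def predict_curve(niche: GaussianNiche, x_grid, site_effect: float = 0.0):
    """Occurrence probability along a gradient grid for one species."""
    x_grid = np.asarray(x_grid, dtype=float)
    logits = response_logit(x_grid, niche.opt, niche.tol, niche.a,
                            float(site_effect))[:, 0]
    return inv_logit(logits)


def classify_groups(opt_means, threshold: float = 0.0,
                    gradient_name: str = "gradient",
                    species_ids=None) -> SpeciesGroups:
    """Group 1: optimum below the threshold; group 2: at or above it
    (ties go to group 2)."""
    opt_means = np.asarray(opt_means, dtype=float)
    labels = np.where(opt_means < threshold, 1, 2)
    return SpeciesGroups(labels, gradient_name, float(threshold),
                         None if species_ids is None else tuple(species_ids))


def _wilcoxon_exact(u, v):
    """Exhaustive-permutation two-sided rank-sum p-value (no ties)."""
    from itertools import combinations

    pooled = np.concatenate([u, v])
    ranks = stats.rankdata(pooled)
    n1 = len(u)
    obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    center = ranks.sum() * n1 / len(pooled)
    p = np.mean(np.abs(sums - center) >= abs(obs - center) - 1e-12)
    return float(obs), float(p)


def trait_difference_tests(groups: SpeciesGroups, traits: TraitTable,
                           continuity_correction: bool = False
                           ) -> pd.DataFrame:
    """Between-group trait comparison table.

    One row per trait: group sizes, means and standard deviations (counts
    of 0/1 for binary traits), the test used, its statistic, and the
    two-sided p-value. Zero-variance continuous traits are skipped with a
    notice.
    """
    i1, i2 = groups.members(1), groups.members(2)
    if len(i1) < 2 or len(i2) < 2:
        raise ValueError("need at least two species in each group")
    rows = []
    for k, name in enumerate(traits.trait_names):
        col = traits.values[:, k]
        u, v = col[i1], col[i2]
        row = {"trait": name, "kind": traits.kinds[k],
               "n1": len(u), "n2": len(v),
               "mean1": float(u.mean()), "mean2": float(v.mean()),
               "sd1": float(u.std(ddof=1)), "sd2": float(v.std(ddof=1))}
        if traits.kinds[k] == "binary":
            # a standardized binary trait still has two levels; the lower
            # one corresponds to raw 0
            lo = np.min(col)
            table = np.array([
                [np.sum(u == lo), np.sum(v == lo)],
                [np.sum(u != lo), np.sum(v != lo)],
            ], dtype=float)
            res = stats.chi2_contingency(table,
                                         correction=continuity_correction)
            row.update(test="chi-square", statistic=float(res.statistic),
                       p_value=float(res.pvalue),
                       counts=table.astype(int).tolist())
        else:
            if np.ptp(col[np.concatenate([i1, i2])]) == 0:
                row.update(test="skipped", statistic=np.nan, p_value=np.nan,
                           note="zero-variance trait")
                rows.append(row)
                continue
            ties = len(np.unique(np.concatenate([u, v]))) < len(u) + len(v)
            if max(len(u), len(v)) <= _EXACT_MAX and not ties:
                statistic, p = _wilcoxon_exact(u, v)
                row.update(test="wilcoxon-exact", statistic=statistic,
                           p_value=p)
            else:
                res = stats.mannwhitneyu(u, v, alternative="two-sided",
                                         method="asymptotic")
                # report the rank-sum statistic of the first group
                w = float(res.statistic) + len(u) * (len(u) + 1) / 2.0
                row.update(test="wilcoxon-normal", statistic=w,
                           p_value=float(res.pvalue))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["continuity_correction"] = continuity_correction
    return out
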