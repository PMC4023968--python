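"""Input tables, validation, preprocessing, and CSV round-tripping.

Three rectangular tables drive every analysis:

* an n x m presence/absence matrix (sites x species),
* an n x L table of quantitative environmental variables (missing cells
  allowed before imputation),
* an m x K table of quantitative and binary species traits.

Preprocessing follows the usual community-ecology pipeline: skewed
variables are transformed to natural logarithms, missing cells are filled
with simple column summaries, every column is centred and scaled to unit
sample standard deviation, and species present in fewer than ``min_frac``
of the sites are dropped.

CSV conventions: first row is a header, first column holds site or species
identifiers. Missing cells may be written as an empty field or as ``NA``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OccurrenceMatrix",
    "EnvTable",
    "TraitTable",
    "read_occurrence",
    "read_env",
    "read_traits",
    "write_table",
    "simple_impute",
    "transform_and_standardize",
    "inverse_transform",
    "filter_rare_species",
]

_NA_VALUES = ["", "NA"]


@dataclass(frozen=True)
class OccurrenceMatrix:
    """Binary sites x species table."""

    values: np.ndarray  # (n, m) of {0, 1}
    site_ids: tuple
    species_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("occurrence matrix must be two-dimensional")
        n, m = v.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 sites and 1 species")
        if np.any(np.isnan(v)):
            raise ValueError("occurrence matrix may not contain missing cells")
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("occurrence matrix cells must be exactly 0 or 1")
        if len(set(self.site_ids)) != n or len(set(self.species_ids)) != m:
            raise ValueError("site and species labels must be unique")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.site_ids),
                            columns=list(self.species_ids))


@dataclass(frozen=True)
class EnvTable:
    """Sites x environmental-variables table (quantitative)."""

    values: np.ndarray  # (n, L), NaN marks missing
    var_names: tuple
    log_flags: tuple = None
    standardized: bool = False
    site_ids: tuple = None
    # retained transformation parameters (set by transform_and_standardize)
    means: np.ndarray = None
    sds: np.ndarray = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("environment table must be two-dimensional")
        L = v.shape[1]
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "var_names", tuple(self.var_names))
        if len(self.var_names) != L:
            raise ValueError("var_names length mismatch")
        flags = self.log_flags if self.log_flags is not None else (False,) * L
        object.__setattr__(self, "log_flags", tuple(bool(f) for f in flags))
        if self.site_ids is None:
            object.__setattr__(self, "site_ids",
                               tuple(f"site{i+1}" for i in range(v.shape[0])))
        else:
            object.__setattr__(self, "site_ids", tuple(self.site_ids))

    @property
    def labels(self):
        return self.site_ids

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.var_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.site_ids),
                            columns=list(self.var_names))


@dataclass(frozen=True)
class TraitTable:
    """Species x traits table of continuous and binary traits."""

    values: np.ndarray  # (m, K), NaN marks missing
    trait_names: tuple
    kinds: tuple = None  # 'continuous' | 'binary' per column
    standardized: bool = False
    species_ids: tuple = None
    log_flags: tuple = None
    means: np.ndarray = None
    sds: np.ndarray = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("trait table must be two-dimensional")
        K = v.shape[1]
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        if len(self.trait_names) != K:
            raise ValueError("trait_names length mismatch")
        if self.kinds is None:
            kinds = tuple(_infer_kind(v[:, k]) for k in range(K))
        else:
            kinds = tuple(self.kinds)
        if any(k not in ("continuous", "binary") for k in kinds):
            raise ValueError("trait kinds must be 'continuous' or 'binary'")
        if not self.standardized:
            for k, kind in enumerate(kinds):
                col = v[:, k]
                obs = col[~np.isnan(col)]
                if kind == "binary" and not np.all((obs == 0) | (obs == 1)):
                    raise ValueError(
                        f"binary trait column '{self.trait_names[k]}' contains "
                        "values other than 0/1")
        object.__setattr__(self, "kinds", kinds)
        flags = self.log_flags if self.log_flags is not None else (False,) * K
        object.__setattr__(self, "log_flags", tuple(bool(f) for f in flags))
        if self.species_ids is None:
            object.__setattr__(self, "species_ids",
                               tuple(f"sp{j+1}" for j in range(v.shape[0])))
        else:
            object.__setattr__(self, "species_ids", tuple(self.species_ids))

    @property
    def labels(self):
        return self.species_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.species_ids),
                            columns=list(self.trait_names))


def _infer_kind(col: np.ndarray) -> str:
    obs = col[~np.isnan(col)]
    if obs.size and np.all((obs == 0) | (obs == 1)):
        return "binary"
    return "continuous"


# ---------------------------------------------------------------------------
# readers / writers


def read_occurrence(path) -> OccurrenceMatrix:
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, float_precision="round_trip")
    return OccurrenceMatrix(df.to_numpy(dtype=float),
                            tuple(map(str, df.index)),
                            tuple(map(str, df.columns)))


def read_env(path, log_columns=()) -> EnvTable:
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, float_precision="round_trip")
    names = tuple(map(str, df.columns))
    unknown = set(log_columns) - set(names)
    if unknown:
        raise ValueError(f"log-flagged columns not in table: {sorted(unknown)}")
    flags = tuple(nm in set(log_columns) for nm in names)
    return EnvTable(df.to_numpy(dtype=float), names, flags,
                    site_ids=tuple(map(str, df.index)))


def read_traits(path, kinds=None, log_columns=()) -> TraitTable:
    df = pd.read_csv(path, index_col=0, na_values=_NA_VALUES,
                     keep_default_na=False, float_precision="round_trip")
    names = tuple(map(str, df.columns))
    flags = tuple(nm in set(log_columns) for nm in names)
    return TraitTable(df.to_numpy(dtype=float), names, kinds=kinds,
                      species_ids=tuple(map(str, df.index)), log_flags=flags)


def write_table(table, path) -> None:
    """Write any of the three tables as CSV (round-trips finite doubles)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g preserves every finite double exactly across the round trip
    table.to_frame().to_csv(path, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# preprocessing operations


def simple_impute(table):
    """Fill missing cells with simple per-column summaries.

    Continuous columns get the mean of observed values; for log-flagged
    columns the mean is taken on the natural-log scale (i.e. the geometric
    mean is imputed), so that the subsequent log transform sees values
    consistent with a Gaussian model on the log scale. Binary columns get
    the observed mode, with ties resolved to 0.

    Returns ``(imputed_table, mask)`` where ``mask`` is a boolean array
    marking the filled cells.
    """
    v = np.array(table.values, dtype=float)
    mask = np.isnan(v)
    kinds = getattr(table, "kinds", None)
    names = getattr(table, "var_names", None) or getattr(table, "trait_names")
    for k in range(v.shape[1]):
        miss = mask[:, k]
        if not miss.any():
            continue
        obs = v[~miss, k]
        if obs.size == 0:
            raise ValueError(f"column '{names[k]}' is entirely missing")
        kind = kinds[k] if kinds is not None else "continuous"
        if kind == "binary":
            ones = int(np.sum(obs == 1))
            zeros = int(np.sum(obs == 0))
            v[miss, k] = 1.0 if ones > zeros else 0.0
        elif table.log_flags[k]:
            if np.any(obs <= 0):
                bad = int(np.nonzero(~miss)[0][np.argmax(obs <= 0)])
                raise ValueError(
                    f"non-positive value in log-flagged column '{names[k]}' "
                    f"at row {bad}")
            v[miss, k] = float(np.exp(np.mean(np.log(obs))))
        else:
            v[miss, k] = float(np.mean(obs))
    return replace(table, values=v), mask


def _standardize_matrix(v, names, log_flags):
    v = np.array(v, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("missing cells present; impute before standardizing")
    for k, flag in enumerate(log_flags):
        if flag:
            col = v[:, k]
            if np.any(col <= 0):
                row = int(np.argmax(col <= 0))
                raise ValueError(
                    f"non-positive value in log-flagged column '{names[k]}' "
                    f"at row {row}")
            v[:, k] = np.log(col)
    means = v.mean(axis=0)
    sds = v.std(axis=0, ddof=1)
    for k in range(v.shape[1]):
        if sds[k] == 0 or not np.isfinite(sds[k]):
            raise ValueError(f"zero variance in column '{names[k]}'")
    return (v - means) / sds, means, sds


def transform_and_standardize(env: EnvTable, traits: TraitTable):
    """Natural-log transform flagged columns, then centre and scale all
    columns to sample mean 0 and sample standard deviation 1 (ddof=1).

    Binary trait columns are standardized the same way as continuous ones.
    The column means and standard deviations are retained on the returned
    tables so the transform can be inverted.
    """
    env_std, e_mean, e_sd = _standardize_matrix(
        env.values, env.var_names, env.log_flags)
    tr_std, t_mean, t_sd = _standardize_matrix(
        traits.values, traits.trait_names, traits.log_flags)
    env2 = replace(env, values=env_std, standardized=True,
                   means=e_mean, sds=e_sd)
    tr2 = replace(traits, values=tr_std, standardized=True,
                  means=t_mean, sds=t_sd)
    return env2, tr2


def inverse_transform(table):
    """Undo standardization (and any log transform), recovering raw values."""
    if not table.standardized or table.means is None:
        raise ValueError("table does not carry transformation parameters")
    v = table.values * table.sds + table.means
    v = np.array(v)
    for k, flag in enumerate(table.log_flags):
        if flag:
            v[:, k] = np.exp(v[:, k])
    return replace(table, values=v, standardized=False, means=None, sds=None)


def filter_rare_species(occ: OccurrenceMatrix,
                        min_frac: float = 0.05) -> OccurrenceMatrix:
    """Drop species occurring in fewer than ``min_frac`` of the sites.

    A species is retained iff (number of presences) / n >= min_frac.
    Column order of the survivors is preserved.
    """
    if not (0.0 < min_frac < 1.0):
        raise ValueError("min_frac must lie strictly between 0 and 1")
    frac = occ.values.sum(axis=0) / occ.n_sites
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("all species removed by the occurrence filter")
    ids = tuple(s for s, k in zip(occ.species_ids, keep) if k)
    return OccurrenceMatrix(occ.values[:, keep], occ.site_ids, ids)
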