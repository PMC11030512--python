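"""Model specification, group abundance distributions, and design matrices.

A model is declared by :class:`ModelSpec`: one outcome column, an ordered
list of continuous covariates, an ordered list of categorical covariates
with ordered level lists, and a set of (categorical, continuous) modifier
pairs that receive interaction columns.  :func:`build_design` expands a
tabular dataset into the *unconstrained* design matrix with one dummy
column per level of every categorical variable (no level is dropped) and
one interaction column per (categorical, level, continuous) modifier
triple.  Identification is deferred to the constraints module.

Column order contract: intercept; continuous covariates in spec order;
per-categorical dummy blocks in level order; interaction columns ordered
by (categorical, level, continuous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_INTERCEPT = "intercept"
ROLE_CONTINUOUS = "continuous"
ROLE_DUMMY = "dummy"
ROLE_INTERACTION = "interaction"


@dataclass(frozen=True)
class ColumnInfo:
    """Metadata for one design-matrix column."""

    role: str
    name: str
    #: owning continuous variable (continuous/interaction columns)
    continuous: str | None = None
    #: owning categorical variable (dummy/interaction columns)
    categorical: str | None = None
    #: level of the owning categorical variable
    level: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Declarative regression model.

    Parameters
    ----------
    outcome
        Name of the outcome column.
    continuous
        Ordered names of the continuous covariates (the p x-variables).
    categoricals
        Ordered ``(name, levels)`` pairs; ``levels`` is the ordered,
        duplicate-free list of admissible levels.
    modifier_pairs
        Set of ``(categorical, continuous)`` pairs whose interaction
        columns enter the design (effect modification).
    standardize
        Center and scale continuous covariates by their sample SD before
        interactions are formed.
    """

    outcome: str
    continuous: tuple[str, ...] = ()
    categoricals: tuple[tuple[str, tuple[str, ...]], ...] = ()
    modifier_pairs: frozenset[tuple[str, str]] = frozenset()
    standardize: bool = False

    def __post_init__(self) -> None:
        if len(set(self.continuous)) != len(self.continuous):
            raise ValueError("duplicate continuous covariate names")
        cat_names = [name for name, _ in self.categoricals]
        if len(set(cat_names)) != len(cat_names):
            raise ValueError("duplicate categorical covariate names")
        for name, levels in self.categoricals:
            if len(levels) == 0:
                raise ValueError(f"categorical {name!r} has an empty level list")
            if len(set(levels)) != len(levels):
                raise ValueError(f"categorical {name!r} has duplicate levels")
        for cat, cont in self.modifier_pairs:
            if cat not in cat_names:
                raise ValueError(f"modifier pair references unknown categorical {cat!r}")
            if cont not in self.continuous:
                raise ValueError(f"modifier pair references unknown continuous {cont!r}")

    # -- convenience accessors -------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.continuous)

    @property
    def L(self) -> int:
        return len(self.categoricals)

    def levels_of(self, cat: str) -> tuple[str, ...]:
        for name, levels in self.categoricals:
            if name == cat:
                return levels
        raise KeyError(cat)

    def modified_continuous(self, cat: str) -> tuple[str, ...]:
        """Continuous variables interacted with ``cat``, in spec order."""
        return tuple(x for x in self.continuous if (cat, x) in self.modifier_pairs)

    @classmethod
    def from_config(cls, config: Mapping) -> "ModelSpec":
        """Build a spec from a JSON-style mapping.

        Expected keys: ``outcome``, ``continuous`` (list), ``categoricals``
        (list of ``{"name": ..., "levels": [...]}`` or ``[name, levels]``),
        ``modifiers`` (list of ``[categorical, continuous]`` pairs, or the
        string ``"all"`` for all pairs), ``standardize`` (bool).
        """
        continuous = tuple(config.get("continuous", ()))
        cats = []
        for entry in config.get("categoricals", ()):
            if isinstance(entry, Mapping):
                cats.append((entry["name"], tuple(entry.get("levels", ()))))
            else:
                name, levels = entry
                cats.append((name, tuple(levels)))
        modifiers = config.get("modifiers", ())
        if modifiers == "all":
            pairs = frozenset((c, x) for (c, _), x in product(cats, continuous))
        else:
            pairs = frozenset((c, x) for c, x in modifiers)
        return cls(
            outcome=config["outcome"],
            continuous=continuous,
            categoricals=tuple(cats),
            modifier_pairs=pairs,
            standardize=bool(config.get("standardize", False)),
        )


def infer_spec_levels(spec: ModelSpec, table: pd.DataFrame) -> ModelSpec:
    """Fill empty level lists with the lexicographically sorted observed labels."""
    cats = []
    for name, levels in spec.categoricals:
        if not levels:
            levels = tuple(sorted(table[name].astype(str).unique()))
        cats.append((name, levels))
    return ModelSpec(
        outcome=spec.outcome,
        continuous=spec.continuous,
        categoricals=tuple(cats),
        modifier_pairs=spec.modifier_pairs,
        standardize=spec.standardize,
    )


@dataclass(frozen=True)
class GroupDistribution:
    """Abundance distribution of the categorical covariates.

    Stores the joint table over all categorical variables plus the per-
    variable marginals derived from it (with one categorical they
    coincide).  ``source`` records whether proportions came from sample
    frequencies or a supplied population table.
    """

    variables: tuple[str, ...]
    #: joint proportions keyed by level tuples, summing to 1
    joint: Mapping[tuple[str, ...], float]
    source: str = "sample"

    def __post_init__(self) -> None:
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"joint proportions sum to {total!r}, not 1")
        if any(v <= 0 for v in self.joint.values()):
            raise ValueError("zero or negative abundance in joint table")

    def marginal(self, variable: str) -> dict[str, float]:
        idx = self.variables.index(variable)
        out: dict[str, float] = {}
        for key, prob in self.joint.items():
            out[key[idx]] = out.get(key[idx], 0.0) + prob
        return out


def group_proportions(
    labels: pd.DataFrame | Mapping[str, Sequence],
    levels: Mapping[str, Sequence[str]] | None = None,
    mode: str = "sample",
    population: Mapping[tuple[str, ...], float] | None = None,
    drop_empty: bool = False,
) -> GroupDistribution:
    """Compute the (joint) group abundance distribution.

    Parameters
    ----------
    labels
        Per-row level assignments, one column per categorical variable.
    levels
        Declared levels per variable; defaults to sorted observed labels.
    mode
        ``"sample"`` uses empirical frequencies (counts / n);
        ``"population"`` uses the supplied joint ``population`` table.
    population
        Joint proportions keyed by level tuples (single-variable keys may
        be bare strings); required in population mode.
    drop_empty
        In sample mode, drop declared levels with zero count (logged)
        instead of raising.
    """
    labels = pd.DataFrame(labels).astype(str)
    variables = tuple(labels.columns)
    if levels is None:
        levels = {v: tuple(sorted(labels[v].unique())) for v in variables}
    for v in variables:
        declared = set(levels[v])
        seen = set(labels[v].unique())
        unknown = seen - declared
        if unknown:
            raise ValueError(
                f"unseen label {sorted(unknown)[0]!r} for variable {v!r}"
            )

    if mode == "population":
        if population is None:
            raise ValueError("population mode requires a population table")
        joint = {}
        for key, prob in population.items():
            if not isinstance(key, tuple):
                key = (key,)
            joint[tuple(str(k) for k in key)] = float(prob)
        # every declared marginal level must be covered
        for v in variables:
            idx = variables.index(v)
            covered = {k[idx] for k in joint}
            absent = set(levels[v]) - covered
            if absent:
                raise ValueError(
                    f"population table missing level {sorted(absent)[0]!r} of {v!r}"
                )
        return GroupDistribution(variables=variables, joint=joint, source="population")

    if mode != "sample":
        raise ValueError(f"unknown mode {mode!r}")

    n = len(labels)
    if n == 0:
        raise ValueError("no rows")
    counts = labels.value_counts(sort=False)
    joint: dict[tuple[str, ...], float] = {}
    for key in product(*(levels[v] for v in variables)):
        c = int(counts.get(key if len(key) > 1 else key[0], 0))
        if c:
            joint[key] = c / n
    # zero-count declared marginal levels break OLS identifiability
    for v in variables:
        marg_counts = labels[v].value_counts()
        for lev in levels[v]:
            if int(marg_counts.get(lev, 0)) == 0:
                if drop_empty:
                    logger.warning(
                        "dropping zero-count level %r of %r", lev, v
                    )
                else:
                    raise ValueError(
                        f"level {lev!r} of {v!r} has zero count; "
                        "OLS with this level is not identifiable"
                    )
    return GroupDistribution(variables=variables, joint=joint, source="sample")


@dataclass
class DesignMatrix:
    """Expanded, unconstrained design matrix with per-column metadata."""

    X: np.ndarray
    columns: tuple[ColumnInfo, ...]
    labels: pd.DataFrame
    spec: ModelSpec
    #: (center, scale) per continuous variable when standardized
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def ncols(self) -> int:
        return self.X.shape[1]

    def column_index(
        self,
        role: str,
        continuous: str | None = None,
        categorical: str | None = None,
        level: str | None = None,
    ) -> int:
        for i, c in enumerate(self.columns):
            if (
                c.role == role
                and (continuous is None or c.continuous == continuous)
                and (categorical is None or c.categorical == categorical)
                and (level is None or c.level == level)
            ):
                return i
        raise KeyError((role, continuous, categorical, level))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=[c.name for c in self.columns])

    def to_csv(self, path) -> None:
        """Export for inspection, with metadata header lines."""
        with open(path, "w") as fh:
            fh.write("# role: " + ",".join(c.role for c in self.columns) + "\n")
            fh.write(
                "# owner: "
                + ",".join(
                    "|".join(x for x in (c.continuous, c.categorical, c.level) if x)
                    or "-"
                    for c in self.columns
                )
                + "\n"
            )
            self.to_frame().to_csv(fh, index=False)


def expected_ncols(spec: ModelSpec) -> int:
    """1 + p + sum_l G_l + sum_l G_l * p*_l, with p*_l the number of
    continuous variables interacted with categorical l."""
    total = 1 + spec.p
    for name, levels in spec.categoricals:
        total += len(levels)
        total += len(levels) * len(spec.modified_continuous(name))
    return total


def build_design(spec: ModelSpec, table: pd.DataFrame) -> DesignMatrix:
    """Expand a tabular dataset into the unconstrained design matrix.

    Missing values in any used column are rejected (count logged), never
    imputed.  When ``spec.standardize`` is set, each continuous column is
    centered and scaled by its sample SD (ddof=1) before interaction
    columns are formed.
    """
    if len(set(table.columns)) != len(table.columns):
        raise ValueError("duplicate column names in input table")
    needed = [spec.outcome, *spec.continuous, *(name for name, _ in spec.categoricals)]
    for col in needed:
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    used = table[needed]
    n_missing = int(used.isna().any(axis=1).sum())
    if n_missing:
        raise ValueError(
            f"{n_missing} rows contain missing values in model columns; "
            "remove or impute upstream"
        )

    n = len(table)
    cont_data: dict[str, np.ndarray] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for var in spec.continuous:
        col = table[var]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(f"continuous column {var!r} is not numeric")
        x = col.to_numpy(dtype=float)
        if spec.standardize:
            mu, sd = float(x.mean()), float(x.std(ddof=1))
            if sd == 0.0:
                raise ValueError(f"zero-variance continuous column {var!r}")
            x = (x - mu) / sd
            scaling[var] = (mu, sd)
        cont_data[var] = x

    labels = pd.DataFrame(
        {name: table[name].astype(str) for name, _ in spec.categoricals},
        index=table.index,
    )
    for name, levels in spec.categoricals:
        unknown = set(labels[name].unique()) - set(levels)
        if unknown:
            raise ValueError(
                f"unseen label {sorted(unknown)[0]!r} for categorical {name!r}"
            )

    cols: list[np.ndarray] = [np.ones(n)]
    meta: list[ColumnInfo] = [ColumnInfo(role=ROLE_INTERCEPT, name="(Intercept)")]
    for var in spec.continuous:
        cols.append(cont_data[var])
        meta.append(ColumnInfo(role=ROLE_CONTINUOUS, name=var, continuous=var))
    dummies: dict[tuple[str, str], np.ndarray] = {}
    for name, levels in spec.categoricals:
        for lev in levels:
            d = (labels[name] == lev).to_numpy(dtype=float)
            dummies[(name, lev)] = d
            cols.append(d)
            meta.append(
                ColumnInfo(
                    role=ROLE_DUMMY, name=f"{name}={lev}", categorical=name, level=lev
                )
            )
    for name, levels in spec.categoricals:
        mod = spec.modified_continuous(name)
        for lev in levels:
            for var in mod:
                cols.append(dummies[(name, lev)] * cont_data[var])
                meta.append(
                    ColumnInfo(
                        role=ROLE_INTERACTION,
                        name=f"{var}:{name}={lev}",
                        continuous=var,
                        categorical=name,
                        level=lev,
                    )
                )

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    assert X.shape[1] == expected_ncols(spec)
    return DesignMatrix(X=X, columns=tuple(meta), labels=labels, spec=spec, scaling=scaling)
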