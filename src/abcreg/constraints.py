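"""Identification constraints and null-space bases.

Four schemes identify the overparametrized design produced by
:func:`abcreg.design.build_design`:

* ``abc`` — abundance-based constraints: the abundance-weighted mean of
  each categorical variable's level coefficients (and of each modified
  variable's interaction coefficients) is zero.
* ``rge`` — reference group encoding: the first level's coefficients are
  zero.
* ``stz`` — sum-to-zero: the unweighted sum of level coefficients is zero.
* ``over`` — overparametrized: no constraints (m = 0); estimable only
  under penalization.

Each constrained scheme contributes one row per categorical variable for
its dummy block plus one row per (categorical, modified continuous)
pair, i.e. m = sum_l (1 + p*_l).  Fitting goes through an orthonormal
basis Q of the null space of the constraint matrix C (from the QR
decomposition of C^T), so a constrained least-squares problem becomes an
unconstrained one in m fewer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .design import (
    ROLE_DUMMY,
    ROLE_INTERACTION,
    DesignMatrix,
    GroupDistribution,
)

SCHEME_ABC = "abc"
SCHEME_RGE = "rge"
SCHEME_STZ = "stz"
SCHEME_OVER = "over"
SCHEMES = (SCHEME_ABC, SCHEME_RGE, SCHEME_STZ, SCHEME_OVER)

_RANK_RTOL = 1e-10  # relative singular-value tolerance for rank checks


@dataclass(frozen=True)
class ConstraintSet:
    """Constraint matrix C with one description per row.

    Each description is ``(categorical, target)`` where ``target`` is
    ``"(Intercept)"`` for the dummy-block row or the name of the modified
    continuous variable for an interaction-block row.
    """

    C: np.ndarray
    scheme: str
    row_info: tuple[tuple[str, str], ...]

    @property
    def m(self) -> int:
        return self.C.shape[0]

    def to_csv(self, path, column_names=None) -> None:
        import pandas as pd

        df = pd.DataFrame(self.C, columns=column_names)
        df.insert(0, "target", [t for _, t in self.row_info])
        df.insert(0, "categorical", [c for c, _ in self.row_info])
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class Basis:
    """Orthonormal basis of the null space of a constraint matrix."""

    Q: np.ndarray  # (ncols, ncols - m)

    @property
    def dim(self) -> int:
        return self.Q.shape[1]


def _level_weights(scheme: str, levels: tuple[str, ...], marg: dict[str, float]):
    if scheme == SCHEME_ABC:
        return np.array([marg[lev] for lev in levels])
    if scheme == SCHEME_STZ:
        return np.ones(len(levels))
    if scheme == SCHEME_RGE:
        w = np.zeros(len(levels))
        w[0] = 1.0
        return w
    raise ValueError(f"unknown scheme {scheme!r}")


def build_constraints(
    dm: DesignMatrix, scheme: str, dist: GroupDistribution | None = None
) -> ConstraintSet:
    """Build the constraint matrix for a scheme, aligned to design columns.

    ``dist`` is required for ABCs (its marginals supply the abundance
    weights) and must cover every declared level with positive
    proportion; it is ignored for the other schemes.
    """
    scheme = scheme.lower()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    spec = dm.spec
    if scheme == SCHEME_OVER:
        return ConstraintSet(
            C=np.empty((0, dm.ncols)), scheme=scheme, row_info=()
        )
    if scheme == SCHEME_ABC:
        if dist is None:
            raise ValueError("ABC constraints require a group distribution")

    rows: list[np.ndarray] = []
    info: list[tuple[str, str]] = []
    for name, levels in spec.categoricals:
        if scheme == SCHEME_ABC:
            marg = dist.marginal(name)
            missing = set(levels) - set(marg)
            if missing:
                raise ValueError(
                    f"no abundance for level {sorted(missing)[0]!r} of {name!r}"
                )
            if any(marg[lev] <= 0 for lev in levels):
                raise ValueError(f"zero abundance level in {name!r} under ABCs")
        else:
            marg = {}
        w = _level_weights(scheme, levels, marg)

        row = np.zeros(dm.ncols)
        for lev, wl in zip(levels, w):
            row[dm.column_index(ROLE_DUMMY, categorical=name, level=lev)] = wl
        rows.append(row)
        info.append((name, "(Intercept)"))

        for var in spec.modified_continuous(name):
            row = np.zeros(dm.ncols)
            for lev, wl in zip(levels, w):
                row[
                    dm.column_index(
                        ROLE_INTERACTION, continuous=var, categorical=name, level=lev
                    )
                ] = wl
            rows.append(row)
            info.append((name, var))

    C = np.vstack(rows) if rows else np.empty((0, dm.ncols))
    if C.shape[0]:
        sv = scipy.linalg.svdvals(C)
        if sv[-1] <= _RANK_RTOL * sv[0]:
            raise ValueError("rank-deficient constraint matrix (duplicated constraints?)")
    return ConstraintSet(C=C, scheme=scheme, row_info=tuple(info))


def null_space_basis(cs: ConstraintSet, ncols: int | None = None) -> Basis:
    """Orthonormal null-space basis via QR of C^T.

    For the overparametrized scheme (m = 0) returns the identity basis.
    """
    if ncols is None:
        ncols = cs.C.shape[1]
    if cs.C.shape[1] != ncols:
        raise ValueError("ncols does not match constraint matrix")
    m = cs.m
    if m == 0:
        return Basis(Q=np.eye(ncols))
    sv = scipy.linalg.svdvals(cs.C)
    if sv[-1] <= _RANK_RTOL * sv[0]:
        raise ValueError("rank-deficient constraint matrix")
    Q, _ = scipy.linalg.qr(cs.C.T, mode="full")
    return Basis(Q=Q[:, m:])


def constraint_residual(cs: ConstraintSet, theta: np.ndarray) -> float:
    """max |C theta|; 0 for an empty constraint set."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != cs.C.shape[1]:
        raise ValueError(
            f"theta has length {theta.shape[0]}, expected {cs.C.shape[1]}"
        )
    if cs.m == 0:
        return 0.0
    return float(np.max(np.abs(cs.C @ theta)))
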