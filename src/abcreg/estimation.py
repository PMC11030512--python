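"""Constrained OLS via null-space reparametrization, with exact
finite-sample inference and moment diagnostics.

The constrained least-squares problem

    minimize ||y - X theta||^2  subject to  C theta = 0

is solved by writing theta = Q zeta for Q an orthonormal basis of the
null space of C, reducing to unconstrained OLS on the adjusted design
Z = X Q.  With iid Gaussian errors the estimator is exactly Gaussian,
theta_hat ~ N(theta, sigma^2 Q (Z'Z)^{-1} Q'), so standard errors,
t-tests and confidence intervals carry over from classical OLS with
n - dim(zeta) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .constraints import (
    SCHEME_ABC,
    SCHEME_OVER,
    Basis,
    ConstraintSet,
    constraint_residual,
    null_space_basis,
)
from .design import ROLE_CONTINUOUS, ROLE_INTERACTION, DesignMatrix

_RCOND_MIN = 1e-12  # reciprocal-condition threshold for collinearity


@dataclass
class FittedModel:
    """Identified fit on the full design-column parametrization."""

    theta_hat: np.ndarray
    sigma2_hat: float
    cov_theta: np.ndarray | None
    scheme: str
    n: int
    dof: int
    dm: DesignMatrix
    cs: ConstraintSet
    basis: Basis
    fitted: np.ndarray
    residuals: np.ndarray
    lam: float = 0.0
    penalty: str = "none"

    @property
    def coef_names(self) -> list[str]:
        return [c.name for c in self.dm.columns]

    def constraint_residual(self) -> float:
        return constraint_residual(self.cs, self.theta_hat)


def _check_conditioning(Z: np.ndarray) -> None:
    sv = scipy.linalg.svdvals(Z)
    if sv[0] == 0 or sv[-1] / sv[0] < _RCOND_MIN:
        raise np.linalg.LinAlgError(
            "adjusted design Z is numerically singular "
            f"(rcond={0.0 if sv[0] == 0 else sv[-1] / sv[0]:.2e}); "
            "check for collinear or empty design columns"
        )


def fit_ols(dm: DesignMatrix, y: np.ndarray, cs: ConstraintSet) -> FittedModel:
    """Constrained OLS through the null-space reparametrization."""
    if cs.scheme == SCHEME_OVER:
        raise ValueError("the overparametrized scheme is not identified for OLS")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != dm.n:
        raise ValueError("y length does not match design rows")
    basis = null_space_basis(cs, dm.ncols)
    Z = dm.X @ basis.Q
    d = Z.shape[1]
    if dm.n <= d:
        raise ValueError(f"need n > dim(zeta) = {d}, got n = {dm.n}")
    _check_conditioning(Z)
    ZtZ = Z.T @ Z
    cho = scipy.linalg.cho_factor(ZtZ)
    zeta = scipy.linalg.cho_solve(cho, Z.T @ y)
    theta = basis.Q @ zeta
    fitted = Z @ zeta
    resid = y - fitted
    dof = dm.n - d
    sigma2 = float(resid @ resid) / dof
    ZtZ_inv = scipy.linalg.cho_solve(cho, np.eye(d))
    cov = sigma2 * basis.Q @ ZtZ_inv @ basis.Q.T
    cov = 0.5 * (cov + cov.T)
    return FittedModel(
        theta_hat=theta,
        sigma2_hat=sigma2,
        cov_theta=cov,
        scheme=cs.scheme,
        n=dm.n,
        dof=dof,
        dm=dm,
        cs=cs,
        basis=basis,
        fitted=fitted,
        residuals=resid,
    )


def fit_ols_kkt_oracle(dm: DesignMatrix, y: np.ndarray, cs: ConstraintSet) -> FittedModel:
    """Constrained OLS by solving the bordered stationarity (KKT) system

        [[X'X, C'], [C, 0]] [theta; nu] = [X'y; 0]

    directly.  An independent route used for cross-checks in tests."""
    if cs.scheme == SCHEME_OVER:
        raise ValueError("the overparametrized scheme is not identified for OLS")
    y = np.asarray(y, dtype=float).ravel()
    X, C = dm.X, cs.C
    D, m = X.shape[1], cs.m
    XtX = X.T @ X
    K = np.zeros((D + m, D + m))
    K[:D, :D] = XtX
    K[:D, D:] = C.T
    K[D:, :D] = C
    rhs = np.zeros(D + m)
    rhs[:D] = X.T @ y
    try:
        sol = scipy.linalg.solve(K, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular bordered KKT system: {exc}") from exc
    theta = sol[:D]
    fitted = X @ theta
    resid = y - fitted
    dof = dm.n - (D - m)
    sigma2 = float(resid @ resid) / dof
    # cov(theta) = sigma^2 * B X'X B' with B the top-left block of K^{-1}
    Kinv = scipy.linalg.inv(K)
    B = Kinv[:D, :D]
    cov = sigma2 * B @ XtX @ B.T
    cov = 0.5 * (cov + cov.T)
    return FittedModel(
        theta_hat=theta,
        sigma2_hat=sigma2,
        cov_theta=cov,
        scheme=cs.scheme,
        n=dm.n,
        dof=dof,
        dm=dm,
        cs=cs,
        basis=null_space_basis(cs, D),
        fitted=fitted,
        residuals=resid,
    )


class LinComb(NamedTuple):
    estimate: float
    se: float
    t: float
    p: float
    ci_lower: float
    ci_upper: float


def linear_combination(
    fit: FittedModel, weights: np.ndarray, level: float = 0.95
) -> LinComb:
    """Point estimate and t-inference for c' theta_hat."""
    c = np.asarray(weights, dtype=float).ravel()
    if c.shape[0] != fit.theta_hat.shape[0]:
        raise ValueError("weight vector length does not match coefficients")
    est = float(c @ fit.theta_hat)
    var = float(c @ fit.cov_theta @ c) if fit.cov_theta is not None else np.nan
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), fit.dof))
    else:
        t, p = (np.inf if est != 0 else 0.0), (0.0 if est != 0 else 1.0)
    q = stats.t.ppf(0.5 + level / 2, fit.dof)
    return LinComb(est, se, t, p, est - q * se, est + q * se)


def coefficient_inference(fit: FittedModel, level: float = 0.95) -> pd.DataFrame:
    """Full coefficient table: every level of every categorical variable
    appears as its own row; no hidden reference level."""
    if fit.dof < 1:
        raise ValueError("no residual degrees of freedom for inference")
    se = np.sqrt(np.clip(np.diag(fit.cov_theta), 0.0, None))
    est = fit.theta_hat
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.t.sf(np.abs(t), fit.dof)
    q = stats.t.ppf(0.5 + level / 2, fit.dof)
    cols = fit.dm.columns
    return pd.DataFrame(
        {
            "name": [c.name for c in cols],
            "role": [c.role for c in cols],
            "continuous": [c.continuous for c in cols],
            "categorical": [c.categorical for c in cols],
            "level": [c.level for c in cols],
            "estimate": est,
            "se": se,
            "t": t,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
            "ci_lower": est - q * se,
            "ci_upper": est + q * se,
        }
    )


def group_specific_slopes(
    fit: FittedModel, continuous: str, categorical: str, level: float = 0.95
) -> pd.DataFrame:
    """Slope of ``continuous`` within each level of ``categorical``:
    alpha_j + gamma_{l,r,j}, with SEs from the joint covariance.

    Under ABCs the abundance-weighted average of the rows equals the main
    effect alpha_j; under RGE the first level's row equals alpha_j.
    """
    spec = fit.dm.spec
    if (categorical, continuous) not in spec.modifier_pairs:
        raise ValueError(
            f"({categorical!r}, {continuous!r}) is not a modifier pair"
        )
    j_main = fit.dm.column_index(ROLE_CONTINUOUS, continuous=continuous)
    rows = []
    for lev in spec.levels_of(categorical):
        c = np.zeros(fit.dm.ncols)
        c[j_main] = 1.0
        c[
            fit.dm.column_index(
                ROLE_INTERACTION,
                continuous=continuous,
                categorical=categorical,
                level=lev,
            )
        ] = 1.0
        lc = linear_combination(fit, c, level=level)
        rows.append(
            {
                "level": lev,
                "estimate": lc.estimate,
                "se": lc.se,
                "t": lc.t,
                "p": lc.p,
                "ci_lower": lc.ci_lower,
                "ci_upper": lc.ci_upper,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupMoments:
    """Within-group scaled moments of continuous covariates.

    ``scaled_cov[r]`` is the matrix with entries
    n_r^{-1} s_r(j,h) - xbar_r(j) xbar_r(h), i.e. the ddof=0 sample
    covariance within group r.  ``heterogeneity`` is the maximum over
    groups and entries of the relative deviation from the first group's
    matrix; it is 0 iff the equal-(co)variance condition holds exactly.
    """

    variables: tuple[str, ...]
    groups: tuple[str, ...]
    n_r: dict[str, int]
    mean: dict[str, np.ndarray]
    raw_second: dict[str, np.ndarray]  # s_r(j,h) = sum_i x_ij x_ih
    scaled_cov: dict[str, np.ndarray]
    heterogeneity: float = field(default=0.0)


def variance_condition_diagnostic(
    x: np.ndarray | pd.DataFrame,
    labels: Sequence[str],
    variables: Sequence[str] | None = None,
) -> GroupMoments:
    """Within-group scaled (co)variances and a heterogeneity summary.

    The estimation-invariance property of ABCs holds when the scaled
    within-group covariance of the continuous covariates is the same in
    every group; this diagnostic quantifies the deviation."""
    if isinstance(x, pd.DataFrame):
        if variables is None:
            variables = tuple(x.columns)
        xv = x.to_numpy(dtype=float)
    else:
        xv = np.atleast_2d(np.asarray(x, dtype=float))
        if xv.shape[0] == 1 and len(labels) != 1:
            xv = xv.T
        if variables is None:
            variables = tuple(f"x{j + 1}" for j in range(xv.shape[1]))
    labels = np.asarray([str(g) for g in labels])
    if labels.shape[0] != xv.shape[0]:
        raise ValueError("labels length does not match rows of x")
    groups = tuple(sorted(set(labels)))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_r, mean, raw, cov = {}, {}, {}, {}
    for g in groups:
        sub = xv[labels == g]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {g!r}")
        n_r[g] = sub.shape[0]
        mean[g] = sub.mean(axis=0)
        raw[g] = sub.T @ sub
        cov[g] = raw[g] / sub.shape[0] - np.outer(mean[g], mean[g])
    ref = cov[groups[0]]
    scale = np.maximum(np.abs(ref), 1e-12)
    het = max(
        float(np.max(np.abs(cov[g] - ref) / scale)) for g in groups[1:]
    )
    return GroupMoments(
        variables=tuple(variables),
        groups=groups,
        n_r=n_r,
        mean=mean,
        raw_second=raw,
        scaled_cov=cov,
        heterogeneity=het,
    )


def abc_slope_identity_gap(fit: FittedModel, dist) -> float:
    """Max absolute gap between each main effect and the abundance-weighted
    average of its group-specific slopes (0 under ABCs, up to rounding)."""
    if fit.scheme != SCHEME_ABC:
        raise ValueError("identity holds under ABCs only")
    spec = fit.dm.spec
    worst = 0.0
    for name, levels in spec.categoricals:
        marg = dist.marginal(name)
        for var in spec.modified_continuous(name):
            tab = group_specific_slopes(fit, var, name)
            avg = sum(marg[lev] * e for lev, e in zip(tab["level"], tab["estimate"]))
            main = fit.theta_hat[fit.dm.column_index(ROLE_CONTINUOUS, continuous=var)]
            worst = max(worst, abs(avg - main))
    return worst
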