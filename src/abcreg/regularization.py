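"""Penalized estimation on the constrained parametrization.

Penalties have the form P(theta) = sum_j w_j |theta_j|^delta on the
*full* design-column coefficients, with delta=2 (adaptive ridge) or
delta=1 (adaptive lasso).  Fitting goes through the null-space basis Q:
theta = Q zeta turns the constrained penalized problem into an
unconstrained one in zeta,

    minimize ||y - Z zeta||^2 + lambda * P(Q zeta),      Z = X Q.

Ridge has the closed form zeta = (Z'Z + lambda D'D)^{-1} Z'y with
D = diag(w^{1/2}) Q.  The lasso objective is a generalized lasso in
zeta (the penalty acts on Q zeta, not zeta); it is solved by ADMM with
the splitting theta = Q zeta, warm-started along a decreasing lambda
grid with a cached Cholesky factorization.

Penalty weights default to the sample SD of each design column (1 for
the intercept): dummy and interaction columns for low-abundance groups
have small SDs and correspondingly large coefficients, so the
standardized penalty avoids overpenalizing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import linprog

from .constraints import SCHEME_OVER, Basis, ConstraintSet, null_space_basis
from .design import ROLE_INTERCEPT, DesignMatrix
from .estimation import FittedModel, fit_ols


def penalty_weights(dm: DesignMatrix) -> np.ndarray:
    """Per-column penalty weights: sample SD (ddof=1), 1 for the intercept."""
    w = dm.X.std(axis=0, ddof=1)
    for j, c in enumerate(dm.columns):
        if c.role == ROLE_INTERCEPT:
            w[j] = 1.0
        elif w[j] == 0.0:
            raise ValueError(f"zero-SD design column {c.name!r} cannot be weighted")
    return w


def lambda_max(
    dm: DesignMatrix, y: np.ndarray, cs: ConstraintSet, weights: np.ndarray
) -> float:
    """Smallest lambda at which the lasso solution is identically zero.

    From the KKT condition of the reparametrized problem at zeta = 0
    (the loss ||y - Z zeta||^2 has gradient -2 Z'y there):
    lambda_max = min over nu of max_j |(2 X'y + C'nu)_j| / w_j, a linear
    program (nu ranges over the constraint-row multipliers).  With no
    constraints this reduces to max_j |2 (X'y)_j| / w_j.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = 2.0 * (dm.X.T @ y)
    w = np.asarray(weights, dtype=float)
    if cs.m == 0:
        return float(np.max(np.abs(g) / w))
    m, D = cs.m, dm.ncols
    # variables (nu, t): minimize t  s.t.  |g + C' nu| <= t * w
    c_obj = np.zeros(m + 1)
    c_obj[-1] = 1.0
    A = np.zeros((2 * D, m + 1))
    A[:D, :m] = cs.C.T
    A[:D, -1] = -w
    A[D:, :m] = -cs.C.T
    A[D:, -1] = -w
    b = np.concatenate([-g, g])
    res = linprog(
        c_obj,
        A_ub=A,
        b_ub=b,
        bounds=[(None, None)] * m + [(0, None)],
        method="highs",
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"lambda_max LP failed: {res.message}")
    return float(res.x[-1])


def lambda_grid(lmax: float, n: int = 100, ratio: float = 1e-4) -> np.ndarray:
    """Decreasing log-spaced grid from lmax down to ratio * lmax."""
    if lmax <= 0:
        raise ValueError("lambda_max must be positive")
    return np.geomspace(lmax, ratio * lmax, n)


# ---------------------------------------------------------------------------
# ridge


def fit_ridge(
    dm: DesignMatrix,
    y: np.ndarray,
    cs: ConstraintSet,
    lam: float,
    weights: np.ndarray | None = None,
) -> FittedModel:
    """Adaptive ridge by the closed form
    theta(lambda) = Q (Z'Z + lambda D'D)^{-1} Z'y, D = diag(w^{1/2}) Q."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0.0:
        return fit_ols(dm, y, cs)  # raises for Over, as required
    y = np.asarray(y, dtype=float).ravel()
    if weights is None:
        weights = penalty_weights(dm)
    basis = null_space_basis(cs, dm.ncols)
    Q = basis.Q
    Z = dm.X @ Q
    DtD = Q.T @ (weights[:, None] * Q)
    A = Z.T @ Z + lam * DtD
    zeta = scipy.linalg.solve(A, Z.T @ y, assume_a="pos")
    theta = Q @ zeta
    fitted = Z @ zeta
    resid = y - fitted
    dof = dm.n - Z.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    return FittedModel(
        theta_hat=theta,
        sigma2_hat=sigma2,
        cov_theta=None,
        scheme=cs.scheme,
        n=dm.n,
        dof=dof,
        dm=dm,
        cs=cs,
        basis=basis,
        fitted=fitted,
        residuals=resid,
        lam=lam,
        penalty="ridge",
    )


# ---------------------------------------------------------------------------
# generalized lasso via ADMM


class LassoNonConvergence(RuntimeError):
    def __init__(self, lam: float, primal: float, dual: float, iters: int):
        self.lam, self.primal, self.dual, self.iters = lam, primal, dual, iters
        super().__init__(
            f"ADMM did not converge at lambda={lam:.4g} after {iters} iterations "
            f"(primal residual {primal:.2e}, dual residual {dual:.2e})"
        )


class _GenLassoADMM:
    """ADMM for min_zeta ||y - Z zeta||^2 + lam * sum_j w_j |(Q zeta)_j|.

    Splitting theta = Q zeta; the zeta-update Cholesky (Z'Z + rho I,
    using Q'Q = I) is cached and reused across lambdas and residual-
    balancing steps only refactor when rho changes.
    """

    def __init__(
        self,
        Z: np.ndarray,
        Q: np.ndarray,
        y: np.ndarray,
        w: np.ndarray,
        tol_abs: float = 1e-8,
        tol_rel: float = 1e-7,
        max_iter: int = 20000,
    ):
        self.Z, self.Q, self.w = Z, Q, w
        # loss is ||y - Z zeta||^2 (no 1/2), gradient 2(Z'Z zeta - Z'y)
        self.ZtZ2 = 2.0 * (Z.T @ Z)
        self.Zty2 = 2.0 * (Z.T @ y)
        self.tol_abs, self.tol_rel, self.max_iter = tol_abs, tol_rel, max_iter
        self.d = Z.shape[1]
        self.D = Q.shape[0]
        self._rho = None
        self._cho = None
        # warm-start state
        self.zeta = np.zeros(self.d)
        self.theta = np.zeros(self.D)
        self.u = np.zeros(self.D)

    def _factor(self, rho: float) -> None:
        if self._rho != rho:
            self._cho = scipy.linalg.cho_factor(
                self.ZtZ2 + rho * np.eye(self.d), check_finite=False
            )
            self._rho = rho

    def solve(self, lam: float) -> np.ndarray:
        """Returns theta = Q zeta at the solution (exact constraint
        satisfaction; sparsity is up to the solver tolerance)."""
        if lam <= 0:
            raise ValueError("lambda must be positive for the lasso")
        rho = max(lam, 1e-8)
        self._factor(rho)
        zeta, theta, u = self.zeta, self.theta, self.u
        Q, w = self.Q, self.w
        sqrtD, sqrtd = np.sqrt(self.D), np.sqrt(self.d)
        r_norm = s_norm = np.inf
        for it in range(self.max_iter):
            rhs = self.Zty2 + rho * (Q.T @ (theta - u))
            zeta = scipy.linalg.cho_solve(
                (self._cho[0], self._cho[1]), rhs, check_finite=False
            )
            Qz = Q @ zeta
            theta_old = theta
            v = Qz + u
            kappa = lam * w / rho
            theta = np.sign(v) * np.maximum(np.abs(v) - kappa, 0.0)
            u = u + Qz - theta
            r = Qz - theta
            r_norm = float(np.linalg.norm(r))
            s_norm = float(rho * np.linalg.norm(Q.T @ (theta - theta_old)))
            eps_pri = sqrtD * self.tol_abs + self.tol_rel * max(
                float(np.linalg.norm(Qz)), float(np.linalg.norm(theta))
            )
            eps_dual = sqrtd * self.tol_abs + self.tol_rel * float(
                rho * np.linalg.norm(Q.T @ u)
            )
            if r_norm <= eps_pri and s_norm <= eps_dual:
                break
            if (it + 1) % 10 == 0:
                if r_norm > 10 * s_norm:
                    rho *= 2.0
                    u = u / 2.0
                    self._factor(rho)
                elif s_norm > 10 * r_norm:
                    rho /= 2.0
                    u = u * 2.0
                    self._factor(rho)
        else:
            raise LassoNonConvergence(lam, r_norm, s_norm, self.max_iter)
        self.zeta, self.theta, self.u = zeta, theta, u
        return Q @ zeta


@dataclass
class PenaltyPath:
    """Coefficient path over a decreasing lambda grid."""

    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambda, n_design_columns)
    penalty: str
    scheme: str
    dm: DesignMatrix
    cs: ConstraintSet
    weights: np.ndarray
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    lambda_min: float | None = None
    lambda_1se: float | None = None

    def coef_frame(self) -> pd.DataFrame:
        """Long-format path: one row per (lambda, column)."""
        names = [c.name for c in self.dm.columns]
        rows = []
        for lam, th in zip(self.lambdas, self.coefs):
            for name, val in zip(names, th):
                rows.append({"lambda": lam, "column": name, "coefficient": val})
        return pd.DataFrame(rows)

    def slope_table(self, continuous: str, categorical: str) -> pd.DataFrame:
        """Group-specific slopes alpha_j + gamma_{l,r,j} along the path."""
        from .design import ROLE_CONTINUOUS, ROLE_INTERACTION

        j = self.dm.column_index(ROLE_CONTINUOUS, continuous=continuous)
        rows = []
        for lev in self.dm.spec.levels_of(categorical):
            k = self.dm.column_index(
                ROLE_INTERACTION, continuous=continuous, categorical=categorical,
                level=lev,
            )
            for lam, th in zip(self.lambdas, self.coefs):
                rows.append(
                    {
                        "lambda": lam,
                        "level": lev,
                        "slope": th[j] + th[k],
                        "main": th[j],
                        "modifier": th[k],
                    }
                )
        return pd.DataFrame(rows)

    def coef_at(self, lam: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coefs[i]


def fit_lasso_path(
    dm: DesignMatrix,
    y: np.ndarray,
    cs: ConstraintSet,
    grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    tol_abs: float = 1e-8,
    tol_rel: float = 1e-7,
    max_iter: int = 20000,
) -> PenaltyPath:
    """Adaptive-lasso coefficient path on a decreasing lambda grid."""
    y = np.asarray(y, dtype=float).ravel()
    if weights is None:
        weights = penalty_weights(dm)
    if grid is None:
        grid = lambda_grid(lambda_max(dm, y, cs, weights))
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) >= 0):
        raise ValueError("lambda grid must be strictly positive and decreasing")
    basis = null_space_basis(cs, dm.ncols)
    Z = dm.X @ basis.Q
    solver = _GenLassoADMM(
        Z, basis.Q, y, weights, tol_abs=tol_abs, tol_rel=tol_rel, max_iter=max_iter
    )
    coefs = np.empty((len(grid), dm.ncols))
    for i, lam in enumerate(grid):
        coefs[i] = solver.solve(lam)
    return PenaltyPath(
        lambdas=grid,
        coefs=coefs,
        penalty="lasso",
        scheme=cs.scheme,
        dm=dm,
        cs=cs,
        weights=weights,
    )


def lasso_kkt_violation(
    dm: DesignMatrix,
    y: np.ndarray,
    cs: ConstraintSet,
    theta: np.ndarray,
    lam: float,
    weights: np.ndarray,
    active_tol: float = 1e-7,
) -> float:
    """Stationarity violation of the generalized-lasso KKT conditions.

    Returns min over admissible subgradients s (s_j = w_j sign(theta_j)
    on the active set, |s_j| <= w_j elsewhere) of
    max_j |(2 Z'(Z zeta - y) + lam Q' s)_j|, computed by an LP.
    Zero (to LP tolerance) iff theta is a solution.
    """
    basis = null_space_basis(cs, dm.ncols)
    Q = basis.Q
    zeta = Q.T @ np.asarray(theta, dtype=float)
    Z = dm.X @ Q
    g = 2.0 * (Z.T @ (Z @ zeta - y))  # gradient of ||y - Z zeta||^2
    w = np.asarray(weights, dtype=float)
    th = Q @ zeta
    active = np.abs(th) > active_tol
    s_fixed = np.where(active, w * np.sign(th), 0.0)
    base = g + lam * (Q.T @ s_fixed)
    free = ~active
    nf = int(free.sum())
    d = Q.shape[1]
    if nf == 0:
        return float(np.max(np.abs(base)))
    # variables (s_free, t): minimize t  s.t. |base + lam Q_free' s_free| <= t
    Qf = Q[free, :]  # (nf, d)
    c_obj = np.zeros(nf + 1)
    c_obj[-1] = 1.0
    A = np.zeros((2 * d, nf + 1))
    A[:d, :nf] = lam * Qf.T
    A[:d, -1] = -1.0
    A[d:, :nf] = -lam * Qf.T
    A[d:, -1] = -1.0
    b = np.concatenate([-base, base])
    bounds = [(-wj, wj) for wj in w[free]] + [(0, None)]
    res = linprog(c_obj, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"KKT LP failed: {res.message}")
    return float(res.x[-1])


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_error: np.ndarray
    se_error: np.ndarray
    lambda_min: float
    lambda_1se: float
    folds: np.ndarray  # per-row fold assignment


def _stratified_folds(labels: pd.DataFrame, K: int, seed: int) -> np.ndarray:
    """Round-robin fold assignment within each joint categorical group,
    so every training split retains all observed levels."""
    n = len(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if labels.shape[1] == 0:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % K
        return folds
    joint = labels.astype(str).agg("\x1f".join, axis=1).to_numpy()
    start = 0
    for g in sorted(set(joint)):
        idx = np.flatnonzero(joint == g)
        if len(idx) < 2:
            raise ValueError(
                f"group {g.replace(chr(31), '/')!r} has fewer than 2 rows; "
                "cannot keep all levels in every training split"
            )
        idx = rng.permutation(idx)
        folds[idx] = (start + np.arange(len(idx))) % K
        start += len(idx)
    return folds


def cross_validate(
    dm: DesignMatrix,
    y: np.ndarray,
    cs: ConstraintSet,
    grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    K: int = 10,
    seed: int = 0,
    penalty: str = "lasso",
    tol_abs: float = 1e-7,
    tol_rel: float = 1e-5,
    max_iter: int = 20000,
) -> CVResult:
    """K-fold cross-validation curve with min and one-SE lambda selection.

    Folds are stratified by the joint categorical label (round-robin
    within group, shuffled by ``seed``) so that every training split
    retains every observed level.  Validation error is mean squared
    error on the raw outcome scale; the SE at each lambda is the
    standard error of the K fold means.
    """
    if K < 2:
        raise ValueError("need K >= 2 folds")
    if penalty not in ("ridge", "lasso"):
        raise ValueError(f"unknown penalty {penalty!r}")
    y = np.asarray(y, dtype=float).ravel()
    if weights is None:
        weights = penalty_weights(dm)
    if grid is None:
        grid = lambda_grid(lambda_max(dm, y, cs, weights))
    grid = np.asarray(grid, dtype=float)
    folds = _stratified_folds(dm.labels, K, seed)
    basis = null_space_basis(cs, dm.ncols)
    Q = basis.Q
    X = dm.X
    errors = np.empty((K, len(grid)))
    for k in range(K):
        tr, va = folds != k, folds == k
        Ztr = X[tr] @ Q
        ytr, Xva, yva = y[tr], X[va], y[va]
        if penalty == "ridge":
            ZtZ = Ztr.T @ Ztr
            Zty = Ztr.T @ ytr
            DtD = Q.T @ (weights[:, None] * Q)
            for i, lam in enumerate(grid):
                zeta = scipy.linalg.solve(ZtZ + lam * DtD, Zty, assume_a="pos")
                pred = Xva @ (Q @ zeta)
                errors[k, i] = float(np.mean((yva - pred) ** 2))
        else:
            solver = _GenLassoADMM(
                Ztr, Q, ytr, weights,
                tol_abs=tol_abs, tol_rel=tol_rel, max_iter=max_iter,
            )
            for i, lam in enumerate(grid):
                theta = solver.solve(lam)
                pred = Xva @ theta
                errors[k, i] = float(np.mean((yva - pred) ** 2))
    mean_err = errors.mean(axis=0)
    se_err = errors.std(axis=0, ddof=1) / np.sqrt(K)
    i_min = int(np.argmin(mean_err))
    lam_min = float(grid[i_min])
    threshold = mean_err[i_min] + se_err[i_min]
    # grid is decreasing: the largest admissible lambda is the first index
    i_1se = int(np.flatnonzero(mean_err <= threshold)[0])
    return CVResult(
        lambdas=grid,
        mean_error=mean_err,
        se_error=se_err,
        lambda_min=lam_min,
        lambda_1se=float(grid[i_1se]),
        folds=folds,
    )


def fit_penalized(
    dm: DesignMatrix,
    y: np.ndarray,
    cs: ConstraintSet,
    penalty: str,
    lam: float,
    weights: np.ndarray | None = None,
    **solver_kwargs,
) -> FittedModel:
    """Fit at a single lambda with the named penalty."""
    if weights is None:
        weights = penalty_weights(dm)
    if penalty == "ridge":
        return fit_ridge(dm, y, cs, lam, weights)
    if penalty != "lasso":
        raise ValueError(f"unknown penalty {penalty!r}")
    y = np.asarray(y, dtype=float).ravel()
    basis = null_space_basis(cs, dm.ncols)
    Z = dm.X @ basis.Q
    solver = _GenLassoADMM(Z, basis.Q, y, np.asarray(weights, float), **solver_kwargs)
    theta = solver.solve(lam)
    fitted = dm.X @ theta
    resid = y - fitted
    dof = dm.n - Z.shape[1]
    return FittedModel(
        theta_hat=theta,
        sigma2_hat=float(resid @ resid) / max(dof, 1),
        cov_theta=None,
        scheme=cs.scheme,
        n=dm.n,
        dof=dof,
        dm=dm,
        cs=cs,
        basis=basis,
        fitted=fitted,
        residuals=resid,
        lam=lam,
        penalty="lasso",
    )
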