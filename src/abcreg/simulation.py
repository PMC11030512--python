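"""Synthetic-data generators and estimator-comparison experiments.

Two study designs are implemented:

* **Main-only Gaussian design** (:class:`SimConfigMain`): p = 10
  continuous covariates, six independent N(0,1) and four whose mean
  equals the group index (N(r,1)), one 4-level categorical variable, a
  main-effects-only truth (alpha_0 = 1, alpha_1..5 = 1, alpha_6..10 = 0,
  beta = (0, 1, 0, -1)), and Gaussian noise calibrated so that
  Var(mu)/sigma^2 equals the target signal-to-noise ratio.  The level
  coefficients satisfy both the reference-group constraint (beta_1 = 0)
  and the abundance constraint (sum_r pi_r beta_r = 0) at the population
  proportions, so every identification scheme is compared against the
  same truth.  Fitted models deliberately include all group-by-covariate
  modifiers, which are extraneous under the truth.

* **Invariance design** (:class:`SimConfigInvariance`): one continuous
  covariate whose distribution depends on the group (shifted normal,
  scaled uniform, shifted t4, gamma), heavy-tailed t4 errors, and a
  response with modifier strength gamma on groups A (positive) and B
  (negative).  Used to compare the main-only and modifier-including
  estimates of the x-effect across identification schemes.

All generators are pure functions of (config, seed, replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constraints import SCHEME_ABC, SCHEME_OVER, build_constraints
from .design import (
    ModelSpec,
    build_design,
    group_proportions,
)
from .estimation import fit_ols
from .regularization import (
    cross_validate,
    fit_penalized,
    lambda_grid,
    lambda_max,
    penalty_weights,
)

MAIN_LEVELS = ("G1", "G2", "G3", "G4")
INV_LEVELS = ("A", "B", "C", "D")

_DEP_COLS = (4, 5, 9, 10)  # 1-based indices of group-dependent covariates


@dataclass(frozen=True)
class SimConfigMain:
    """Main-only Gaussian design."""

    n: int = 250
    p: int = 10
    pi: tuple[float, ...] = (0.15, 0.35, 0.15, 0.35)
    alpha0: float = 1.0
    alpha: tuple[float, ...] = (1.0,) * 5 + (0.0,) * 5
    beta: tuple[float, ...] = (0.0, 1.0, 0.0, -1.0)
    snr: float = 1.0
    n_reps: int = 500
    seed: int = 0
    #: minimum rows per group; p + 1 is needed to fit per-group slopes
    min_group: int | None = None
    max_redraws: int = 1000

    def __post_init__(self):
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ValueError("group proportions must sum to 1")
        if len(self.alpha) != self.p or len(self.beta) != len(self.pi):
            raise ValueError("coefficient lengths do not match p / #groups")
        if abs(self.beta[0]) > 0 or abs(sum(p * b for p, b in zip(self.pi, self.beta))) > 1e-12:
            raise ValueError(
                "truth must satisfy both beta_1 = 0 and sum_r pi_r beta_r = 0"
            )

    @property
    def min_per_group(self) -> int:
        return self.p + 1 if self.min_group is None else self.min_group


@dataclass(frozen=True)
class SimConfigInvariance:
    """Four-group mixture design with t4 errors for invariance checks."""

    n: int = 500
    pi: tuple[float, ...] = (0.55, 0.20, 0.10, 0.15)
    gamma: float = 0.0
    n_reps: int = 500
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.pi) - 1.0) > 1e-12:
            raise ValueError("group proportions must sum to 1")
        if self.gamma < 0:
            raise ValueError("modifier strength gamma must be nonnegative")


def _rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def model_variance(cfg: SimConfigMain) -> float:
    """Analytic Var(mu(X, R)) under the main-only truth.

    The independent covariates contribute sum alpha_j^2.  The group-
    dependent covariates share mean r given R = r, so with
    s1 = sum of their alphas and s2 = sum of their squared alphas,
    their joint contribution with the level effects is
    s2 + Var_pi(r * s1 + beta_r).
    """
    pi = np.asarray(cfg.pi)
    alpha = np.asarray(cfg.alpha)
    dep = np.array([j - 1 for j in _DEP_COLS if j <= cfg.p])
    indep = np.array([j for j in range(cfg.p) if j not in set(dep)], dtype=int)
    var = float(np.sum(alpha[indep] ** 2)) if len(indep) else 0.0
    s1 = float(np.sum(alpha[dep])) if len(dep) else 0.0
    s2 = float(np.sum(alpha[dep] ** 2)) if len(dep) else 0.0
    r_idx = np.arange(1, len(pi) + 1, dtype=float)
    g = r_idx * s1 + np.asarray(cfg.beta)
    var += s2 + float(np.sum(pi * g**2) - np.sum(pi * g) ** 2)
    return var


def noise_scale_for_snr(cfg: SimConfigMain) -> float:
    """Noise SD sigma with sigma^2 = Var(mu)/snr, Var(mu) analytic."""
    if cfg.snr <= 0:
        raise ValueError("snr must be positive")
    v = model_variance(cfg)
    if v <= 0:
        raise ValueError("zero signal variance; cannot calibrate noise")
    return float(np.sqrt(v / cfg.snr))


def main_only_spec(cfg: SimConfigMain, modifiers: bool = True) -> ModelSpec:
    """ModelSpec for fitting: all covariates, the group variable, and
    (optionally) all group-by-covariate modifiers."""
    cont = tuple(f"x{j + 1}" for j in range(cfg.p))
    pairs = frozenset(("group", x) for x in cont) if modifiers else frozenset()
    return ModelSpec(
        outcome="y",
        continuous=cont,
        categoricals=(("group", MAIN_LEVELS[: len(cfg.pi)]),),
        modifier_pairs=pairs,
    )


def simulate_main_only(cfg: SimConfigMain, replicate: int = 0):
    """One dataset from the main-only design.

    Returns ``(table, truth)``: a DataFrame with columns y, x1..xp,
    group, and a dict with the generating coefficients and noise SD.
    Redraws the whole dataset until every group has at least p + 1 rows
    (attempt cap ``cfg.max_redraws``).
    """
    rng = _rng(cfg.seed, replicate)
    G = len(cfg.pi)
    sigma = noise_scale_for_snr(cfg)
    for _ in range(cfg.max_redraws):
        g = rng.choice(G, size=cfg.n, p=cfg.pi)
        counts = np.bincount(g, minlength=G)
        if counts.min() >= cfg.min_per_group:
            break
    else:
        raise RuntimeError(
            f"could not draw all group counts >= {cfg.min_per_group} in "
            f"{cfg.max_redraws} attempts"
        )
    X = rng.standard_normal((cfg.n, cfg.p))
    for j in _DEP_COLS:
        if j <= cfg.p:
            X[:, j - 1] += g + 1  # mean = group index (1-based)
    beta = np.asarray(cfg.beta)
    mu = cfg.alpha0 + X @ np.asarray(cfg.alpha) + beta[g]
    y = mu + sigma * rng.standard_normal(cfg.n)
    table = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(cfg.p)])
    table.insert(0, "y", y)
    table["group"] = [MAIN_LEVELS[i] for i in g]
    truth = {
        "alpha0": cfg.alpha0,
        "alpha": np.asarray(cfg.alpha),
        "beta": beta,
        "sigma": sigma,
        "mu": mu,
    }
    return table, truth


def true_theta(cfg: SimConfigMain, dm) -> np.ndarray:
    """Truth on the design-column parametrization (modifiers are zero)."""
    theta = np.zeros(dm.ncols)
    theta[0] = cfg.alpha0
    for j in range(cfg.p):
        theta[dm.column_index("continuous", continuous=f"x{j + 1}")] = cfg.alpha[j]
    for i, lev in enumerate(MAIN_LEVELS[: len(cfg.pi)]):
        theta[dm.column_index("dummy", categorical="group", level=lev)] = cfg.beta[i]
    return theta


# ---------------------------------------------------------------------------
# invariance design


def simulate_invariance(cfg: SimConfigInvariance, replicate: int = 0):
    """One dataset from the four-group mixture design.

    X | group: A -> 5 + N(0,1); B -> sqrt(12) * Uniform(0,1);
    C -> 5 + t4; D -> Gamma(1,1).  Response
    y = 1 + x + gamma*x*1{A} - gamma*x*1{B} + t4 error.
    """
    rng = _rng(cfg.seed, replicate)
    g = rng.choice(len(cfg.pi), size=cfg.n, p=np.asarray(cfg.pi))
    x = np.empty(cfg.n)
    a, b, c, d = (g == 0), (g == 1), (g == 2), (g == 3)
    x[a] = 5.0 + rng.standard_normal(a.sum())
    x[b] = np.sqrt(12.0) * rng.uniform(0.0, 1.0, b.sum())
    x[c] = 5.0 + rng.standard_t(4, c.sum())
    x[d] = rng.gamma(1.0, 1.0, d.sum())
    mu = 1.0 + x + cfg.gamma * x * a - cfg.gamma * x * b
    y = mu + rng.standard_t(4, cfg.n)
    table = pd.DataFrame(
        {"y": y, "x": x, "group": [INV_LEVELS[i] for i in g]}
    )
    truth = {"alpha0": 1.0, "alpha1": 1.0, "gamma": cfg.gamma, "mu": mu}
    return table, truth


INV_SPEC_MAIN = ModelSpec(
    outcome="y",
    continuous=("x",),
    categoricals=(("group", INV_LEVELS),),
)
INV_SPEC_MODIFIED = ModelSpec(
    outcome="y",
    continuous=("x",),
    categoricals=(("group", INV_LEVELS),),
    modifier_pairs=frozenset({("group", "x")}),
)


# ---------------------------------------------------------------------------
# experiments


@dataclass
class SimResult:
    """Long-format experiment results plus the generating config."""

    results: pd.DataFrame
    config: object
    errors: pd.DataFrame | None = None


def _fit_table(spec: ModelSpec, table: pd.DataFrame, scheme: str):
    dm = build_design(spec, table)
    dist = group_proportions(dm.labels)
    cs = build_constraints(dm, scheme, dist)
    return dm, dist, cs


def rmse_experiment(
    cfg: SimConfigMain,
    schemes: tuple[str, ...] = ("abc", "rge", "over"),
    estimators: tuple[str, ...] = ("ols", "ridge", "lasso"),
    cv_folds: int = 5,
    n_lambda: int = 30,
    lambda_ratio: float = 3e-3,
    tol_abs: float = 3e-5,
    tol_rel: float = 3e-3,
) -> SimResult:
    """Scheme-by-estimator RMSE comparison on the main-only design.

    Every cell fits the *modifier-including* model on the same replicate
    data; ridge/lasso tuning uses the one-standard-error rule.  RMSEs
    are reported for the regression coefficients, the group-specific
    slopes, and the fitted model expectations.  Fit errors are recorded
    per cell, not fatal.
    """
    spec = main_only_spec(cfg, modifiers=True)
    rows, err_rows = [], []
    for rep in range(cfg.n_reps):
        table, truth = simulate_main_only(cfg, rep)
        y = table["y"].to_numpy()
        for scheme in schemes:
            dm, dist, cs = _fit_table(spec, table, scheme)
            th_true = true_theta(cfg, dm)
            w = penalty_weights(dm)
            for est in estimators:
                if est == "ols" and scheme == SCHEME_OVER:
                    continue  # not identified for OLS
                try:
                    if est == "ols":
                        fit = fit_ols(dm, y, cs)
                    else:
                        grid = lambda_grid(
                            lambda_max(dm, y, cs, w), n=n_lambda, ratio=lambda_ratio
                        )
                        cv = cross_validate(
                            dm, y, cs, grid, w, K=cv_folds,
                            seed=cfg.seed * 100003 + rep, penalty=est,
                            tol_abs=tol_abs, tol_rel=tol_rel,
                        )
                        fit = fit_penalized(
                            dm, y, cs, est, cv.lambda_1se, w,
                            **({"tol_abs": tol_abs, "tol_rel": tol_rel}
                               if est == "lasso" else {}),
                        )
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    err_rows.append(
                        {"replicate": rep, "scheme": scheme, "estimator": est,
                         "error": str(exc)}
                    )
                    continue
                th = fit.theta_hat
                rmse_coef = float(np.sqrt(np.mean((th - th_true) ** 2)))
                # group-specific slopes alpha_j + gamma_{r,j} for all (r, j)
                slopes_hat, slopes_true = [], []
                for j in range(cfg.p):
                    jm = dm.column_index("continuous", continuous=f"x{j + 1}")
                    for lev in MAIN_LEVELS[: len(cfg.pi)]:
                        k = dm.column_index(
                            "interaction", continuous=f"x{j + 1}",
                            categorical="group", level=lev,
                        )
                        slopes_hat.append(th[jm] + th[k])
                        slopes_true.append(cfg.alpha[j])
                rmse_slope = float(
                    np.sqrt(np.mean((np.array(slopes_hat) - np.array(slopes_true)) ** 2))
                )
                rmse_fit = float(np.sqrt(np.mean((fit.fitted - truth["mu"]) ** 2)))
                rows.append(
                    {
                        "replicate": rep,
                        "scheme": scheme,
                        "estimator": est,
                        "rmse_coef": rmse_coef,
                        "rmse_slope": rmse_slope,
                        "rmse_fitted": rmse_fit,
                    }
                )
    return SimResult(
        results=pd.DataFrame(rows),
        config=cfg,
        errors=pd.DataFrame(err_rows) if err_rows else None,
    )


def invariance_experiment(
    cfg: SimConfigInvariance,
    schemes: tuple[str, ...] = ("abc", "rge", "stz"),
) -> SimResult:
    """Per-scheme (alpha1_main_only, alpha1_modified) pairs.

    For every replicate the main-only and modifier-including models are
    fitted on identical data under each scheme; the discrepancy
    |alpha1 - alpha1_main_only| measures estimation invariance.
    """
    rows = []
    for rep in range(cfg.n_reps):
        table, _ = simulate_invariance(cfg, rep)
        y = table["y"].to_numpy()
        for scheme in schemes:
            dm_m, dist, cs_m = _fit_table(INV_SPEC_MAIN, table, scheme)
            dm_x, _, cs_x = _fit_table(INV_SPEC_MODIFIED, table, scheme)
            fit_m = fit_ols(dm_m, y, cs_m)
            fit_x = fit_ols(dm_x, y, cs_x)
            a_m = fit_m.theta_hat[dm_m.column_index("continuous", continuous="x")]
            a_x = fit_x.theta_hat[dm_x.column_index("continuous", continuous="x")]
            rows.append(
                {
                    "replicate": rep,
                    "scheme": scheme,
                    "alpha1_main_only": a_m,
                    "alpha1_modified": a_x,
                    "discrepancy": abs(a_x - a_m),
                }
            )
    return SimResult(results=pd.DataFrame(rows), config=cfg)


def invariance_summary(res: SimResult) -> pd.DataFrame:
    """Per-scheme invariance summaries over replicates.

    ``slope_45`` is the least-squares slope of the line *through the
    origin* fit to the (alpha1_main_only, alpha1_modified) cloud — 1
    exactly when the points lie on the 45-degree line.  (A free-intercept
    regression slope is also reported; it is attenuated by the sampling
    noise shared between the two fits and is a weaker diagnostic.)
    """
    out = []
    for scheme, sub in res.results.groupby("scheme"):
        x = sub["alpha1_main_only"].to_numpy()
        z = sub["alpha1_modified"].to_numpy()
        slope_free = float(np.polyfit(x, z, 1)[0]) if len(x) > 1 else np.nan
        slope_45 = float(np.sum(x * z) / np.sum(x * x))
        out.append(
            {
                "scheme": scheme,
                "median_discrepancy": float(sub["discrepancy"].median()),
                "max_discrepancy": float(sub["discrepancy"].max()),
                "slope_45": slope_45,
                "regression_slope": slope_free,
            }
        )
    return pd.DataFrame(out)
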