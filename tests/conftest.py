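import numpy as np
import pandas as pd
import pytest

from abcreg import (
    ModelSpec,
    build_constraints,
    build_design,
    group_proportions,
)

THREE_LEVELS = ("A", "B", "C")


def random_table(
    rng: np.random.Generator,
    n: int = 60,
    p: int = 1,
    levels: tuple[str, ...] = THREE_LEVELS,
    noise: float = 0.3,
) -> pd.DataFrame:
    """Small random dataset: group-shifted covariates, linear outcome."""
    g = rng.integers(0, len(levels), size=n)
    X = rng.standard_normal((n, p)) + g[:, None] * 0.5
    beta = np.linspace(-1, 1, len(levels))
    y = 1.0 + X.sum(axis=1) + beta[g] + noise * rng.standard_normal(n)
    tab = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
    tab["y"] = y
    tab["group"] = [levels[i] for i in g]
    return tab


def spec_with_modifiers(p: int = 1, levels: tuple[str, ...] = THREE_LEVELS) -> ModelSpec:
    cont = tuple(f"x{j + 1}" for j in range(p))
    return ModelSpec(
        outcome="y",
        continuous=cont,
        categoricals=(("group", levels),),
        modifier_pairs=frozenset(("group", x) for x in cont),
    )


def spec_main_only(p: int = 1, levels: tuple[str, ...] = THREE_LEVELS) -> ModelSpec:
    return ModelSpec(
        outcome="y",
        continuous=tuple(f"x{j + 1}" for j in range(p)),
        categoricals=(("group", levels),),
    )


def prepared(table: pd.DataFrame, spec: ModelSpec, scheme: str):
    """(design, distribution, constraints) for a table under a scheme."""
    dm = build_design(spec, table)
    dist = group_proportions(dm.labels)
    cs = build_constraints(dm, scheme, dist)
    return dm, dist, cs


def equal_variance_table(
    rng: np.random.Generator,
    sizes: dict[str, int] = None,
    shifts: dict[str, float] = None,
    modifier: dict[str, float] = None,
    p: int = 1,
    noise: float = 0.2,
) -> pd.DataFrame:
    """Groups of unequal sizes whose within-group scaled (ddof=0)
    covariances of the continuous covariates are *exactly* equal:
    each group's covariate block is an exactly standardized draw, shifted
    by a group-specific location."""
    sizes = sizes or {"A": 30, "B": 70, "C": 50}
    shifts = shifts or {"A": 0.0, "B": 2.0, "C": -1.5}
    modifier = modifier or {"A": 0.8, "B": -0.5, "C": 0.2}
    beta = {g: b for g, b in zip(sizes, np.linspace(-0.4, 0.5, len(sizes)))}
    frames = []
    for g, n in sizes.items():
        B = rng.standard_normal((n, p))
        B = B - B.mean(axis=0)
        # exact whitening: equal ddof=0 covariance (identity) in every group
        cov = B.T @ B / n
        B = B @ np.linalg.inv(np.linalg.cholesky(cov)).T
        X = B + shifts[g]
        y = (
            1.0
            + X.sum(axis=1) * (1.0 + modifier[g])
            + beta[g]
            + noise * rng.standard_normal(n)
        )
        f = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(p)])
        f["y"] = y
        f["group"] = g
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


@pytest.fixture
def toy():
    """One modifier-including toy problem under each fixture request."""
    r = np.random.default_rng(7)
    table = random_table(r, n=60, p=2)
    spec = spec_with_modifiers(p=2)
    return table, spec
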