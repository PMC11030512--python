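import numpy as np
import pandas as pd
import pytest

from abcreg import (
    ModelSpec,
    build_design,
    fit_ols,
    fit_ols_kkt_oracle,
    group_proportions,
    variance_condition_diagnostic,
)
from abcreg.estimation import (
    coefficient_inference,
    group_specific_slopes,
    linear_combination,
)

from conftest import (
    equal_variance_table,
    prepared,
    random_table,
    spec_main_only,
    spec_with_modifiers,
)


def _noiseless_identity_table():
    # two equal-size groups, y == x exactly
    x = np.array([-2.0, -1.0, 0.5, 1.5, -0.5, 0.25, 2.0, -1.5])
    return pd.DataFrame(
        {"x1": x, "y": x, "group": ["A", "B"] * 4}
    )


class TestFitOLS:
    @pytest.mark.parametrize("scheme", ["abc", "rge", "stz"])
    def test_noiseless_identity(self, scheme):
        tab = _noiseless_identity_table()
        dm, _, cs = prepared(tab, spec_with_modifiers(levels=("A", "B")), scheme)
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        assert abs(fit.theta_hat[dm.column_index("continuous", continuous="x1")] - 1) < 1e-10
        others = [
            i for i, c in enumerate(dm.columns) if c.role in ("dummy", "interaction")
        ]
        assert np.max(np.abs(fit.theta_hat[others])) < 1e-10
        assert np.max(np.abs(fit.theta_hat[0])) < 1e-10

    @pytest.mark.parametrize("scheme", ["abc", "rge", "stz"])
    def test_matches_kkt_oracle_random_instances(self, scheme):
        rng = np.random.default_rng(123)
        for _ in range(100):
            tab = random_table(rng, n=40, p=2)
            dm, _, cs = prepared(tab, spec_with_modifiers(p=2), scheme)
            y = tab["y"].to_numpy()
            a = fit_ols(dm, y, cs)
            b = fit_ols_kkt_oracle(dm, y, cs)
            assert np.max(np.abs(a.theta_hat - b.theta_hat)) <= 1e-8
            assert a.constraint_residual() <= 1e-8

    def test_rge_main_only_equals_textbook_ols(self, rng):
        # dropping the reference dummy reduces RGE to plain OLS
        tab = random_table(rng, n=50, p=1)
        dm, _, cs = prepared(tab, spec_main_only(p=1), "rge")
        y = tab["y"].to_numpy()
        fit = fit_ols(dm, y, cs)
        keep = [
            i for i, c in enumerate(dm.columns)
            if not (c.role == "dummy" and c.level == "A")
        ]
        beta, *_ = np.linalg.lstsq(dm.X[:, keep], y, rcond=None)
        np.testing.assert_allclose(fit.theta_hat[keep], beta, atol=1e-8)
        assert abs(fit.theta_hat[dm.column_index("dummy", categorical="group", level="A")]) < 1e-12

    def test_over_not_identified(self, rng):
        tab = random_table(rng, n=30)
        dm, _, cs = prepared(tab, spec_with_modifiers(), "over")
        with pytest.raises(ValueError, match="not identified"):
            fit_ols(dm, tab["y"].to_numpy(), cs)

    def test_collinear_design_raises(self, rng):
        tab = random_table(rng, n=40, p=1)
        tab["x2"] = 2.0 * tab["x1"]  # exact collinearity
        spec = ModelSpec(
            outcome="y",
            continuous=("x1", "x2"),
            categoricals=(("group", ("A", "B", "C")),),
        )
        dm, _, cs = prepared(tab, spec, "abc")
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_ols(dm, tab["y"].to_numpy(), cs)

    def test_sigma2_and_cov_shape(self, rng):
        tab = random_table(rng, n=60, p=2)
        dm, _, cs = prepared(tab, spec_with_modifiers(p=2), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        assert fit.dof == 60 - (dm.ncols - cs.m)
        ssr = float(fit.residuals @ fit.residuals)
        assert abs(fit.sigma2_hat - ssr / fit.dof) < 1e-12
        evals = np.linalg.eigvalsh(fit.cov_theta)
        assert evals.min() > -1e-10  # PSD


class TestInference:
    def test_equal_proportions_give_equal_opposite_effects(self):
        # balanced two-level variable under ABCs: effects equal and
        # opposite with a shared SE
        rng = np.random.default_rng(5)
        n = 40
        x = rng.standard_normal(n)
        g = np.array(["M", "F"] * (n // 2))
        y = 0.3 * x + 0.5 * (g == "M") + rng.standard_normal(n)
        tab = pd.DataFrame({"x1": x, "y": y, "sex": g})
        spec = ModelSpec(
            outcome="y", continuous=("x1",), categoricals=(("sex", ("F", "M")),)
        )
        dm, _, cs = prepared(tab, spec, "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        t = coefficient_inference(fit)
        block = t[t["role"] == "dummy"]
        est = block["estimate"].to_numpy()
        se = block["se"].to_numpy()
        assert abs(est[0] + est[1]) < 1e-10
        assert abs(se[0] - se[1]) < 1e-12

    def test_ci_is_estimate_plus_minus_t_quantile(self, rng):
        from scipy import stats

        tab = random_table(rng, n=50)
        dm, _, cs = prepared(tab, spec_with_modifiers(), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        t = coefficient_inference(fit, level=0.95)
        q = stats.t.ppf(0.975, fit.dof)
        np.testing.assert_allclose(
            t["ci_upper"], t["estimate"] + q * t["se"], atol=1e-12
        )
        np.testing.assert_allclose(
            t["ci_lower"], t["estimate"] - q * t["se"], atol=1e-12
        )
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()

    def test_se_matches_monte_carlo_sd(self):
        # fixed design, 2000 Gaussian noise replicates: empirical SD of
        # theta-hat within 5% of the reported SE
        rng = np.random.default_rng(11)
        tab = random_table(rng, n=60, p=1)
        dm, _, cs = prepared(tab, spec_with_modifiers(p=1), "abc")
        mu = dm.X @ rng.standard_normal(dm.ncols) * 0.1
        sigma = 1.0
        fit0 = fit_ols(dm, mu + sigma * rng.standard_normal(60), cs)
        se_reported = np.sqrt(np.diag(fit0.cov_theta) / fit0.sigma2_hat) * sigma
        # vectorized refits across noise draws (linear estimator)
        Q = fit0.basis.Q
        Z = dm.X @ Q
        P = Q @ np.linalg.solve(Z.T @ Z, Z.T)  # theta-hat = P y
        Y = mu[:, None] + sigma * rng.standard_normal((60, 2000))
        thetas = P @ Y
        sd_emp = thetas.std(axis=1, ddof=1)
        ratio = sd_emp / se_reported
        assert np.all(np.abs(ratio - 1) < 0.05)

    def test_dof_guard(self, rng):
        tab = random_table(rng, n=50)
        dm, _, cs = prepared(tab, spec_with_modifiers(), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        fit.dof = 0
        with pytest.raises(ValueError, match="degrees of freedom"):
            coefficient_inference(fit)


class TestLinearCombination:
    def _printed_fit(self, estimates: dict[str, float]):
        """A fit object whose coefficients hold externally printed
        estimates (synthetic covariance), for arithmetic identities."""
        rng = np.random.default_rng(2)
        tab = random_table(rng, n=40, p=1, levels=("NHW", "NHB", "Hisp"))
        tab = tab.rename(columns={"x1": "RI"})
        spec = ModelSpec(
            outcome="y",
            continuous=("RI",),
            categoricals=(("race", ("NHW", "NHB", "Hisp")),),
            modifier_pairs=frozenset({("race", "RI")}),
        )
        tab["race"] = tab.pop("group")
        dm, _, cs = prepared(tab, spec, "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        theta = np.array(fit.theta_hat)
        for name, val in estimates.items():
            theta[[c.name for c in dm.columns].index(name)] = val
        fit.theta_hat = theta
        return fit, dm

    @pytest.mark.parametrize(
        "main, modifier, total",
        [(-0.032, -0.038, -0.070), (-0.020, -0.020, -0.040)],
    )
    def test_group_slope_from_printed_estimates(self, main, modifier, total):
        fit, dm = self._printed_fit({"RI": main, "RI:race=NHB": modifier})
        c = np.zeros(dm.ncols)
        c[dm.column_index("continuous", continuous="RI")] = 1.0
        c[dm.column_index("interaction", continuous="RI", categorical="race", level="NHB")] = 1.0
        lc = linear_combination(fit, c)
        assert abs(lc.estimate - total) < 1e-12

    def test_zero_weights(self, rng):
        tab = random_table(rng, n=40)
        dm, _, cs = prepared(tab, spec_with_modifiers(), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        lc = linear_combination(fit, np.zeros(dm.ncols))
        assert lc.estimate == 0.0 and lc.se == 0.0


class TestGroupSpecificSlopes:
    def test_rge_first_level_equals_main_effect(self, rng):
        tab = random_table(rng, n=60)
        dm, _, cs = prepared(tab, spec_with_modifiers(), "rge")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        t = group_specific_slopes(fit, "x1", "group")
        main = fit.theta_hat[dm.column_index("continuous", continuous="x1")]
        assert abs(t.loc[t["level"] == "A", "estimate"].iloc[0] - main) < 1e-12

    def test_slopes_identical_across_schemes(self, rng):
        tab = random_table(rng, n=60)
        y = tab["y"].to_numpy()
        slopes = {}
        for scheme in ("abc", "rge", "stz"):
            dm, _, cs = prepared(tab, spec_with_modifiers(), scheme)
            fit = fit_ols(dm, y, cs)
            slopes[scheme] = group_specific_slopes(fit, "x1", "group")["estimate"].to_numpy()
        for scheme in ("rge", "stz"):
            np.testing.assert_allclose(slopes[scheme], slopes["abc"], atol=1e-8)

    def test_non_modifier_pair_rejected(self, rng):
        tab = random_table(rng, n=40)
        dm, _, cs = prepared(tab, spec_main_only(), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        with pytest.raises(ValueError, match="not a modifier pair"):
            group_specific_slopes(fit, "x1", "group")


class TestVarianceDiagnostic:
    def test_location_shifted_copies_have_zero_summary(self):
        base = np.array([0.3, -1.2, 0.8, 1.1, -0.5, 0.1])
        x = np.concatenate([base, base + 2.0, base - 1.0])
        labels = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        gm = variance_condition_diagnostic(x, labels)
        assert gm.heterogeneity < 1e-12
        vals = [gm.scaled_cov[g][0, 0] for g in gm.groups]
        assert np.ptp(vals) < 1e-12

    def test_heterogeneous_sds_match_two_pass_oracle(self):
        rng = np.random.default_rng(9)
        sds = {"A": 0.7, "B": 1.0, "C": 1.3}
        x, labels = [], []
        for g, s in sds.items():
            v = s * rng.standard_normal(50)
            x.extend(v)
            labels.extend([g] * 50)
        x = np.array(x)
        gm = variance_condition_diagnostic(x, labels)
        assert gm.heterogeneity > 0
        for g in gm.groups:
            sub = x[np.array(labels) == g]
            two_pass = np.mean((sub - sub.mean()) ** 2)
            assert abs(gm.scaled_cov[g][0, 0] - two_pass) < 1e-12

    def test_pooled_moment_identity(self):
        # law of total variance on the empirical quantities
        rng = np.random.default_rng(4)
        x = rng.standard_normal(90)
        labels = np.repeat(["A", "B", "C"], 30)
        gm = variance_condition_diagnostic(x, labels)
        n = len(x)
        within = sum(gm.n_r[g] / n * gm.scaled_cov[g][0, 0] for g in gm.groups)
        between = sum(
            gm.n_r[g] / n * (gm.mean[g][0] - x.mean()) ** 2 for g in gm.groups
        )
        assert abs((within + between) - np.mean((x - x.mean()) ** 2)) < 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            variance_condition_diagnostic(np.ones(3), ["A", "A", "A"])


class TestEstimationInvariance:
    def test_equal_variance_invariance_p1(self, rng):
        # exactly equal within-group scaled variances, unequal group sizes
        tab = equal_variance_table(rng, p=1)
        y = tab["y"].to_numpy()
        diffs = {}
        for scheme in ("abc", "rge", "stz"):
            dm_m, _, cs_m = prepared(tab, spec_main_only(p=1), scheme)
            dm_x, _, cs_x = prepared(tab, spec_with_modifiers(p=1), scheme)
            am = fit_ols(dm_m, y, cs_m).theta_hat[1]
            ax = fit_ols(dm_x, y, cs_x).theta_hat[1]
            diffs[scheme] = abs(am - ax)
        assert diffs["abc"] <= 1e-8
        assert diffs["rge"] > 1e-3
        assert diffs["stz"] > 1e-3

    def test_equal_covariance_invariance_p3(self, rng):
        # multivariable version: equal within-group scaled covariance
        # matrices, all three main-effect estimates invariant under ABCs
        tab = equal_variance_table(rng, p=3)
        y = tab["y"].to_numpy()
        for scheme, bound, op in (("abc", 1e-8, "le"), ("rge", 1e-3, "gt")):
            dm_m, _, cs_m = prepared(tab, spec_main_only(p=3), scheme)
            dm_x, _, cs_x = prepared(tab, spec_with_modifiers(p=3), scheme)
            am = fit_ols(dm_m, y, cs_m).theta_hat[1:4]
            ax = fit_ols(dm_x, y, cs_x).theta_hat[1:4]
            gap = np.max(np.abs(am - ax))
            assert gap <= bound if op == "le" else gap > bound

    def test_abc_block_means_are_zero(self, rng):
        # the fitted coefficients themselves satisfy the abundance
        # constraints: weighted means of level and modifier blocks vanish
        tab = random_table(rng, n=80, p=2)
        dm, dist, cs = prepared(tab, spec_with_modifiers(p=2), "abc")
        fit = fit_ols(dm, tab["y"].to_numpy(), cs)
        marg = dist.marginal("group")
        w = np.array([marg[lev] for lev in ("A", "B", "C")])
        block = [
            dm.column_index("dummy", categorical="group", level=lev)
            for lev in ("A", "B", "C")
        ]
        assert abs(w @ fit.theta_hat[block]) < 1e-10
        for var in ("x1", "x2"):
            block = [
                dm.column_index(
                    "interaction", continuous=var, categorical="group", level=lev
                )
                for lev in ("A", "B", "C")
            ]
            assert abs(w @ fit.theta_hat[block]) < 1e-10


class TestUnbiasedness:
    def test_mean_estimate_within_monte_carlo_error(self):
        # fixed design, 500 Gaussian replicates
        rng = np.random.default_rng(17)
        tab = random_table(rng, n=100, p=2)
        dm, _, cs = prepared(tab, spec_with_modifiers(p=2), "abc")
        theta_true = np.zeros(dm.ncols)
        theta_true[0] = 1.0
        theta_true[1:3] = [1.0, -0.5]
        # project onto the constraint null space so the truth is feasible
        theta_true = theta_true - cs.C.T @ np.linalg.lstsq(cs.C.T, theta_true, rcond=None)[0]
        mu = dm.X @ theta_true
        sigma = 0.5
        B = 500
        Qb = fit_ols(dm, mu, cs).basis.Q
        Z = dm.X @ Qb
        P = Qb @ np.linalg.solve(Z.T @ Z, Z.T)
        Y = mu[:, None] + sigma * rng.standard_normal((100, B))
        thetas = P @ Y
        mean = thetas.mean(axis=1)
        mc_se = thetas.std(axis=1, ddof=1) / np.sqrt(B)
        assert np.all(np.abs(mean - theta_true) <= 3 * np.maximum(mc_se, 1e-12))
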