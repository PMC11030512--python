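# abcreg — abundance-based constraints for regression with effect modifiers

`abcreg` fits linear regressions in which the effect of continuous
covariates may be *modified* by categorical group membership (race, sex,
education level, ...), identified with **abundance-based constraints
(ABCs)** instead of the near-universal reference-group encoding (RGE).

## The problem

The model for an outcome *y* with continuous covariates
*x = (x₁, …, x_p)ᵀ* and categorical covariates *r = (r₁, …, r_L)* is

    μ(x, r) = α₀ + xᵀα + Σ_ℓ β_{ℓ, r_ℓ} + Σ_ℓ xᵀ γ_{ℓ, r_ℓ}

The level effects {β} and modifier effects {γ} are not identified: any
constant can be moved between α₀ and the β's (and between α_j and the
γ's) without changing the model. Software defaults resolve this by
zeroing one "reference" level (RGE), which makes every reported main
effect a reference-group effect, hides the reference level from the
output, biases shrinkage toward the reference group, and changes the
main-effect estimates when modifiers are added.

ABCs instead require the abundance-weighted level effects to vanish:

    Σ_r π̂_{ℓ,r} β_{ℓ,r} = 0,    Σ_r π̂_{ℓ,r} γ_{ℓ,r,j} = 0  for all j

with π̂ the (sample or population) group proportions. Under ABCs:

* each main effect α_j is the **group-averaged slope**
  α_j = Σ_r π̂_r (α_j + γ_{r,j});
* every level of every categorical variable gets its own coefficient —
  no hidden reference group;
* main-effect estimates are nearly **invariant** to adding modifiers
  whenever the within-group scaled (co)variances of x are similar
  across groups, so group-specific effects come "for free";
* shrinking a modifier to zero pulls a group toward the *average*
  slope, not toward a privileged group's slope.

Fitting uses the null-space reparametrization θ = Q₋ζ, where Q₋ is an
orthonormal basis of the null space of the constraint matrix C (from
the QR decomposition of Cᵀ), reducing constrained OLS — and penalized
variants — to unconstrained problems in m = Σ_ℓ(1 + p*_ℓ) fewer
parameters. Adaptive ridge has a closed form; the adaptive lasso on the
constrained parametrization is a generalized lasso solved by ADMM, with
per-column penalty weights equal to each design column's sample SD so
that low-abundance groups are not overpenalized.

## Worked example

Fit a group-modified model to a synthetic dataset in which the slope of
`x` is 1.5 in group A, 0.5 in group B, and 1 elsewhere:

```python
from abcreg import (ModelSpec, build_design, group_proportions,
                    build_constraints, fit_ols)
from abcreg.estimation import coefficient_inference, group_specific_slopes
from abcreg.presentation import format_coefficient_table
from abcreg.simulation import SimConfigInvariance, simulate_invariance

table, _ = simulate_invariance(SimConfigInvariance(n=500, gamma=0.5, seed=1), 0)
spec = ModelSpec(outcome="y", continuous=("x",),
                 categoricals=(("group", ("A", "B", "C", "D")),),
                 modifier_pairs=frozenset({("group", "x")}))
dm = build_design(spec, table)
dist = group_proportions(dm.labels)
cs = build_constraints(dm, "abc", dist)
fit = fit_ols(dm, table["y"].to_numpy(), cs)
print(format_coefficient_table(coefficient_inference(fit), fit,
                               pi_source=dist.source).to_text())
```

prints

```
Variable   Estimate (SE)     p-value
Intercept  1.101 (0.250)     <0.001
x          1.212 (0.059)     <0.001
group
  A        -0.117 (0.202)    0.562
  B        -0.352 (0.338)    0.298
  C        1.126 (0.719)     0.118
  D        -0.042 (0.337)    0.901
x x group
  x:A      0.303 (0.051)     <0.001
  x:B      -0.563 (0.129)    <0.001
  x:C      -0.480 (0.143)    <0.001
  x:D      -0.112 (0.154)    0.469

Scheme: ABC; n = 500; group proportions: sample.
```

Every group appears with its own coefficient, and the abundance-weighted
sums of the `group` and `x x group` blocks are zero. The `x` row, 1.212,
is the group-averaged slope: `group_specific_slopes(fit, "x", "group")`
returns the per-group slopes (A: 1.515, B: 0.648, C: 0.731, D: 1.100),
whose π̂-weighted average is 1.211695 — exactly the main effect. The
positive `x:A` and negative `x:B` modifiers recover the generating
γ = ±0.5 pattern.

The same pipeline is scriptable:

```sh
abcreg fit data.csv model.json --scheme abc --out results/
abcreg fit data.csv model.json --scheme abc --penalty lasso --lambda cv-1se
abcreg bench rmse --reps 100 --n 250 --seed 1
abcreg bench invariance --reps 100 --gamma 0.5 --seed 1
```

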