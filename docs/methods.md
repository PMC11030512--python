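# Methods

## Model and identification

The fitted model is a linear regression with continuous covariates
x ∈ ℝᵖ and L categorical covariates, in which any subset of
(categorical, continuous) pairs may interact:

μ(x, r) = α₀ + xᵀα + Σ_ℓ β_{ℓ,r_ℓ} + Σ_ℓ xᵀγ_{ℓ,r_ℓ}.

The expanded design keeps *every* level's dummy column and every
(level, continuous) interaction column, so each categorical variable's
dummy block sums row-wise to the intercept and the design is rank
deficient by exactly one direction per constraint row. Identification
is imposed as explicit linear constraints Cθ = 0, one row per
categorical variable for its dummy block and one per (categorical,
modified continuous) pair:

* **ABC** rows carry the abundance weights π̂_{ℓ,r} (sample joint
  proportions by default; a population table may be supplied). The
  marginal weights are derived from the stored joint table; with one
  categorical variable they coincide.
* **STZ** rows carry 1's, **RGE** rows a single 1 on the first level.
* **Over** imposes nothing (m = 0) and is estimable only with a
  penalty.

With all pairs interacted, m = L(1 + p); e.g. p = 10 and one 4-level
categorical gives a 55-column design and 44 identifiable parameters.

## Estimation and inference

Constrained OLS is computed through the QR decomposition of Cᵀ: the
trailing columns Q₋ of Q form an orthonormal basis of the null space of
C, and θ = Q₋ζ turns the constrained problem into unconstrained least
squares on Z = XQ₋. Exact finite-sample inference follows from
θ̂ = Q₋ζ̂: with iid Gaussian errors, θ̂ ~ N(θ, σ²Q₋(ZᵀZ)⁻¹Q₋ᵀ), with
σ̂² = SSR/(n − dim ζ). Degrees of freedom use the identifiable
dimension dim ζ = (#columns − m), matching the reparametrized fit.
Correctness of the solver is defined by contracts, not by a particular
QR sign convention: Cθ̂ = 0 to 1e-8, invariance of θ̂ to rotations,
permutations, and sign flips of the null-space basis, and agreement to
1e-8 with an independent bordered-KKT solve
[[XᵀX, Cᵀ], [C, 0]][θ; ν] = [Xᵀy; 0] used only in tests.

Collinearity is detected on Z via its singular values; a reciprocal
condition number below 1e-12 raises an error rather than returning a
pseudoinverse solution. The Over scheme raises "not identified for
OLS". Rank checks on C use a relative singular-value tolerance of
1e-10.

Under ABCs two algebraic identities hold for the *estimates* and are
asserted in the suite: each categorical (and modifier) block has zero
abundance-weighted mean, and each main effect equals the π̂-weighted
average of the group-specific slopes α̂_j + γ̂_{r,j}.

### Estimation invariance

Adding modifiers leaves the main-effect estimates unchanged, under
ABCs, when the within-group *scaled* covariances
σ̂_x[r](j,h) = n_r⁻¹ s_r(j,h) − x̄_r(j) x̄_r(h) are equal across
groups. `variance_condition_diagnostic` reports these moments and a
heterogeneity summary (maximum relative elementwise deviation from the
first group; 0 iff the condition holds exactly). On data constructed to
satisfy the condition exactly — per-group covariate blocks whitened to
identical ddof-0 covariance, then location-shifted, with *unequal*
group sizes so that the unweighted sum-to-zero scheme does not
accidentally coincide with ABCs — the observed ABC discrepancy is at
floating-point level (≤1e-8 asserted; ~1e-14 observed), while RGE and
STZ move by >1e-3 whenever a modifier effect is present.

## Penalized estimation

The penalty is P(θ) = Σ_j ω_j |θ_j|^δ on the full design-column
coefficients with δ = 2 (adaptive ridge) or δ = 1 (adaptive lasso), and
ω_j the sample SD of design column j (ω = 1 for the intercept).
Group-level coefficients scale inversely with group abundance, so the
SD weights prevent overpenalizing low-abundance groups. The intercept
is penalized (ω₁ = 1) by design; `--no-penalize-intercept` switches
this off for users who prefer the more common convention.

* **Ridge** uses the closed form
  θ̂(λ) = Q₋(ZᵀZ + λDᵀD)⁻¹Zᵀy with D = diag(ω^{1/2})Q₋, verified in
  tests against an independent BFGS minimization of the objective.
* **Lasso** in ζ is a *generalized* lasso (the ℓ₁ norm acts on Q₋ζ).
  It is solved by ADMM with the splitting θ = Q₋ζ: the ζ-update is a
  cached Cholesky solve of (2ZᵀZ + ρI) (Q₋ᵀQ₋ = I), the θ-update a
  weighted soft-threshold, with residual-balancing ρ adaptation and
  warm starts along the decreasing λ grid. Reported coefficients are
  Q₋ζ̂, so constraints hold exactly along the entire path; sparsity is
  a numerical-zero notion at the solver tolerance. Solutions satisfy
  the KKT stationarity condition of the generalized lasso, checked by a
  linear program over admissible subgradients (≤1e-5 relative at the
  test tolerances; ~1e-15 observed at tight tolerances). Iteration caps
  raise an error carrying λ and the final primal/dual residuals.
* **λ grid**: 100 log-spaced values by default from λ_max — the exact
  smallest λ with an all-zero solution, computed by a small LP from the
  KKT condition at ζ = 0 (min over constraint multipliers ν of
  max_j |(2Xᵀy + Cᵀν)_j|/ω_j) — down to 10⁻⁴λ_max.
* **Cross-validation**: K = 10 by default, folds stratified by the
  joint categorical label (shuffled round-robin within group) so every
  training split retains every level; groups with a single observation
  raise an error. Validation error is MSE on the raw outcome scale. The
  one-SE rule picks the largest λ whose mean CV error is within one
  standard error (over fold means) of the minimum.

## Simulation designs

**Main-effects design** (`SimConfigMain` defaults): n = 250, p = 10;
X₁..₃, X₆..₈ ~ N(0,1) independent; X₄, X₅, X₉, X₁₀ | group r ~ N(r, 1);
group proportions π = (0.15, 0.35, 0.15, 0.35); truth α₀ = 1,
α₁..₅ = 1, α₆..₁₀ = 0, β = (0, 1, 0, −1) — satisfying both the
reference-group (β₁ = 0) and abundance (Σπ_rβ_r = 0) identifications so
no scheme is favored; Gaussian noise with σ² = Var(μ)/SNR at SNR = 1.
Var(μ) is computed analytically (independent covariates contribute
Σα_j²; the group-dependent block and level effects contribute
s₂ + Var_π(r·s₁ + β_r) with s₁, s₂ the sum and sum of squares of their
α's) and is verified against Monte Carlo within 1%. Datasets are
redrawn whole until every group has ≥ p + 1 rows (cap 1000 attempts).
Estimation always uses the *sample* proportions.

The RMSE experiment fits the modifier-including (hence overparametrized
relative to the truth) model in every scheme × estimator cell on
identical replicate data, tunes ridge/lasso by the one-SE rule, and
reports RMSEs for the coefficients, the group-specific slopes, and the
fitted expectations. Inside the experiment harness, cross-validation
uses 5 folds, a 30-point grid down to 3·10⁻³λ_max, and ADMM tolerances
of 3·10⁻⁵/3·10⁻³ — desk-scale settings chosen so a 100-replicate
comparison completes in minutes on one core; the selected λ values
match the library-default settings on spot checks, and the compared
medians are insensitive to these knobs. The library defaults (K = 10,
100-point grid) remain as stated above.

**Invariance design** (`SimConfigInvariance`): groups {A, B, C, D} with
π = (0.55, 0.20, 0.10, 0.15); X | group is 5 + N(0,1), √12·U(0,1),
5 + t₄, or Gamma(1,1); response y = 1 + x + γx·1{A} − γx·1{B} + t₄
error with γ ∈ {0, 0.5, 1.5}. The uniform component is scaled by √12 so
its population variance is 1; note the t₄ component's variance is 2,
not 1, so the four group variances are *not* all equal in population —
the design is used as a robustness check with mild, random violations
of the equal-variance condition, heavy-tailed errors, and no scheme's
constraints satisfied by the truth. For each replicate the main-only
and modifier-including models are fitted on the same data under ABC,
RGE (reference A), and STZ, recording the two x-effect estimates.

The "45-degree line" summary is the least-squares slope of the line
*through the origin* fitted to the (α̂₁ᴹ, α̂₁) cloud, which equals 1
exactly when the points lie on the diagonal. A free-intercept
regression slope is also reported but is attenuated by the sampling
noise shared between the two fits and does not separate the schemes;
the through-origin slope does (ABC stays within 0.05 of 1 at all γ;
RGE ≈ 1.3 and STZ ≈ 0.87 already at γ = 0.5).

## What the generators do and do not emulate

The generators reproduce the stated covariate laws, group structures,
truth coefficients, and noise calibrations, including group-dependent
covariate means and heavy-tailed errors. They do not emulate features
of observational cohorts such as missing data, measurement error,
nonlinear effects, correlated covariates beyond the shared group
dependence, or categorical × categorical interactions. Passing tests
therefore demonstrate the identification, invariance, and accuracy
properties of the estimators under the stated designs — not robustness
to those unmodeled features.

## Numerical choices and scale

* Rank/collinearity tolerances: 1e-10 (relative singular value on C),
  1e-12 (reciprocal condition number on Z).
* Replicate counts at desk scale: 100 (RMSE and invariance
  experiments, parameter recovery), versus 500 in the library defaults
  of the config objects; 2000 noise draws for the Monte-Carlo SE check.
* Determinism: every generator is a pure function of (config, seed,
  replicate index) via `SeedSequence([seed, replicate])`; CV folds are
  reproducible from their seed.
* Ties/degenerate inputs: zero-count levels are rejected (or dropped on
  request, logged); missing values are rejected, never imputed; a
  zero-SD continuous column is an error when standardizing, as is a
  zero-SD penalized column.
* Level order is taken from the spec when supplied, otherwise
  lexicographic in the observed labels. Standardization (when enabled)
  centers and scales by the sample SD computed on the final analysis
  table, before interaction columns are formed.

## Known limitations

* Only continuous × categorical interactions; no categorical ×
  categorical interactions or basis expansions.
* Gaussian-error exact inference only; no sandwich/robust SEs or
  weighted least squares.
* No formal inference after penalized fits (point estimates only).
* The Over scheme is supported only under penalization, and its
  estimates remain non-identified quantities — comparisons against it
  use the fixed generating truth.
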