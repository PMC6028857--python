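# Methods

## Model

The MR-DoC model couples an instrumental-variable regression to the
bivariate classical twin design.  Each trait loads on latent additive
genetic (A), shared environment (C) and unique environment (E) factors of
unit variance; all scale is carried by the path coefficients
`a_x..e_y`.  The polygenic score enters as a standardized latent variable
with paths `b1` (to the exposure) and `b2` (directly to the outcome, the
pleiotropy path); `x` is the standard deviation of the observed score.
The causal paths are `g1` (X→Y) and optionally `g2` (Y→X); the reciprocal
variant is solved through the reduced form `(I − B)^{-1}`, and the MR-DoC
working models fix `g2 = 0`.

Cross-twin structure: A factors correlate 1 (MZ) / 0.5 (DZ) within trait
and `ra` / `0.5·ra` across traits; C factors correlate 1 within trait and
`rc` across traits in both zygosities; E factors are uncorrelated across
twins; the polygenic score correlates 1 (MZ) / 0.5 (DZ) across co-twins
(random mating, purely additive score).  Phenotypic means carry no
information about these parameters and are excluded: all fitting is on
covariance structure.

**The MZ singularity.**  Because MZ co-twins carry identical genotypes,
the model-implied 6×6 MZ covariance matrix of
`(PGS1, X1, Y1, PGS2, X2, Y2)` is singular by construction — the PGS2 rows
duplicate the PGS1 rows exactly.  The normal-theory discrepancy needs a
positive-definite implied matrix, so estimation reduces the MZ group to
the 5-variate system `(PGS, X1, Y1, X2, Y2)`.  This is lossless for the
model (and for exact-simulated data); for real data where the two measured
scores differ by genotyping noise the duplicate column is simply dropped.
Identification analysis, which only differentiates the moment map, keeps
all 42 stacked moments (21 MZ + 21 DZ); duplicated rows add no rank.

Sign convention: `a, c, e` path coefficients and `x` enter the covariance
only through squares and products with the cross-trait correlations, so
their signs are not identified; they are constrained nonnegative during
estimation and reported as such.

## Estimation

Multi-group maximum likelihood minimizes

```
F(θ) = Σ_g N_g [ ln det Σ_g(θ) + tr(S_g Σ_g(θ)^{-1}) − ln det S_g − p_g ]
```

with `S_g` the (n−1)-divisor sample covariance and `N_g` the pair count.
`F` is the likelihood-ratio statistic against the saturated model
(saturated fit ⇒ 0), so differences of minimized `F` between nested fits
are chi-square statistics, and exact-data fits recover generating
parameters with zero misfit.  The same divisor is used in simulation and
fitting so this identity is exact rather than asymptotic.

Optimization is bounded L-BFGS-B (paths and `x` ≥ 0, correlations in
(−1, 1)) with convergence tolerance 1e−12 on `F`.  A solution counts as
converged when refitting from it changes `F` by < 1e−8 (guarding against
line-search failures at an exact optimum).  The 12–13-parameter surface
has genuinely distinct local optima — constrained null models fitted far
from their generating values are especially prone — so fits explore
multiple starting points: the caller-supplied start, a moment-based start
(sample SD for `x`, first-stage slope for `b1`, instrument-ratio estimate
for `g1`, Falconer-style ACE decompositions of the cross-twin covariances
for the path coefficients), a mid-range heuristic (paths 0.5, correlations
0), and jittered/random restarts.  Cold fits default to 12 starts; warm
fits to one.  Null fits inside power and type-I-error loops use extra
starts, and the likelihood-ratio machinery refits the fuller model from
the null solution whenever an ordering violation reveals a stalled
optimum.

Standard errors come from the numerical Hessian of `F` at the optimum
(`vcov = 2 H^{-1}`, since `F` differs from −2 log L by a constant); the
Wald z is estimate/SE.

## Scenario bookkeeping

Power scenarios are declared on the reduced-form regression scale with
Var(X) = Var(Y) = 1: instrument strength `b1² = instrument_r2`, residual
correlation `r` between the regression residuals of X and Y, pleiotropy
path `b2`, and total explained outcome variance fixed at 10% (so
`σ²_ξY = 0.90`).  The causal path solves

```
g1² + b2² + 2 g1 b1 b2 + 2 g1 σ_ξXξY = total_r2_y ,
σ_ξXξY = r √((1 − b1²) σ²_ξY)
```

taking the positive root.  The explained variance splits into five
path-tracing components (`g1²b1²`, `g1²σ²_ξX`, `b2²`, `2g1b1b2`,
`2g1σ_ξXξY`) plus residual.

Mapping to twin parameters: ACE proportions are interpreted as fractions
of each trait's *residual* variance (`1 − b1²` for X, `σ²_ξY` for Y) and
converted to path coefficients, which keeps the traits standardized.  The
residual covariance must be allocated across the latent channels
(`ra·a_x·a_y + rc·c_x·c_y + re·e_x·e_y = σ_ξXξY`); the default rule
divides it proportionally to the channel path products (making the channel
correlations equal), with `a_only` / `c_only` alternatives.  This
allocation is a genuine free choice — the implied trivariate moments, and
hence everything standard MR sees, are invariant to it, while twin-model
NCPs shift by a few percent between rules.

Instrument-strength variation across power-grid cells
(`vary_instrument_strength`) rescales `b1` holding the residual generating
structure, `g1` and `b2` fixed, so the score explains the requested share
of the resulting Var(X).  Under this variation the power to detect `g1` in
the pleiotropic model is exactly invariant to instrument strength: with
`b2` estimated, the instrument channel carries no information about `g1`,
which is identified entirely through the (unchanged) non-instrument
channels.  If instead `g1` is re-solved from the budget at fixed `b2`, the
NCP shifts by the ratio of residual exposure variances (≈ 5% between 5%
and 10% instruments).

## Simulation

`exact_mvn_sample` draws normal deviates, centers them, whitens them by
the Cholesky factor of their own sample covariance, and colors them by an
eigen-factor of the target, so the (n−1)-divisor sample covariance equals
the target to ~1e−12.  Rank-deficient targets (the MZ matrix) are handled
by factoring on the positive eigenspace; `n` must exceed the target's
rank.  Exact mode makes ML parameter recovery an algebraic identity and is
the basis of the NCP computations; random mode draws ordinary multivariate
normals for Monte-Carlo studies.  "2000 twin pairs" is read as 1000 MZ +
1000 DZ by default; both counts are explicit arguments everywhere.

The generator emulates bivariate normal twin data with zero means, equal
means/variances across twins and zygosities, no missingness, no
ascertainment, and a perfectly additive, measured polygenic score.  Real
data violate most of these in small ways (non-normality, scale
differences, sibling interaction, assortative mating, noisy scores), so
passing tests certify the estimator and power machinery on the model's own
terms, not robustness to those violations.

## Power and type-I error

The NCP of a likelihood-ratio test is computed in the classical SEM way:
population (exact) covariance matrices are treated as data at the target
sample sizes, the true model is fitted (zero misfit, checked against a
1e−6 guard), the tested parameters are dropped, and the null misfit is λ.
Power is `P(χ²(df, λ) > central critical value)`.  λ is exactly linear in
the group sizes.

Equivalent standard-MR sample sizes divide a target λ by the
per-individual NCP λ₁ of dropping `g1` in the trivariate MR-as-SEM model
(just-identified: `x, b1, g1`, residual variances and covariance) fitted
to the implied `(PGS, X, Y)` moments.  λ₁ agrees with the closed-form
2SLS approximation `R²_GX g1²/(1 − R²_GX g1²)` to well under 5%.

Type-I error is estimated by full Monte Carlo: random-mode simulation
under `g1 = 0`, full and constrained fits per replicate, empirical
rejection rate with an exact binomial CI.  The default of 1000 replicates
at 2000 pairs keeps the study at desk scale; non-convergent replicates are
excluded and reported (none observed in calibration runs, which give
rates ≈ 0.057 at α = .05 and ≈ 0.005 at α = .01).

## Numerical choices and limitations

- Jacobian rank for identification: central differences (step 1e−6),
  rank threshold 1e−8 × largest singular value, 5 random admissible points
  per verdict (paths in (0.2, 0.9), correlations in (−0.6, 0.6), `x` in
  (0.5, 2)).  Identification is generic, so agreement across points and
  seeds is required and observed.  A constraint that orphans another free
  parameter (e.g. fixing `c_y = 0` while leaving `rc` free, which then
  multiplies nothing) correctly reports a rank deficiency.
- The trivariate MR-as-SEM with both `b2` and the residual covariance free
  is not identified; `mr_sem_fit` refuses `pleiotropy_free=True` unless
  the residual correlation is fixed.
- 2SLS and the ratio of coefficients are implemented in closed form for
  the single-instrument case (they are algebraically identical there);
  multi-instrument MR, MR-Egger and median estimators are out of scope.
- Binary traits, means/threshold models, missing data (FIML), dominance,
  sex limitation, assortative mating and G×E are out of scope.
- Supplementary-grade power grids depend on the residual-covariance
  allocation rule; the package reproduces their qualitative structure
  (orderings and monotonicities) exactly and their cell values to a few
  percent under the default proportional rule.
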