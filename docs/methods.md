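# Methods

## Model structure and assumptions

Two closely related animal species share a habitat of area S.  Males of
each species indiscriminately direct mating attempts at females of both;
heterospecific attempts reduce female fecundity (reproductive interference)
without hybridization.  Costs to the interfering males themselves are
assumed negligible (operational sex ratios are typically male-biased), only
heterospecific males harm females, organisms are polygamous and
non-territorial, and no other interspecific interaction (resource
competition, hybridization) is modelled.

The two-sex formulation tracks F_i and M_i with births allocated at a fixed
sex ratio s_i; because both sexes share mortality and crowding, the pair of
equations collapses to a single total-density equation at the consistent
split F = (1−s)N, and the package treats the single-equation form as
primary (a property test keeps the two consistent).

The per-female rate of heterospecific mating attempts is derived from a
type II functional response: males of species j with searching efficiencies
e_ij, e_jj and handling times h_ij, h_jj divide their time between
searching and handling females of both species.  The mate-search period
cancels and is not a parameter.  Fecundity declines exponentially with the
attempt rate, B = B₀·exp(−α·I).  Only the products a = α·e_ij,
b_ij = e_ij·h_ij, b_jj = e_jj·h_jj are identifiable from dynamics, and the
package stores those three; `compose_interaction` maps mechanistic
components onto them, and an equivalence test holds the two parameterizations
together to machine precision.

The interference exponent depends on absolute density, not just frequency:
rescaling both densities by k > 1 strictly lowers the birth rate whenever
a > 0, N_j > 0.  At very high density the exponent converges to a function
of the species ratio alone, recovering frequency dependence as a limit.
The conventional comparison model B = B₀·s_iN_i/(s_iN_i + i·s_jN_j) is
exactly frequency-dependent at all densities.

## Parameters

| symbol | meaning | units | typical default |
|---|---|---|---|
| B₀ | intrinsic birth rate | offspring · female⁻¹ · time⁻¹ | 20 (reference demography) |
| s | fraction of males | — | 0.5 |
| D | density-independent mortality | time⁻¹ | 2 |
| H | conspecific crowding coefficient | time⁻¹ · density⁻¹ | 0.1 |
| S | habitat area | area | 1 |
| a | interference efficiency (α·e_ij) | area · time⁻¹ | fitted |
| b_ij, b_jj | dilution coefficients (e·h) | area | fitted |
| i | conventional interference coefficient | — | fitted |

The reference demography (B₀, s, D, H, S) = (20, 0.5, 2, 0.1, 1) gives a
single-species carrying capacity K = 80 and is used throughout the
phase-plane tests and examples; all qualitative regimes are reachable from
it by varying a, b_ij, b_jj (or i).

## Phase-plane analysis

Isoclines use the closed forms obtained by solving the per-capita bracket
for N_j: grid points where the logarithm's argument is non-positive, the
denominator vanishes, or N_j < 0 are dropped, never extrapolated.  Two
degenerate branches are handled explicitly: a = 0 (or s_j = 0) yields the
vertical line N_i = K, and b_jj(1−s_j) = 0 yields an explicit linear-in-L
branch.  The printed invasion-threshold inequality and intercept use the
heterospecific dilution coefficient b_jj; a numeric oracle (sign of
per-capita growth of a vanishing invader against a resident at 10⁶·S)
confirms this choice across random parameter draws.

Equilibria are found by scanning a grid (default 200², box [0, 2K]²) of
both per-capita growth fields for sign-change cells, refining candidates by
2-D root iteration (Powell hybrid, Levenberg–Marquardt fallback), and
always appending the origin and single-species capacities.  Points are
deduplicated within 10⁻⁴ of the box size and must re-evaluate to
|growth| < 10⁻⁶ (scaled).  Stability comes from a finite-difference
Jacobian (central, one-sided on the axes), labelled by eigenvalue real
parts with tolerance 10⁻⁷.  At the origin the conventional model's
linearization is direction-dependent; the along-axis derivative is used and
this limitation is documented rather than hidden — regime flags that depend
on low-density behaviour are computed from explicit low-density growth
evaluations instead.

Regime flags: `origin_positive_growth` evaluates both species' per-capita
growth at an ε-dense state; `priority_effect_present` requires at least two
attractors of which one is a single-species exclusion state;
`bistable_coexistence` requires two stable interior equilibria.  Regime
boundaries are detected by scanning, not continuation.

## Dynamics

Continuous trajectories use `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁸,
atol 10⁻¹¹) with terminal extinction events: when a species' total crosses
the absorbing threshold ε = 10⁻⁹ (configurable) it is pinned to zero and
integration restarts, making the axes exactly invariant.  Discrete maps are
iterated with a synchronous update (both species read the generation-t
state; the per-species map equations do not dictate an order, and the
choice is documented).  Negative discrete-map outputs — possible when H·N
is large — are clamped to zero; the fitting application sets H = 0, so the
clamp never binds there.  Outcome classification labels a trajectory
`coexistence` only when both species persist *and* the terminal state has
settled (|dN/dt| below a scaled tolerance); otherwise `undecided` is
returned rather than guessed.

## Fitting

Dish-level total fecundity y_k is modelled as Gaussian with mean given by
the one-generation map (focal sex ratio 1/2, all-male interferers, S = 1,
H = 0) and variance σ²·n_pairs.  σ² is profiled analytically
(σ̂² = n⁻¹Σ(y−μ)²/F) inside the objective, which makes the optimization a
4- (generalized) or 3-parameter (conventional) problem; a test verifies the
profiled optimum matches joint optimization to <10⁻⁶ in log-likelihood.
σ² is counted as an estimated parameter: k = 5/4 for AIC and residual
degrees of freedom n − 5 for the F comparison.  R(d) = R₀ + c·d must stay
positive over the observed dates; violating parameter points receive a
smooth penalty.

Optimization is bounded L-BFGS-B from 20 seeded multi-starts (default):
R₀ from the per-female mean of the no-interferer dishes, c near zero,
interference parameters log-uniform on [10⁻³, 1].  The surface is only
mildly multimodal; in Monte-Carlo loops 6 starts give identical optima and
are used for speed.

The two families are not strictly nested.  The F comparison is the
extra-sum-of-squares statistic on weighted residuals (y−μ)/√n_pairs with
df₁ = 1 (the families differ by one mean parameter) — a reporting
convention, not a claim of exact nesting; a chi-square likelihood-ratio
variant is provided.  An H-estimating fit is deliberately not exposed as a
default: conspecific crowding is negligible over the design's density range
and is switched off for fitting.

## Synthetic data

The generator reproduces the experimental design the inference module
assumes: a full factorial of 1–10 focal pairs × 0–10 heterospecific males
(110 cells), 3 replicates (330 dishes), dated over a 1,166-day window —
uniformly at random by default (the real assignment rule being unknown, a
"sorted" batch schedule is available).  Egg totals are drawn from the
model's own Gaussian noise law, truncated at zero with a reported count
(truncation preserves the likelihood's form and is rare at realistic
noise), and kept continuous (a rounding flag exists).  An optional rule
adds a fourth replicate to any zero-egg cell, mirroring a dish-failure
protocol.

The per-female variance scale defaults to σ² = 100 — an SD of 10 eggs for
a single-female dish, CV ≈ 17% at a baseline fecundity of ~58 eggs —
chosen as a realistic moderate dispersion for seed-beetle fecundity.  The
reference mean parameters for simulation studies are the beetle-experiment
estimates (R₀, a, b, c) = (58.3, 0.119, 0.275, 0.0162) and
(R₀, i, c) = (57.4, 0.272, 0.0156).

What the generator does **not** emulate: individual mating encounters,
overdispersed or integer egg counts, within-cell batch effects, or any
conspecific density dependence of fecundity.  Passing recovery and
discrimination tests therefore show the pipeline is correct and
well-calibrated *under the model's own assumptions*, not that real dish
data satisfy those assumptions.

## Problem sizes and numerical choices

Monte-Carlo studies (parameter recovery, AIC discrimination) use 50
replicate experiments at the full 330-dish design, which the package's own
tests and acceptance script run end to end; median relative recovery
errors are ~1% (R₀) to ~10% (b), and the generating family wins the AIC
contest in ≳90% of replicates in both directions.  Root-finding and
equilibrium tolerances (10⁻⁸ per-capita, 10⁻⁶ re-evaluation, 10⁻⁴·box
deduplication) sit far below biologically meaningful resolution.

## Known limitations

- Stability at the conventional model's origin is direction-dependent and
  only the axis-based linearization is reported.
- Very small interior saddles (below grid resolution near the origin) can
  be missed by the default 200² scan; raising `grid_density` finds them.
- The F-statistic convention (σ² counted in residual df) is one defensible
  choice among several; AIC conclusions do not depend on it.
- Isocline branches approaching vertical asymptotes produce very large
  N_j values that are mathematically valid but biologically irrelevant;
  consumers should window them.
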