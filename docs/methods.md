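# Methods

This note records the model choices, numerical conventions and design
decisions behind `genbayes`, in the order a reader meets them.

## The update rule and its representation

Beliefs about a parameter θ are updated by

    ν(θ) ∝ exp{ −w · Σᵢ l(θ, xᵢ) } π(θ),   w > 0,

the minimizer of ∫Σl dν + KL(ν‖π) over probability measures. The package
treats this as the primitive operation; everything else is either a way of
choosing w or an application with a particular loss.

**Grids and particles.** One- and two-dimensional parameters use a dense
rectangular grid; the default 1-D prior grid has 2048 points spanning the
prior mean ± 8 prior standard deviations, which carries all but ~1e-15 of
Gaussian prior mass. Densities are stored as logs; normalization uses
composite-trapezoid quadrature (weight-sum for particle clouds) through a
log-sum-exp, so the normalizer of `exp{−w·Σl}·π` can neither overflow nor
underflow for finite losses. A single-point grid is a point mass and is
returned unchanged by any update, the degenerate limit of the rule. Loss
values of +∞ encode hard constraints (zero posterior density); −∞ is
rejected as an error.

**Quadrature accuracy.** Trapezoid integration on a 2048-point grid is
accurate to roughly 1e-7 for smooth integrands; tests that compare the
update against conjugate closed forms therefore normalize the analytic
density by the same rule on the same grid, so that what is tested is the
update (exact up to floating rounding) and not the quadrature. Quantities
that are *defined* as integrals (the prior complexity, the unit-information
denominator) use finer grids (2^15 points) where the stated precision
requires it.

## Calibrating the loss weight

* **Unit information.** w = E_π[log π(θ̂)/π(θ)] / E_m[l(θ, x)], with the
  loss standardized so min_θ l(θ, x) = 0 per datum. The numerator is 1/2
  for any normal prior, 0 for a flat prior (for which the scheme is
  refused), 1 for an exponential prior. The denominator is computed by
  nested quadrature when the joint belief m supplies a conditional density
  and x-grid, otherwise by Monte Carlo with a reported standard error. Per-
  datum minima come from a grid scan with three-point parabolic refinement
  (exact for quadratic losses) plus bounded scalar minimization to 1e-10
  where cheap.
* **Empirical unit information.** The expected loss is estimated by
  n⁻¹ Σᵢ l(θ̂₋ᵢ, xᵢ) with θ̂₋ᵢ the leave-one-out cumulative-loss
  minimizer; the pairs (θ̂₋ᵢ, xᵢ) act as draws from the joint belief. For
  n ≤ 2000 each minimizer is polished by bounded minimization (ties broken
  toward the smaller θ by the scan order); beyond that the grid/parabola
  estimate alone is used, which is accurate far beyond the few-percent
  level the estimator itself carries. For squared loss on data of variance
  σ² the estimate converges to 1/(2σ²).
* **Hierarchical.** w is given the scale loss ξ·log(w), yielding the joint
  density ∝ w^ξ exp{−w·L(θ)} π(θ, w) on a (θ, w) grid. With a Gamma(a, b)
  prior slice at fixed θ the w-conditional is Gamma(a + ξ, b + L), which
  the tests verify.
* **Operational / Bayes factor.** At design points where the loss
  difference statistic S has the F₁,ₙ₋₁(1−α) value (a confidence interval
  touching the null), an elicited posterior-to-prior odds BF ∈ (0, 1]
  fixes w = −log(BF)/S. Note S *decreases* toward the χ²₁ limit as n
  grows, so w increases with n at fixed BF.
* **Coverage matching.** w is chosen on a grid (default 25 log-spaced
  points over four decades) so the equal-tailed central (1−α) posterior
  interval attains 1−α Monte-Carlo coverage of the generating θ₀;
  datasets are shared across the grid (common random numbers) and a
  warning flag is raised when no grid point is within 3 binomial SEs of
  the target. Equal-tailed intervals are a convention; nothing in the
  construction fixes the interval type.
* **Conjugate.** A prior expressible as exp{−Σλⱼ l(θ, μⱼ)} worth m
  observations gives w/Λ = 1/m with Λ = Σλⱼ.

## Survival: the partial likelihood as a loss

The loss is the **negative** log partial likelihood — small loss must mean
good fit for exp{−l} to reward it — with the sum over observed events only
and Breslow handling of ties (tied events share the full joint risk set;
this keeps the loss smooth and matches standard reference
implementations). The implementation sorts subjects by decreasing time and
accumulates running log-sum-exp/cumulative sums, giving O(n·p²) loss,
gradient and Hessian with a max-shifted linear predictor so weights never
overflow. It agrees with lifelines' partial log-likelihood to ~1e-12.

Because the loss is a (partial) log likelihood, the weight defaults to
w = 1; it remains a configuration key.

**Priors.** Effects have spike-and-slab priors: π(βⱼ | δⱼ=1) = N(0, vⱼ)
with vⱼ = 0.5 by default (modest effects on the log-hazard scale), and
π(δⱼ) = Bernoulli(aⱼ) with aⱼ = 1/p (one associated marker expected
a priori). Both are exposed.

**Marker scan.** gBF(j) integrates the 1-D effect against its slab by
importance sampling (default 10⁴ draws) from the Laplace approximation at
the penalized MAP; the proposal is widened (×2, at most three times) if any
draw produces a non-finite loss. The reported `mc_se` is the delta-method
standard error of log gBF. A constant covariate column carries no
information and returns gBF = 1 exactly. A 1-D adaptive-quadrature oracle
agrees within Monte Carlo error.

**Selection sampler.** One add/remove/swap move per iteration, the move
type uniform among feasible types and the marker(s) uniform within type
(the proposal mass is accounted for in both directions). The coefficient
proposal is the independence density N(β̃_δ′, Ṽ_δ′) at the proposed
model's MAP; MAP and Cholesky factors are cached per inclusion state.
After each move the sampler performs a *within-model refresh*: an
independence MH step on β at fixed δ with the same proposal. Without it, β
only refreshes when the chain leaves and re-enters a model, and
coefficient effective sample sizes collapse once a marker's inclusion
probability approaches one; the extra stage leaves the target invariant.
The reported acceptance rate is that of the δ-moves. The empty model is a
legal state. Newton iterations for the MAP use a halving line search with
a 1e-12 relative slack (pure strict decrease stalls at floating-point
resolution near the optimum) and terminate at gradient sup-norm 1e-8.

## Biclustering with common change points

**Conventions.** Columns are 1-based; a change point at c places the
boundary between columns c and c+1, so k_t change points make k_t + 1
time segments. Row-group labels are kept contiguous by first-appearance
relabeling. The loss is the plain within-cell sum of squares (w is applied
separately), computed by per-cell count/sum/sum-of-squares accumulation.

**Calibration.** The F-reference uses the one-way ANOVA identity for a
uniformly random allocation of the n cells into k groups; n defaults to
the number of matrix cells (the objects receiving cell means) and is a
configuration key. Two weight variants are provided: the *literal* recipe
w = −log R / [l_null · f*_α (k−1)/(n−k)], and an *exact* variant
w = −log R / [l_null − l_ref] that equates the posterior ratio to R
exactly; they agree to first order whenever f*(k−1)/(n−k) is small, and
both are kept because the recipe's denominator admits either reading.

**Partition prior.** Poisson(3) on the number of row groups and
Poisson(2) on the number of time groupings (k_t + 1). Given the counts,
the default spreads mass uniformly over configurations — a partition's
prior is pmf(k_s)·pmf(k_t+1)/[Stirling2(n_rows, k_s)·C(n_cols−1, k_t)].
An alternative (`uniform_given_counts=False`) weights each partition by
the count pmfs directly. The distinction matters: under the uniform
convention the unique singleton partition dominates any *specific* coarse
partition a priori (Stirling numbers grow much faster than Poisson tails
decay), so free-count mode-seeking over individual partitions is not
meaningful there; under the count-pmf convention the Poisson rates act as
a per-partition Occam penalty. In configuration-level (cell) comparisons
the multiplicity factor cancels exactly, so both conventions give the
same model grid.

**Sampler.** Metropolis over partitions with three moves: reassign one
row (to an existing or new group), add/remove a change point at a
uniformly chosen feasible boundary, and shift a change point by ±1; all
proposal asymmetries (option counts, direction probabilities, feasible
move types on both sides) enter the acceptance ratio. With
`fixed_counts=True` the sampler conditions on (k_s, k_t): rows migrate
only between existing groups (moves that would empty a group are
rejected) and change points only shift. It matches exhaustive enumeration
on a 2×2 matrix to ~0.002 total variation at 10⁵ iterations.

**Free-count posteriors are diffuse.** Refining a partition never
increases the SOS loss, and one-split refinements of a good partition are
combinatorially numerous, so the highest-posterior single partition
(typically the planted one) carries only a small share of total mass in a
free-count chain. Partition-level summaries — modal configuration,
co-clustering, change-point locations — are therefore reported
*conditionally on the counts*, and `ChangePointBicluster` is two-stage:
a configuration grid (default k_s ≤ 4, k_t ≤ 2) is scored first, then the
conditional sampler produces the summaries at the selected counts. At
small row counts the configuration comparison can legitimately prefer one
extra group (the Poisson Occam factor at k=3 vs 4 is only 4/3); capping
`k_s_max` expresses an analyst's bound where wanted.

**Configuration scores.** The per-configuration log marginal
log E_uniform[e^{−w·l}] is estimated by thermodynamic integration,
log Z(w) = −∫₀^w E_{w′}[l] dw′, along a quadratically spaced ladder of
weights (denser near zero, where the expected loss falls fastest) with a
conditional chain per rung; log Z(0) = 0 in this expectation form, and the
(k_s=1, k_t=0) cell is the deterministic −w·l_null. The reported "average
loss" per configuration excludes the factor w; the weighted value is also
tabulated. Ladder bias is shared across configurations of similar
landscape, but the estimator's differences at the ~0.3-nat level should
not be over-read.

## Synthetic data

The generators produce exactly the structures the analyses assume:
genotypes Binomial(2, maf) with independent markers, exponential event
times with hazard baseline·exp(x'β) (the baseline is irrelevant to the
partial likelihood, so the simplest proportional-hazards-consistent choice
suffices), and independent exponential censoring whose rate is solved
numerically so the expected censored fraction hits the target. The
bicluster generator adds i.i.d. Gaussian noise to a k_s × (k_t+1) table of
cell means. Defaults used throughout the tests: minor allele frequency
0.3, censoring 20–25%, noise σ = 1 with 5σ mean separation. What the
generators deliberately do **not** emulate: linkage disequilibrium between
markers, covariate-dependent censoring, heavy-tailed or correlated matrix
noise, and unequal group sizes; passing tests say nothing about robustness
to those features of real data.

## Problem sizes and numerical tolerances

The test suite runs the samplers at the sizes where independent oracles
are available: 10⁵ iterations against an 8-model enumeration (p=3, n=60)
and a 4-partition enumeration (2×2 matrix), both within 0.03 total
variation; recovery studies use 20 seeded replicates of n=500, p=20
survival data (4000 iterations each) and of 12×12 matrices (10⁴
iterations each). Axiomatic identities are required pointwise to 1e-10,
conjugate recoveries to sup-norm 1e-8, reference-implementation agreement
to 1e-6, and importance-sampling-versus-quadrature agreement to 3 Monte
Carlo standard errors.

## Known limitations

* Grid updates cover 1–2 parameter dimensions; higher-dimensional
  posteriors are the samplers' job, and no generic high-dimensional grid
  path is provided.
* Interval coverage of the spike-and-slab survival posterior measures
  ≈94% at nominal 95% under the test conditions (finite-n partial
  likelihood plus slab shrinkage); this is a property of the model, not
  of the sampler, which matches enumeration to well under a TV of 0.01.
* The thermodynamic configuration scores carry rung-discretization bias;
  comparisons closer than a few tenths of a nat need longer ladders.
* No missing data, time-varying covariates, frailties, or baseline-hazard
  estimation in the survival module; no per-row change points or
  non-Gaussian cell losses in the biclustering module.
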