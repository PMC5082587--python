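# genbayes

General Bayesian updating of belief distributions via loss functions.

## The problem

Classical Bayesian inference requires a full sampling model f(x; θ) for the
data, even when the quantity of interest is a single low-dimensional
functional — a mean, a median, a regression coefficient, a cluster
partition. When no credible likelihood exists (or the parameter does not
index one), a coherent update of beliefs is still available: connect the
parameter to the data through a **loss function** l(θ, x) and update

    ν(θ) ∝ exp{ −w · Σᵢ l(θ, xᵢ) } · π(θ),

the unique minimizer of expected-loss-plus-KL over probability measures,
and the only update consistent with coherence (batchwise = all-at-once),
restriction, monotonicity and shift invariance. With the self-information
loss l(θ, x) = −log f(x; θ) and w = 1 this is exactly Bayes' rule; with an
M-estimation loss it is a Gibbs posterior. The weight w > 0 sets the rate
of exchange between information in the data and information in the prior,
and is the one genuinely new quantity the analyst must fix.

The package provides:

* **`genbayes.update`** — the grid/particle update engine
  (`gibbs_update`, `log_partition`, `sequential_update`, and the
  sklearn-style `GibbsPosterior` estimator), all in the log domain.
* **`genbayes.calibration`** — procedures for choosing w: unit-information
  matching w·E[l] = E[log π(θ̂)/π(θ)] (analytic or leave-one-out empirical),
  a hierarchical treatment with density ∝ w^ξ exp{−w·l}π(θ, w), elicitation
  through a Bayes factor at F-distributed design points, frequentist
  coverage matching, and conjugate prior-observation counting w = Λ/m.
* **`genbayes.survival`** — proportional-hazards regression through the
  **partial likelihood as a loss**: the negative log partial likelihood
  l(β) = −Σ_events [xᵢ'β − log Σ_{l∈Rᵢ} exp(x_l'β)] uses only the event
  ordering and risk sets Rᵢ, so no baseline-hazard prior is ever specified.
  Marker-wise general Bayes factors
  gBF(j) = ∫ e^{−l(βⱼ)} N(βⱼ|0, v) dβⱼ / e^{−l(0)} are computed by
  importance sampling from a Laplace proposal; multi-marker selection uses
  a spike-and-slab prior π(βⱼ|δⱼ=1) = N(0, vⱼ), π(δⱼ) = Bernoulli(aⱼ) with
  an add/remove/swap Metropolis–Hastings sampler and joint independence
  proposals at the per-model MAP (`CoxSpikeSlabSelector`).
* **`genbayes.bicluster`** — model-free biclustering of a matrix into row
  groups × common column change-point segments under the within-cell
  sum-of-squares loss, with w calibrated against the one-way ANOVA
  F-reference: a uniformly random k-group allocation satisfies
  [(l_null − l(S'))/(k−1)] / [l(S')/(n−k)] ~ F_{k−1,n−k}, and the analyst's
  posterior-ratio statement R at the α tail fixes
  w = −log R / [l_null · f*_α (k−1)/(n−k)]. Poisson priors govern the
  number of row groups and time segments; a Metropolis sampler over
  partitions yields co-clustering and change-point posteriors
  (`ChangePointBicluster`).
* **`genbayes.synthetic`** — seeded generators for i.i.d. toys,
  proportional-hazards genotype survival data, and blocked mean-shift
  matrices, each returning the generating truth.
* **`genbayes.cli`** — a `genbayes` command with `simulate`, `calibrate`,
  `scan`, `select`, `cluster` and `update` subcommands over TSV/CSV files.

## Worked example

Survival marker scan and selection on synthetic genotype data (400
subjects, 5 markers, one true log-hazard effect of 0.9 at marker 3, 25%
censoring):

```python
import numpy as np
import genbayes as gb

ds, truth = gb.gen_survival(400, 5, maf=0.3, beta_true={2: 0.9},
                            censor_rate=0.25, seed=42)
print(gb.gbf_scan(ds, v=0.5, seed=0))

sel = gb.CoxSpikeSlabSelector(iterations=10_000, random_state=0)
sel.fit(ds.X, np.column_stack([ds.times, ds.events]))
print(sel.inclusion_probabilities_, sel.coef_)
```

```
 marker   log_gbf    mc_se
      1 -2.094521 0.000234
      2 -2.078898 0.000236
      3 31.153393 0.000104
      4 -1.635469 0.000202
      5 -1.846904 0.000209
inclusion: [0.037 0.025 1.    0.031 0.031]
coef:      [ 0.002 -0.001  0.796  0.002  0.002]
```

The planted marker carries a log Bayes factor of 31 (its neighbours sit
near the null at −2), its posterior inclusion probability is 1.0, and the
posterior-mean coefficient 0.796 recovers the generating 0.9 up to
shrinkage and sampling noise.

Biclustering a 12×12 matrix with three planted row groups and change
points after columns 4 and 8 (5σ mean separation):

```python
means = 5.0 * np.arange(9).reshape(3, 3)
X, _ = gb.gen_bicluster(12, 12, 3, (4, 8), means, sigma=1.0, seed=7)
est = gb.ChangePointBicluster(k_s_max=3, random_state=0).fit(X)
print(est.w_, (est.k_s_, est.k_t_), est.row_labels_, est.change_points_)
```

```
w = 0.00281  selected (k_s, k_t) = (3, 2)
modal groups: [0 0 0 0 1 1 1 1 2 2 2 2]   change points: (4, 8)
```

The F-calibrated weight is ≈0.0028, the configuration comparison selects
three groups with two change points, and the conditional sampler's modal
partition recovers the planted structure exactly.

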