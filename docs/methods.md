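# Methods

## Model

Two sensor arrays observe the same P cortical sources through known linear
forward operators (lead fields): `M(t) = X_M S(t) + e_M(t)` and
`E(t) = X_E S(t) + e_E(t)`, with Gaussian sensor noise `N(0, sigma2_M H_M)` /
`N(0, sigma2_E H_E)`; `H_M`, `H_E` are known correlation structures (identity
by default, or supplied from baseline recordings).  The inverse problem is
ill-posed — many source fields reproduce the data — so sources are
regularized by a latent finite Gaussian mixture: the P locations are embedded
in a regular grid of `N_v` voxels through the map `v(.)`, every voxel carries
a one-hot label over K components, and

    S_j(t) | Z, mu, alpha ~ N(mu_l(t), alpha_l),   l = label of voxel v(j).

Component 1 is the inactive state (`mu_1 = 0`); labels follow a Potts prior
`P(Z) ∝ exp(beta * sum_{h~j} delta(Z_j, Z_h))` on the 6-connected grid with
`delta = 2 Z_j' Z_h - 1`; active means follow a VAR(1) process
`mu_A(t) = A mu_A(t-1) + a(t)`, `a(t) ~ N(0, sigma2_a I)`, with
`mu_A(1) ~ N(0, sigma2_mu1 I)`.  Inverse-gamma priors sit on all variances
and independent `N(0, sigma2_A)` priors on the entries of A.

The estimation objective is the log of the joint density of data and
parameters.  Two normalization conventions matter:

* the Potts constant `G(beta)` is dropped — beta is fixed, so `G(beta)`
  shifts every candidate solution equally; reported objective values are
  therefore defined up to this additive constant and comparable only at equal
  beta;
* all densities are evaluated in the log domain, with the quadratic forms in
  `H_M`, `H_E` going through one Cholesky factorization per fit.

## Optimizers

**ICM** cycles exact conditional-mode updates in a fixed order (sensor
variances, VAR innovation variance, A, component variances, component means,
source courses, labels).  Every printed-formula block was re-derived from the
joint density and is verified in the test suite against numeric maximization
of the objective over that block.  Details:

* all four variance families share the inverse-gamma mode
  `(b + half_ssq) / (a + n/2 + 1)`;
* A is a ridge regression of `mu_A(t)` on `mu_A(t-1)` (the Gaussian prior
  guarantees a nonsingular system);
* component means are updated time point by time point in time order
  (Gauss-Seidel), each a small `(K-1)`-dimensional solve; endpoints use the
  initial-state prior / one-sided coupling;
* source courses are updated cluster by cluster (Gauss-Seidel).  Locations
  may be pre-grouped into J spatial K-means clusters sharing one course; the
  cluster acts through the summed lead-field column.  `J = P` (no grouping)
  is the default;
* labels use the chequerboard scheme: the 6-connected grid is two-coloured,
  same-colour voxels are conditionally independent given the other colour,
  so each colour is re-labelled simultaneously by per-voxel argmax of
  `-(T N_k / 2) log alpha_h - SSE_h / (2 alpha_h) + 2 beta (# neighbours
  labelled h)`, ties to the lowest component index; empty voxels are driven
  by the neighbour term alone.

Convergence is declared when the relative Frobenius change of S between
sweeps falls below `tol` (default 1e-4, `max_sweeps` 100).  Because every
block update is a conditional maximizer, the objective is non-decreasing
along the run; the suite audits this after every block update.  A variance
floor (`jitter`, default 1e-10) guards against a component collapsing onto a
perfectly fit location.

**ACS-ICM** wraps ICM in an ant-colony search over labelings.  A pheromone
matrix `tau(s, l)` (initialized at `tau0`) guides construction: visiting
voxels in a fresh random order, an ant exploits (`argmax tau`, probability
`q0`) or samples proportionally to the pheromone row, and immediately applies
the local update `tau(s, l) <- (1-rho) tau(s, l) + rho tau0` for the chosen
label with pure evaporation `(1-rho) tau(s, k)` for the rest (the printed
update rule's index is read as the standard evaporate-non-chosen semantics).
Each ant's constructed labelling replaces Z in that ant's carried parameter
set (warm start), ICM runs to convergence, and the solution is scored by the
objective.  After all ants finish, the global update applies the same
arithmetic along the all-time-best labelling (a config switch selects the
iteration best instead).  Deposit is exactly `rho * tau0` — no quality
scaling.  One designated ant always restarts from the incumbent labelling
(the initial labelling in iteration 1), which guarantees the returned
objective is at least the plain ICM value from the same initialization.
The outer loop stops when the incumbent improves by less than `outer_tol`
(default 1e-3) over an iteration, or at `max_outer`.  All per-ant randomness
comes from deterministic substreams of one master seed, so runs are exactly
reproducible and would remain so under parallel execution.

Default tuning `(q0, tau0, rho, n_ants) = (0.43, 0.05, 0.64, 10)`; `tune_acs`
optimizes `(q0, tau0, rho)` by Nelder-Mead on an unconstrained scale (logit,
log, logit) with the number of ants held fixed, scoring each point by a
seeded ACS-ICM run.

## Initialization

Both optimizers start from the same data-driven values: a ridge minimum-norm
source estimate `S0 = X'(XX' + lambda I)^{-1} Y` on the stacked modalities,
voxel labels from K-means on voxel-aggregated `S0` courses with the cluster
count chosen by silhouette score over 2..K, the weakest-power cluster taken
as inactive, component means/variances from the members, `A = 0`.  The order
selection step matters: K-means run at a deliberately generous K splits one
genuine activity pattern into near-duplicate clusters, and deterministic ICM
can never merge duplicates once their means have been fit to their members
(its estimated model order then sticks at K).  Silhouette selection is the
standard remedy and reproduces the qualitative behaviour expected of ICM:
mostly correct modal order with occasional over-estimation, which the
ant-colony search then corrects or confirms.

## Model-order estimate

Running either optimizer with a generous K leaves redundant components
empty; `estimate_K` counts occupied components, `K_hat <= K`.

## Synthetic data

The generator emulates the evaluation design: K_true - 1 disjoint contiguous
active voxel blocks grown from farthest-point seeds (the rest inactive);
active mean courses are Gaussian bumps at staggered peak times or sinusoids
at staggered frequencies, peak amplitude = `separation` (1.0 well-separated,
0.35 less-separated); sources are `N(mu_label, alpha_true)` per location and
time with `alpha_true = 0.01` — small, because the emulated design gives all
locations in a region a common smooth profile (with larger within-region
variance even a perfect estimator's flattened truth correlation is capped
well below the values the method is expected to reach); lead fields are
seeded standard-normal matrices with unit-norm columns (head-model operators
are out of scope); per-sensor noise is i.i.d. Gaussian with variance equal to
`noise_frac` (default 5%) of that sensor's noiseless temporal variance.
Trial-level data repeat the projection with an independent noise draw per
trial; for bootstrap experiments the per-trial noise fraction is 2.0 (about
-3 dB single-trial SNR — conservative relative to raw EEG/MEG trials, whose
evoked responses are usually buried 10-20 dB below background), so a 50-trial
average carries ~4% noise, comparable to the averaged-data setting.

What a green test does *not* establish: performance under realistic head
geometry (the random unit-norm lead fields mix sources far more uniformly
than physical operators), under spatially correlated sensor noise, or at the
full problem size (thousands of locations, hundreds of sensors).  All
full-scale claims are mirrored only ordinally.

## Bootstrap inference

Trials are resampled with replacement independently per modality (the two
recordings come from separate sessions with different trial counts), averaged,
and refit; per-replicate randomness comes from substreams indexed by the
replicate number (order-independent), while initialization/optimizer seeds
derive from the master seed alone so identical data give identical fits.
T-map = point total power / bootstrap SD (ddof 1); zero-SD locations are
returned as NaN.  Confidence bands are pointwise percentile intervals
(method choice exposed in config; percentile is the default).  A measured
limitation: the bootstrap SD matches the true sampling SD of the estimator,
but MAP estimates carry shrinkage bias that resampling cannot see, so
percentile intervals under-cover where that bias is comparable to the SD
(observed ~70-85% pointwise coverage at nominal 95% on the desk-scale
design).  The peak location for reporting is the argmax of the T-map.

## Numerical choices and degenerate inputs

* Half-open voxel cells `[lo, hi)` with the top face closed; boundary
  locations bin to the lower cell.  Degenerate (zero-width) axes collapse to
  index 0.
* Label ties break to the lowest component index everywhere (argmax), making
  the q0 = 1 construction on a fresh pheromone field deterministic.
* Cluster source updates guard a zero denominator (empty effective column
  with an infinitely flat mixture) with a floor.
* Spatial K-means for location clustering uses canonical farthest-point
  seeding (no randomness), so cluster maps are permutation-equivariant.
* Sensors with zero noiseless temporal variance receive a configurable
  variance floor when noise is added.

## Known limitations

* ICM's solution (and its estimated model order) is strongly determined by
  the initialization; this is inherent to deterministic coordinate ascent and
  is the motivation for the ant-colony layer.
* At desk scale the posterior itself occasionally favours one extra occupied
  component; ACS-ICM reports that mode faithfully, so its model-order error
  can exceed ICM's there even though it always attains a better objective.
* Spatial clustering (J < P) only helps when clusters are small relative to
  active regions; with few locations it can straddle region boundaries and
  degrade recovery, so the desk-scale experiments default to J = P.
* White sensor noise only; structured/correlated noise is not modelled.
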