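# acsicm

Bayesian spatial-mixture source localization for **combined EEG/MEG data**,
with two optimizers: plain **Iterated Conditional Modes (ICM)** and an
**Ant Colony System coupled with ICM local search (ACS-ICM)**, plus a
nonparametric trial-resampling bootstrap for uncertainty quantification.

## Who this is for

Researchers reconstructing cortical current sources from simultaneous (or
session-paired) MEG and EEG recordings who want a *spatiotemporal* solution
to the electromagnetic inverse problem: the estimate is regularized by a
latent spatial mixture over brain states rather than by a generic minimum-norm
penalty, and the number of active states is estimated alongside the sources.

## The model

Sensor data follow a linear forward model through known lead fields,

    M(t) = X_M S(t) + e_M(t),   e_M(t) ~ N(0, sigma2_M H_M)
    E(t) = X_E S(t) + e_E(t),   e_E(t) ~ N(0, sigma2_E H_E)

and the P cortical source amplitudes are a latent Gaussian mixture allocated
at the level of N_v grid voxels,

    S_j(t) | Z, mu, alpha  ~  N(mu_l(t), alpha_l)   where l labels voxel v(j),

with component 1 the *inactive* state (mu_1 = 0).  Voxel labels Z follow a
Potts prior with fixed inverse temperature beta (spatial cohesion), and the
active-state means follow a VAR(1) process mu_A(t) = A mu_A(t-1) + a(t).
Inverse-gamma priors sit on all variances and a Gaussian prior on A.  Both
optimizers maximize the joint log-posterior; ICM cycles exact conditional
modes (with a chequerboard scheme for the labels), while ACS-ICM layers a
pheromone-guided stochastic search over labelings on top of ICM, which
escapes the local optima ICM is known to stick in.  The number of occupied
components of the solution, K_hat, estimates the number of latent states.

## Worked example

```python
import numpy as np
import acsicm as m

coords = m.make_coords(100, seed=0)                 # cortical locations
grid = m.build_grid(coords, (3, 3, 3))              # voxel grid for the Potts prior
X_M, X_E = m.make_lead_fields(20, 20, 100, seed=1)  # stand-in forward operators
truth = m.make_ground_truth(grid, K_true=3, T=30, seed=2)
data = m.simulate_sensors(truth, X_M, X_E, noise_frac=0.05, seed=100, coords=coords)

hyper = m.Hyperparameters(K=3, beta=0.3)
init = m.default_init(data, grid, hyper, seed=4)
icm = m.icm_run(data, init, hyper, grid)
acs = m.acs_icm_run(data, init, hyper, grid,
                    tuning=m.AcsTuning(n_ants=5, max_outer=5, seed=7))

print(f"ICM     objective {icm.objective_trace[-1]:10.2f}  "
      f"corr {m.source_correlation(truth.S_true, icm.sources.S):.3f}  K_hat {icm.k_hat}")
print(f"ACS-ICM objective {acs.objective_trace[-1]:10.2f}  "
      f"corr {m.source_correlation(truth.S_true, acs.sources.S):.3f}  K_hat {acs.k_hat}")
```

Output (this exact script, seeds as shown):

```
ICM     objective    4673.77  corr 0.880  K_hat 3
ACS-ICM objective    5348.88  corr 0.918  K_hat 3
```

The objective is the joint log-posterior up to the constant Potts
normalizer: ACS-ICM finds a strictly better mode than ICM from the same
start (here by ~675 nats), and its source estimates correlate more strongly
with the simulated truth.  `k_hat` counts the mixture components actually
occupied by voxels — the model-order estimate.

There is also a CLI covering the same pipeline:

```sh
acsicm simulate --seed 1 --out sim/
acsicm fit-acs --dataset sim/dataset.h5 --k 3 --out fit/
acsicm bootstrap --trials sim/trials.h5 --replicates 100 --out boot/
acsicm evaluate --truth sim/truth.h5 --fits fits/ --out tables/
```

## The acceptance script

`scripts/acceptance.py` re-runs the core computation from scratch: it
simulates a two-modality dataset at the documented desk-scale design, fits it
with ICM and ACS-ICM from a common initialization, computes the comparison
metrics (final objectives, truth correlation, estimated model order), and
runs a small trial-resampling bootstrap with its T-map.  Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It prints the pipeline summary and writes the results JSON to `--out`.

## Scope notes

Forward operators (lead fields) are *inputs*: computing them from head
geometry is out of scope, as are estimation of the Potts inverse temperature
and its normalizing constant.  See `docs/methods.md` for the estimation
procedure, all tunable parameters, what the synthetic-data generator does and
does not emulate, and known limitations.
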