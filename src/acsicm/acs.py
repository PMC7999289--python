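"""Ant Colony System coupled with ICM local search.

Each outer iteration, every ant constructs a candidate voxel labelling from
the pheromone matrix (exploiting the best-scented label with probability q0,
otherwise sampling proportionally to pheromone), refines it with ICM run to
convergence, and is scored by the joint log-posterior.  Pheromone evaporates
locally while ants construct and is reinforced globally along the best
labelling, concentrating the search around high-quality solutions.  One
designated ant always restarts from the incumbent labelling (the initial
labelling in the first iteration), so the final objective can never fall
below a plain ICM run from the same initialization.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .icm import IcmSettings, icm_run
from .model import (
    FitResult,
    Hyperparameters,
    InputError,
    MixtureState,
    SensorDataset,
    SourceField,
)
from .spatial import ClusterMap, VoxelGrid, estimate_K

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AcsTuning:
    """Tuning parameters of the ant colony.

    q0 in (0,1) is the exploitation probability, tau0 > 0 the initial and
    deposited pheromone, rho in (0,1) the evaporation rate.  Defaults are the
    values selected by outer-level tuning in the reference application
    (q0, tau0, rho) = (0.43, 0.05, 0.64) with 10 ants.
    """

    q0: float = 0.43
    tau0: float = 0.05
    rho: float = 0.64
    n_ants: int = 10
    max_outer: int = 10
    outer_tol: float = 1e-3
    seed: int = 0
    deposit_on: str = "all_time_best"  # or "iteration_best"
    converged: bool = True  # set False by tune_acs when the budget ran out

    def __post_init__(self):
        if not (0.0 < self.q0 < 1.0) and self.q0 != 1.0:
            raise InputError("q0 must lie in (0, 1] ")
        if self.tau0 <= 0:
            raise InputError("tau0 must be positive")
        if not (0.0 < self.rho < 1.0):
            raise InputError("rho must lie in (0, 1)")
        if self.n_ants < 1:
            raise InputError("n_ants must be at least 1")
        if self.max_outer < 1:
            raise InputError("max_outer must be at least 1")
        if self.outer_tol <= 0:
            raise InputError("outer_tol must be positive")
        if self.deposit_on not in ("all_time_best", "iteration_best"):
            raise InputError("deposit_on must be 'all_time_best' or 'iteration_best'")


@dataclasses.dataclass
class PheromoneField:
    """Positive N_v x K pheromone matrix tau(s, l)."""

    tau: np.ndarray

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=np.float64)
        if self.tau.ndim != 2:
            raise InputError("tau must be N_v x K")
        if np.any(self.tau <= 0):
            raise InputError("pheromone entries must be strictly positive")

    def transition_probabilities(self) -> np.ndarray:
        """Row-normalized sampling probabilities p(s, l) = tau(s, l)/sum_u tau(s, u)."""
        return self.tau / self.tau.sum(axis=1, keepdims=True)


def initialize_pheromone(N_v: int, K: int, tau0: float) -> PheromoneField:
    """Constant field tau(s, l) = tau0 (uniform transition probabilities)."""
    if tau0 <= 0:
        raise InputError("tau0 must be positive")
    return PheromoneField(np.full((N_v, K), float(tau0)))


def local_pheromone_update(pher: PheromoneField, voxel: int, label: int, tuning: AcsTuning) -> PheromoneField:
    """Evaporate all labels of the visited voxel; deposit rho*tau0 on the chosen one.

    tau(s, l) <- (1-rho) tau(s, l) + rho tau0 for the chosen label, and pure
    evaporation tau(s, k) <- (1-rho) tau(s, k) for k != l.  Entries stay
    strictly positive.  The field is updated in place and returned.
    """
    rho = tuning.rho
    pher.tau[voxel] *= 1.0 - rho
    pher.tau[voxel, label] += rho * tuning.tau0
    return pher


def global_pheromone_update(pher: PheromoneField, Z_best: np.ndarray, tuning: AcsTuning) -> PheromoneField:
    """Apply the evaporation/deposit rule voxel-wise along the best labelling."""
    labels = np.argmax(np.asarray(Z_best), axis=1)
    rho = tuning.rho
    pher.tau *= 1.0 - rho
    pher.tau[np.arange(pher.tau.shape[0]), labels] += rho * tuning.tau0
    return pher


def construct_labeling(pher: PheromoneField, tuning: AcsTuning, rng: np.random.Generator) -> np.ndarray:
    """One ant's labelling pass: visit voxels in random order, pick labels, evaporate.

    With probability q0 the ant exploits (argmax pheromone, ties to the lowest
    label index); otherwise it samples a label proportionally to the voxel's
    pheromone row.  Each choice immediately triggers the local pheromone
    update, so later voxels (and later ants) see the evaporated field.
    """
    N_v, K = pher.tau.shape
    labels = np.empty(N_v, dtype=np.int64)
    for s in rng.permutation(N_v):
        row = pher.tau[s]
        if rng.uniform() <= tuning.q0:
            l = int(np.argmax(row))
        else:
            p = row / row.sum()
            l = int(rng.choice(K, p=p))
        labels[s] = l
        local_pheromone_update(pher, s, l, tuning)
    Z = np.zeros((N_v, K), dtype=np.int8)
    Z[np.arange(N_v), labels] = 1
    return Z


def _ant_rng(seed: int, iteration: int, ant: int) -> np.random.Generator:
    """Deterministic substream for one ant in one outer iteration."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration, ant)))


def acs_icm_run(
    dataset: SensorDataset,
    init: Tuple[MixtureState, SourceField],
    hyper: Hyperparameters,
    grid: VoxelGrid,
    clusters: Optional[ClusterMap] = None,
    tuning: Optional[AcsTuning] = None,
    icm_settings: Optional[IcmSettings] = None,
    iteration_log: Optional[List[dict]] = None,
) -> FitResult:
    """ACS with ICM local search; returns the incumbent (all-time best) solution.

    Ant 0 is incumbent-seeded: in iteration 1 it reuses the unmodified initial
    labelling, afterwards the current best one, so the returned objective is
    guaranteed to be at least that of ``icm_run`` from the same ``init``.
    Every other ant constructs a labelling from the pheromone field; each ant
    carries its own continuous parameters across iterations as an ICM warm
    start (only Z is replaced by the construction).  The run stops when the
    incumbent's objective improves by less than ``outer_tol`` over a full
    outer iteration, or at ``max_outer``.
    """
    if tuning is None:
        tuning = AcsTuning()
    if icm_settings is None:
        icm_settings = IcmSettings()
    init_state, init_sources = init[0].copy(), init[1].copy()
    pher = initialize_pheromone(grid.N_v, hyper.K, tuning.tau0)

    ants = [(init_state.copy(), init_sources.copy()) for _ in range(tuning.n_ants)]
    incumbent: Optional[FitResult] = None
    prev_best = -math.inf
    outer_done = 0

    for it in range(tuning.max_outer):
        outer_done = it + 1
        iter_best: Optional[FitResult] = None
        for a in range(tuning.n_ants):
            carried_state, carried_sources = ants[a]
            if a == 0:
                # incumbent-seeded ant: exact init labelling first, then the best
                Z = init_state.Z.copy() if incumbent is None else incumbent.state.Z.copy()
            else:
                Z = construct_labeling(pher, tuning, _ant_rng(tuning.seed, it, a))
            start = carried_state.copy()
            start.Z = Z
            try:
                fit = icm_run(dataset, (start, carried_sources), hyper, grid, clusters, icm_settings)
            except RuntimeError as exc:
                logger.warning("ant %d failed in outer iteration %d: %s", a, it + 1, exc)
                continue
            ants[a] = (fit.state, fit.sources)
            score = fit.objective_trace[-1]
            if iter_best is None or score > iter_best.objective_trace[-1]:
                iter_best = fit
            if incumbent is None or score > incumbent.objective_trace[-1]:
                incumbent = FitResult(
                    state=fit.state.copy(),
                    sources=fit.sources.copy(),
                    objective_trace=list(fit.objective_trace),
                    k_hat=fit.k_hat,
                    converged=fit.converged,
                    iterations=fit.iterations,
                    seed=tuning.seed,
                )
            if iteration_log is not None:
                iteration_log.append(
                    {"iteration": it + 1, "ant": a, "objective": score,
                     "incumbent": incumbent.objective_trace[-1]}
                )
        if incumbent is None:
            raise RuntimeError("every ant failed; no solution available")
        best_Z = incumbent.state.Z if tuning.deposit_on == "all_time_best" else iter_best.state.Z
        global_pheromone_update(pher, best_Z, tuning)

        best_obj = incumbent.objective_trace[-1]
        if it > 0 and best_obj - prev_best < tuning.outer_tol:
            prev_best = best_obj
            break
        prev_best = best_obj

    return FitResult(
        state=incumbent.state,
        sources=incumbent.sources,
        objective_trace=incumbent.objective_trace,
        k_hat=estimate_K(incumbent.state.Z),
        converged=outer_done < tuning.max_outer or tuning.max_outer == 1,
        iterations=outer_done,
        seed=tuning.seed,
    )


# ---------------------------------------------------------------------------
# outer-level tuning
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def tune_acs(
    dataset: Optional[SensorDataset],
    init,
    hyper: Optional[Hyperparameters],
    grid: Optional[VoxelGrid],
    clusters: Optional[ClusterMap] = None,
    budget: int = 30,
    seed: int = 0,
    n_ants: int = 10,
    icm_settings: Optional[IcmSettings] = None,
    start: Tuple[float, float, float] = (0.43, 0.05, 0.64),
    objective: Optional[Callable[[float, float, float], float]] = None,
    max_outer: int = 5,
) -> AcsTuning:
    """Nelder-Mead search over (q0, tau0, rho) on an unconstrained scale.

    The default objective is the final log-joint of a seeded ``acs_icm_run``;
    ``objective(q0, tau0, rho)`` may be supplied instead (used for testing and
    for cheap surrogates).  The number of ants is held fixed.  Returns the
    best-evaluated tuple; ``converged`` is False when the evaluation budget
    was exhausted before the simplex converged.
    """
    if budget < 1:
        raise InputError("budget must be at least 1")

    def run_objective(q0: float, tau0: float, rho: float) -> float:
        if objective is not None:
            return objective(q0, tau0, rho)
        tuning = AcsTuning(q0=q0, tau0=tau0, rho=rho, n_ants=n_ants,
                           max_outer=max_outer, seed=seed)
        fit = acs_icm_run(dataset, init, hyper, grid, clusters, tuning, icm_settings)
        return fit.objective_trace[-1]

    best = {"val": -math.inf, "x": start}
    evals = {"n": 0}

    def neg(xt: np.ndarray) -> float:
        if evals["n"] >= budget:
            # starve the optimizer once the budget is spent
            return math.inf
        evals["n"] += 1
        q0 = min(max(_expit(xt[0]), 1e-6), 1 - 1e-6)
        rho = min(max(_expit(xt[2]), 1e-6), 1 - 1e-6)
        tau0 = math.exp(min(max(xt[1], -30.0), 30.0))
        val = run_objective(q0, tau0, rho)
        if val > best["val"]:
            best["val"] = val
            best["x"] = (q0, tau0, rho)
        return -val

    x0 = np.array([_logit(start[0]), math.log(start[1]), _logit(start[2])])
    if budget == 1:
        neg(x0)
    else:
        minimize(neg, x0, method="Nelder-Mead",
                 options={"maxfev": budget, "xatol": 1e-7, "fatol": 1e-10})
    q0, tau0, rho = best["x"]
    return AcsTuning(q0=q0, tau0=tau0, rho=rho, n_ants=n_ants, seed=seed,
                     converged=evals["n"] < budget)
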