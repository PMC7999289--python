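"""Iterated Conditional Modes for the spatial mixture source model.

Each sweep replaces every parameter block with the exact mode of its full
conditional distribution, in the fixed order

    sigma2_M, sigma2_E, sigma2_a, A, alpha, mu, S, Z (black), Z (white),

so the joint log-posterior never decreases.  Voxel labels use the
chequerboard scheme: under a first-order neighbourhood, same-colour voxels
are conditionally independent given the other colour, so each colour is
re-labelled simultaneously by an exact per-voxel argmax.  Convergence is
monitored by the relative Frobenius change of the source field between
consecutive sweeps.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Tuple

import numpy as np

from .model import (
    FitResult,
    Hyperparameters,
    InputError,
    MixtureState,
    SensorDataset,
    SourceField,
    log_joint,
    residuals,
)
from .spatial import ClusterMap, VoxelGrid, estimate_K, singleton_clusters


@dataclasses.dataclass
class IcmSettings:
    """Convergence controls for an ICM run.

    ``tol`` thresholds the relative Frobenius change of S between sweeps;
    ``jitter`` floors conditional variance modes away from zero (a component
    that fits its locations perfectly would otherwise collapse).
    """

    tol: float = 1e-4
    max_sweeps: int = 100
    jitter: float = 1e-10

    def __post_init__(self):
        if self.tol <= 0:
            raise InputError("tol must be positive")
        if self.max_sweeps < 1:
            raise InputError("max_sweeps must be at least 1")
        if self.jitter <= 0:
            raise InputError("jitter must be positive")


# ---------------------------------------------------------------------------
# closed-form block updates
# ---------------------------------------------------------------------------

def ig_conditional_mode(a: float, b: float, n_terms: float, half_ssq: float) -> float:
    """Mode ``(b + half_ssq) / (a + n_terms/2 + 1)`` of an inverse-gamma conditional.

    A Gaussian block with ``n_terms`` observations and summed half squared
    error ``half_ssq`` combined with an IG(a, b) prior has an IG conditional
    with shape ``a + n_terms/2`` and scale ``b + half_ssq``; its mode is the
    ICM update used for all four variance families (sensor noise, VAR
    innovation, mixture components).
    """
    if a <= 0 or b <= 0:
        raise InputError("inverse-gamma parameters a, b must be positive")
    if n_terms < 0 or half_ssq < 0:
        raise InputError("n_terms and half_ssq must be nonnegative")
    return (b + half_ssq) / (a + 0.5 * n_terms + 1.0)


def update_ar_matrix(mu_A: np.ndarray, sigma2_a: float, sigma2_A: float) -> np.ndarray:
    """Conditional mode of the VAR(1) coefficient matrix A.

    Penalized least-squares regression of ``mu_A(t)`` on ``mu_A(t-1)``:
    ``A = C (G + (sigma2_a / sigma2_A) I)^{-1}`` with cross-product
    ``C = sum_t mu_A(t) mu_A(t-1)'`` and Gram ``G = sum_t mu_A(t-1) mu_A(t-1)'``.
    The ridge term from the Gaussian prior keeps the system nonsingular.
    """
    mu_A = np.asarray(mu_A, dtype=np.float64)
    if not np.all(np.isfinite(mu_A)):
        raise InputError("mu_A contains non-finite values")
    if mu_A.ndim != 2 or mu_A.shape[1] < 2:
        raise InputError("mu_A must be (K-1) x T with T >= 2")
    prev = mu_A[:, :-1]
    cur = mu_A[:, 1:]
    C = cur @ prev.T
    G = prev @ prev.T
    lam = sigma2_a / sigma2_A
    return np.linalg.solve(G + lam * np.eye(G.shape[0]), C.T).T


def update_component_means(
    sources: SourceField,
    state: MixtureState,
    grid: VoxelGrid,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Conditional-mode update of the component means mu (row 0 stays zero).

    Active means are updated coordinate-wise in time order (Gauss-Seidel over
    t = 1..T), each solving the (K-1)-dimensional normal equations that
    combine the mixture data term with the VAR(1) coupling to the current
    neighbouring time points.  Endpoints use the initial-state prior (t = 1)
    and the one-sided coupling (t = T).
    """
    K, T = state.K, sources.T
    mu = state.mu.copy()
    mu_A = mu[1:]  # view; updated in place, time-ordered
    A = state.A
    s2a = state.sigma2_a
    AtA = A.T @ A
    I = np.eye(K - 1)

    lab = state.labels[grid.v]  # per-location component index
    # D = diag over active components of (#locations assigned)/alpha_l
    cnt = np.bincount(lab, minlength=K).astype(np.float64)
    D = cnt[1:] / state.alpha[1:]
    # data RHS: for active l, sum_{j assigned to l} S_j(t) / alpha_l
    rhs_data = np.zeros((K - 1, T))
    for l in range(1, K):
        sel = lab == l
        if np.any(sel):
            rhs_data[l - 1] = sources.S[sel].sum(axis=0) / state.alpha[l]

    for t in range(T):
        if t == 0:
            B = np.diag(D) + AtA / s2a + I / hyper.sigma2_mu1
            rhs = rhs_data[:, 0] + (A.T @ mu_A[:, 1]) / s2a
        elif t == T - 1:
            B = np.diag(D) + I / s2a
            rhs = rhs_data[:, t] + (A @ mu_A[:, t - 1]) / s2a
        else:
            B = np.diag(D) + (AtA + I) / s2a
            rhs = rhs_data[:, t] + (A @ mu_A[:, t - 1] + A.T @ mu_A[:, t + 1]) / s2a
        mu_A[:, t] = np.linalg.solve(B, rhs)
    return mu


class _SourceWork:
    """Per-fit precomputations for the clustered source update.

    With locations in a cluster constrained to one shared course, the cluster
    acts through the effective forward column ``X_tilde[:, c] = sum_{j in c}
    X[:, j]``; the per-cluster quadratic coefficient and H^{-1}-projected
    columns are computed once per fit.
    """

    def __init__(self, dataset: SensorDataset, clusters: ClusterMap):
        self.members = clusters.members
        J = clusters.J
        ind = np.zeros((dataset.P, J))
        ind[np.arange(dataset.P), clusters.assignment] = 1.0
        self.Xm = dataset.X_M @ ind  # n_M x J effective columns
        self.Xe = dataset.X_E @ ind
        self.HinvXm = dataset.solve_HM(self.Xm)
        self.HinvXe = dataset.solve_HE(self.Xe)
        self.gm = np.sum(self.Xm * self.HinvXm, axis=0)  # X~' H^-1 X~ per cluster
        self.ge = np.sum(self.Xe * self.HinvXe, axis=0)


def _update_sources_inplace(
    S: np.ndarray,
    dataset: SensorDataset,
    state: MixtureState,
    grid: VoxelGrid,
    work: _SourceWork,
) -> None:
    """Gauss-Seidel pass over clusters; each shared course set to its conditional mode."""
    lab = state.labels[grid.v]
    inv_alpha = 1.0 / state.alpha
    w_loc = inv_alpha[lab]                     # per-location mixture precision
    wmu_loc = state.mu[lab] * w_loc[:, None]   # per-location mu_l/alpha_l course

    # cluster-level source courses (locations within a cluster may start unequal;
    # the update writes the shared mode back to every member)
    s2M, s2E = state.sigma2_M, state.sigma2_E
    pred_M = dataset.X_M @ S
    pred_E = dataset.X_E @ S

    for c, mem in enumerate(work.members):
        # remove this cluster's current contribution from the predictions
        pred_M -= dataset.X_M[:, mem] @ S[mem]
        pred_E -= dataset.X_E[:, mem] @ S[mem]
        num = (
            (work.HinvXm[:, c] @ (dataset.M - pred_M)) / s2M
            + (work.HinvXe[:, c] @ (dataset.E - pred_E)) / s2E
            + wmu_loc[mem].sum(axis=0)
        )
        den = work.gm[c] / s2M + work.ge[c] / s2E + w_loc[mem].sum()
        course = num / max(den, 1e-300)
        S[mem] = course
        pred_M += np.outer(work.Xm[:, c], course)
        pred_E += np.outer(work.Xe[:, c], course)


def update_sources(
    dataset: SensorDataset,
    state: MixtureState,
    sources: SourceField,
    clusters: Optional[ClusterMap] = None,
    grid: Optional[VoxelGrid] = None,
) -> SourceField:
    """Conditional-mode update of the source field under the cluster constraint."""
    if clusters is None:
        clusters = singleton_clusters(dataset.P)
    S = sources.S.copy()
    _update_sources_inplace(S, dataset, state, grid, _SourceWork(dataset, clusters))
    return SourceField(S)


def _label_scores(
    sources: SourceField,
    state: MixtureState,
    grid: VoxelGrid,
    hyper: Hyperparameters,
) -> np.ndarray:
    """Per-voxel, per-component conditional log-scores excluding the neighbour term.

    score[kappa, h] = -(T N_kappa / 2) log alpha_h
                      - (1/(2 alpha_h)) sum_{j: v(j)=kappa} sum_t (S_j(t)-mu_h(t))^2
    """
    K = state.K
    N_v = grid.N_v
    sse = np.empty((N_v, K))
    for l in range(K):
        d = sources.S - state.mu[l][None, :]
        per_loc = np.einsum("ij,ij->i", d, d)
        sse[:, l] = np.bincount(grid.v, weights=per_loc, minlength=N_v)
    T = sources.T
    return (
        -0.5 * T * grid.counts[:, None] * np.log(state.alpha)[None, :]
        - sse / (2.0 * state.alpha)[None, :]
    )


def update_labels_chequerboard(
    sources: SourceField,
    state: MixtureState,
    grid: VoxelGrid,
    hyper: Hyperparameters,
    colours: Tuple[str, ...] = ("black", "white"),
) -> np.ndarray:
    """Simultaneous chequerboard relabelling; returns a new one-hot Z.

    For each requested colour all voxels of that colour are set at once to
    ``argmax_h [ data score + 2 beta * (# neighbours labelled h) ]`` (ties to
    the lowest component index); empty voxels are driven by the neighbour
    term alone.  Black is updated first, then white sees the new black labels.
    """
    Z = np.ascontiguousarray(state.Z, dtype=np.float64)
    data_score = _label_scores(sources, state, grid, hyper)
    sets = {"black": np.flatnonzero(grid.parity == 0), "white": np.flatnonzero(grid.parity == 1)}
    for colour in colours:
        idx = sets[colour]
        if idx.size == 0:
            continue
        nbr = grid.adjacency[idx] @ Z  # neighbours per candidate label
        score = data_score[idx] + 2.0 * hyper.beta * nbr
        q = np.argmax(score, axis=1)  # np.argmax breaks ties toward the lowest index
        Z[idx] = 0.0
        Z[idx, q] = 1.0
    return Z.astype(np.int8)


# ---------------------------------------------------------------------------
# the full ICM sweep loop
# ---------------------------------------------------------------------------

def _half_quad_M(dataset: SensorDataset, S: np.ndarray) -> float:
    r = dataset.M - dataset.X_M @ S
    return 0.5 * float(np.sum(r * dataset.solve_HM(r)))


def _half_quad_E(dataset: SensorDataset, S: np.ndarray) -> float:
    r = dataset.E - dataset.X_E @ S
    return 0.5 * float(np.sum(r * dataset.solve_HE(r)))


def _update_alphas(
    sources: SourceField,
    state: MixtureState,
    grid: VoxelGrid,
    hyper: Hyperparameters,
    jitter: float,
) -> np.ndarray:
    """Conditional modes of all component variances (separable blocks)."""
    lab = state.labels[grid.v]
    T = sources.T
    alpha = np.empty(state.K)
    for l in range(state.K):
        sel = lab == l
        n_assigned = int(np.count_nonzero(sel))
        if n_assigned:
            dev = sources.S[sel] - state.mu[l][None, :]
            half_ssq = 0.5 * float(np.sum(dev * dev))
        else:
            half_ssq = 0.0
        alpha[l] = ig_conditional_mode(hyper.a_alpha, hyper.b_alpha, T * n_assigned, half_ssq)
    return np.maximum(alpha, jitter)


def icm_run(
    dataset: SensorDataset,
    init: Tuple[MixtureState, SourceField],
    hyper: Hyperparameters,
    grid: VoxelGrid,
    clusters: Optional[ClusterMap] = None,
    settings: Optional[IcmSettings] = None,
    callback: Optional[Callable[[str, MixtureState, SourceField], None]] = None,
) -> FitResult:
    """Run ICM to convergence from ``init``; deterministic coordinate ascent.

    ``callback(block_name, state, sources)`` (if given) fires after every
    block update, which lets callers audit per-block monotonicity of the
    objective.  The objective trace records the log-joint after each full
    sweep.
    """
    if settings is None:
        settings = IcmSettings()
    if clusters is None:
        clusters = singleton_clusters(dataset.P)
    state = init[0].copy()
    sources = init[1].copy()
    T, K = dataset.T, state.K
    work = _SourceWork(dataset, clusters)

    def fire(name: str):
        if callback is not None:
            callback(name, state, sources)

    trace = []
    converged = False
    sweeps = 0
    for sweep in range(settings.max_sweeps):
        sweeps = sweep + 1
        S_old = sources.S.copy()

        state.sigma2_M = max(
            ig_conditional_mode(hyper.a_M, hyper.b_M, T * dataset.n_M, _half_quad_M(dataset, sources.S)),
            settings.jitter,
        )
        fire("sigma2_M")
        state.sigma2_E = max(
            ig_conditional_mode(hyper.a_E, hyper.b_E, T * dataset.n_E, _half_quad_E(dataset, sources.S)),
            settings.jitter,
        )
        fire("sigma2_E")

        innov = state.mu_A[:, 1:] - state.A @ state.mu_A[:, :-1]
        state.sigma2_a = max(
            ig_conditional_mode(hyper.a_a, hyper.b_a, (T - 1) * (K - 1), 0.5 * float(np.sum(innov**2))),
            settings.jitter,
        )
        fire("sigma2_a")

        state.A = update_ar_matrix(state.mu_A, state.sigma2_a, hyper.sigma2_A)
        fire("A")

        state.alpha = _update_alphas(sources, state, grid, hyper, settings.jitter)
        fire("alpha")

        state.mu = update_component_means(sources, state, grid, hyper)
        fire("mu")

        _update_sources_inplace(sources.S, dataset, state, grid, work)
        fire("S")

        state.Z = update_labels_chequerboard(sources, state, grid, hyper, colours=("black",))
        fire("Z_black")
        state.Z = update_labels_chequerboard(sources, state, grid, hyper, colours=("white",))
        fire("Z_white")

        obj = log_joint(dataset, state, sources, grid, hyper)
        if not np.isfinite(obj):
            raise RuntimeError(
                f"ICM objective became non-finite at sweep {sweeps}; "
                f"state: sigma2_M={state.sigma2_M:.3e}, sigma2_E={state.sigma2_E:.3e}, "
                f"sigma2_a={state.sigma2_a:.3e}, alpha={state.alpha}"
            )
        trace.append(obj)

        denom = max(float(np.linalg.norm(S_old)), 1e-12)
        if float(np.linalg.norm(sources.S - S_old)) / denom < settings.tol:
            converged = True
            break

    return FitResult(
        state=state,
        sources=sources,
        objective_trace=trace,
        k_hat=estimate_K(state.Z),
        converged=converged,
        iterations=sweeps,
        seed=None,
    )
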