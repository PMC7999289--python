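"""Core model types and the joint log-posterior for two-modality source localization.

The model ties together MEG sensor readings ``M(t)`` and EEG readings ``E(t)``
through a shared field of cortical source amplitudes ``S`` via known forward
(lead-field) operators, and regularizes the ill-posed inverse problem with a
latent Gaussian mixture over sources whose voxel-level allocations follow a
Potts (spatially cohesive) prior.  Component 1 (index 0 here) is the
"inactive" state with mean fixed at zero; the means of active components
evolve over time as a first-order vector autoregression.

The single scalar objective maximized by both optimizers is the log of the
joint density of data and parameters.  The Potts normalizing constant G(beta)
is dropped: the inverse temperature is held fixed, so G(beta) shifts every
candidate solution equally and the reported objective is defined up to that
additive constant.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import linalg
from scipy.special import gammaln

LOG_2PI = float(np.log(2.0 * np.pi))


class InputError(ValueError):
    """Raised when inputs violate a documented precondition."""


def _as_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 2:
        raise InputError(f"{name} must be a 2-D array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite entries")
    return a


def _check_spd(H: np.ndarray, name: str):
    """Return the (lower) Cholesky factor of a symmetric positive-definite matrix."""
    if H.shape[0] != H.shape[1]:
        raise InputError(f"{name} must be square, got {H.shape}")
    if not np.allclose(H, H.T, atol=1e-10):
        raise InputError(f"{name} is not symmetric")
    try:
        return linalg.cho_factor(H, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - message path
        raise InputError(f"{name} is not positive definite") from exc


@dataclasses.dataclass(eq=False)
class SensorDataset:
    """Two-modality sensor data with forward operators and noise structure.

    Parameters
    ----------
    M, E
        MEG (``n_M x T``) and EEG (``n_E x T``) sensor time series.
    X_M, X_E
        Forward operators mapping the ``P`` cortical sources to the sensors.
        These are treated as known inputs (computed upstream from a head
        model); they are never estimated here.
    H_M, H_E
        Known sensor-noise correlation matrices (defaults: identity).
    coords
        Optional ``P x 3`` coordinates of the cortical locations, required to
        build a voxel grid or spatial clusters.
    """

    M: np.ndarray
    E: np.ndarray
    X_M: np.ndarray
    X_E: np.ndarray
    H_M: Optional[np.ndarray] = None
    H_E: Optional[np.ndarray] = None
    coords: Optional[np.ndarray] = None

    def __post_init__(self):
        self.M = _as_matrix(self.M, "M")
        self.E = _as_matrix(self.E, "E")
        self.X_M = _as_matrix(self.X_M, "X_M")
        self.X_E = _as_matrix(self.X_E, "X_E")
        if self.H_M is None:
            self.H_M = np.eye(self.M.shape[0])
        if self.H_E is None:
            self.H_E = np.eye(self.E.shape[0])
        self.H_M = _as_matrix(self.H_M, "H_M")
        self.H_E = _as_matrix(self.H_E, "H_E")
        if self.M.shape[0] != self.X_M.shape[0]:
            raise InputError(
                f"n_M mismatch: M has {self.M.shape[0]} sensors, X_M has {self.X_M.shape[0]} rows"
            )
        if self.E.shape[0] != self.X_E.shape[0]:
            raise InputError(
                f"n_E mismatch: E has {self.E.shape[0]} sensors, X_E has {self.X_E.shape[0]} rows"
            )
        if self.X_M.shape[1] != self.X_E.shape[1]:
            raise InputError("X_M and X_E disagree on the number of cortical locations P")
        if self.M.shape[1] != self.E.shape[1]:
            raise InputError("M and E disagree on the number of time points T")
        if self.T < 2:
            raise InputError("at least T >= 2 time points are required")
        if self.H_M.shape[0] != self.n_M:
            raise InputError("H_M dimension does not match the number of MEG sensors")
        if self.H_E.shape[0] != self.n_E:
            raise InputError("H_E dimension does not match the number of EEG sensors")
        if self.coords is not None:
            self.coords = _as_matrix(self.coords, "coords")
            if self.coords.shape != (self.P, 3):
                raise InputError(f"coords must be P x 3 = ({self.P}, 3), got {self.coords.shape}")
        self._cho_M = _check_spd(self.H_M, "H_M")
        self._cho_E = _check_spd(self.H_E, "H_E")

    # -- dimensions -------------------------------------------------------
    @property
    def n_M(self) -> int:
        return self.M.shape[0]

    @property
    def n_E(self) -> int:
        return self.E.shape[0]

    @property
    def P(self) -> int:
        return self.X_M.shape[1]

    @property
    def T(self) -> int:
        return self.M.shape[1]

    # -- noise-covariance algebra (factorized once) -----------------------
    def solve_HM(self, V: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self._cho_M, V)

    def solve_HE(self, V: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self._cho_E, V)

    @property
    def logdet_HM(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._cho_M[0]))))

    @property
    def logdet_HE(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self._cho_E[0]))))


@dataclasses.dataclass
class SourceField:
    """Source amplitude and polarity at each cortical location over time (P x T)."""

    S: np.ndarray

    def __post_init__(self):
        self.S = _as_matrix(self.S, "S")

    @property
    def P(self) -> int:
        return self.S.shape[0]

    @property
    def T(self) -> int:
        return self.S.shape[1]

    def copy(self) -> "SourceField":
        return SourceField(self.S.copy())


def _check_one_hot(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z)
    if Z.ndim != 2:
        raise InputError("Z must be a 2-D one-hot matrix")
    if not np.all((Z == 0) | (Z == 1)) or not np.all(Z.sum(axis=1) == 1):
        raise InputError("every row of Z must be one-hot (exactly one 1)")
    return Z


@dataclasses.dataclass
class MixtureState:
    """All model parameters except the sources.

    ``Z`` is the one-hot voxel labeling (N_v x K); ``mu`` the K x T component
    means with row 0 pinned to zero (the inactive state); ``alpha`` the K
    component variances; ``A`` the (K-1) x (K-1) VAR(1) coefficient matrix for
    the active means; the three scalars are noise/innovation variances.
    """

    Z: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray
    A: np.ndarray
    sigma2_a: float
    sigma2_E: float
    sigma2_M: float

    def __post_init__(self):
        self.Z = np.ascontiguousarray(_check_one_hot(self.Z), dtype=np.int8)
        self.mu = _as_matrix(self.mu, "mu")
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.A = _as_matrix(self.A, "A")
        K = self.Z.shape[1]
        if self.mu.shape[0] != K or self.alpha.shape != (K,):
            raise InputError("Z, mu and alpha disagree on the number of components K")
        if self.A.shape != (K - 1, K - 1):
            raise InputError(f"A must be (K-1) x (K-1) = ({K-1}, {K-1}), got {self.A.shape}")
        if np.any(self.mu[0] != 0.0):
            raise InputError("mu[0, :] (the inactive component mean) must be identically zero")
        if np.any(self.alpha <= 0):
            raise InputError("all component variances alpha must be positive")
        for name in ("sigma2_a", "sigma2_E", "sigma2_M"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def N_v(self) -> int:
        return self.Z.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Integer voxel labels in 0..K-1 (0 = inactive)."""
        return np.argmax(self.Z, axis=1)

    @property
    def mu_A(self) -> np.ndarray:
        """Means of the active components, (K-1) x T."""
        return self.mu[1:]

    def copy(self) -> "MixtureState":
        return MixtureState(
            Z=self.Z.copy(),
            mu=self.mu.copy(),
            alpha=self.alpha.copy(),
            A=self.A.copy(),
            sigma2_a=self.sigma2_a,
            sigma2_E=self.sigma2_E,
            sigma2_M=self.sigma2_M,
        )


@dataclasses.dataclass
class Hyperparameters:
    """Fixed hyperparameters of the hierarchical model.

    ``K`` is the (upper bound on the) number of mixture components and
    ``beta`` the fixed Potts inverse temperature.  The inverse-gamma prior
    pairs ``(a, b)`` and the Gaussian prior scales are weakly informative
    defaults; all are configurable.
    """

    K: int
    beta: float = 0.3
    a_E: float = 2.0
    b_E: float = 1.0
    a_M: float = 2.0
    b_M: float = 1.0
    a_alpha: float = 2.0
    b_alpha: float = 1.0
    a_a: float = 2.0
    b_a: float = 1.0
    sigma2_mu1: float = 10.0
    sigma2_A: float = 1.0

    def __post_init__(self):
        if self.K < 2:
            raise InputError("K must be at least 2 (one inactive + one active component)")
        if self.beta < 0:
            raise InputError("beta must be nonnegative")
        for name in (
            "a_E", "b_E", "a_M", "b_M", "a_alpha", "b_alpha",
            "a_a", "b_a", "sigma2_mu1", "sigma2_A",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclasses.dataclass
class FitResult:
    """Output of an optimizer run."""

    state: MixtureState
    sources: SourceField
    objective_trace: Sequence[float]
    k_hat: int
    converged: bool
    iterations: int
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# density building blocks
# ---------------------------------------------------------------------------

def ig_logpdf(x: float, a: float, b: float) -> float:
    """Log density of the inverse-gamma distribution with shape a, scale b."""
    if x <= 0:
        return -np.inf
    return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x


def potts_log_kernel(Z: np.ndarray, beta: float, grid) -> float:
    """Unnormalized Potts log-probability ``beta * sum_{h~j} delta(Z_j, Z_h)``.

    ``delta`` is +1 when two first-order neighbours share a label and -1
    otherwise (``delta = 2 Z_j' Z_h - 1``).  The normalizing constant G(beta)
    is intentionally omitted.
    """
    Z = _check_one_hot(Z)
    labels = np.argmax(Z, axis=1)
    e = grid.edges
    if e.size == 0:
        return 0.0
    same = labels[e[:, 0]] == labels[e[:, 1]]
    return float(beta) * float(np.sum(2 * same.astype(np.int64) - 1))


def residuals(dataset: SensorDataset, sources: SourceField):
    """Sensor-space residuals ``(eps_E, eps_M)`` of the linear forward model."""
    if sources.P != dataset.P or sources.T != dataset.T:
        raise InputError("source field dimensions do not match the dataset")
    eps_M = dataset.M - dataset.X_M @ sources.S
    eps_E = dataset.E - dataset.X_E @ sources.S
    return eps_E, eps_M


def log_joint_terms(
    dataset: SensorDataset,
    state: MixtureState,
    sources: SourceField,
    grid,
    hyper: Hyperparameters,
) -> dict:
    """Named additive terms of the joint log-posterior objective.

    Keys: the two sensor-likelihood terms, two inverse-gamma noise priors,
    the source mixture term, the VAR(1) dynamics term plus its initial-state
    prior, the Potts kernel, the variance priors on the mixture components,
    and the Gaussian / inverse-gamma priors on the VAR block.
    """
    if state.K != hyper.K:
        raise InputError("state and hyperparameters disagree on K")
    if grid.N_v != state.N_v:
        raise InputError("grid and state disagree on the number of voxels")
    if grid.v.shape[0] != dataset.P:
        raise InputError("grid location->voxel map does not cover all P locations")
    eps_E, eps_M = residuals(dataset, sources)

    T, n_M, n_E, K = dataset.T, dataset.n_M, dataset.n_E, state.K
    s2M, s2E, s2a = state.sigma2_M, state.sigma2_E, state.sigma2_a

    qM = float(np.sum(eps_M * dataset.solve_HM(eps_M)))
    qE = float(np.sum(eps_E * dataset.solve_HE(eps_E)))
    ll_M = -0.5 * T * n_M * LOG_2PI - 0.5 * T * (n_M * np.log(s2M) + dataset.logdet_HM) - qM / (2.0 * s2M)
    ll_E = -0.5 * T * n_E * LOG_2PI - 0.5 * T * (n_E * np.log(s2E) + dataset.logdet_HE) - qE / (2.0 * s2E)

    # mixture term: each location inherits the label of its voxel
    lab = state.labels[grid.v]
    mu_loc = state.mu[lab]          # P x T
    a_loc = state.alpha[lab]        # P
    dev = sources.S - mu_loc
    mix = float(
        np.sum(-0.5 * T * (LOG_2PI + np.log(a_loc)))
        - np.sum((dev * dev).sum(axis=1) / (2.0 * a_loc))
    )

    mu_A = state.mu_A
    innov = mu_A[:, 1:] - state.A @ mu_A[:, :-1]
    var_term = (
        -0.5 * (T - 1) * (K - 1) * (LOG_2PI + np.log(s2a))
        - float(np.sum(innov * innov)) / (2.0 * s2a)
    )
    init_term = (
        -0.5 * (K - 1) * (LOG_2PI + np.log(hyper.sigma2_mu1))
        - float(np.sum(mu_A[:, 0] ** 2)) / (2.0 * hyper.sigma2_mu1)
    )

    potts = potts_log_kernel(state.Z, hyper.beta, grid)

    alpha_prior = float(sum(ig_logpdf(a, hyper.a_alpha, hyper.b_alpha) for a in state.alpha))
    A_prior = float(
        -0.5 * state.A.size * (LOG_2PI + np.log(hyper.sigma2_A))
        - np.sum(state.A ** 2) / (2.0 * hyper.sigma2_A)
    )

    return {
        "loglik_M": ll_M,
        "loglik_E": ll_E,
        "prior_sigma2_M": ig_logpdf(s2M, hyper.a_M, hyper.b_M),
        "prior_sigma2_E": ig_logpdf(s2E, hyper.a_E, hyper.b_E),
        "mixture": mix,
        "var_dynamics": var_term,
        "var_initial": init_term,
        "potts": potts,
        "prior_alpha": alpha_prior,
        "prior_A": A_prior,
        "prior_sigma2_a": ig_logpdf(s2a, hyper.a_a, hyper.b_a),
    }


def log_joint(
    dataset: SensorDataset,
    state: MixtureState,
    sources: SourceField,
    grid,
    hyper: Hyperparameters,
) -> float:
    """Joint log-posterior objective (up to the constant Potts normalizer)."""
    return float(sum(log_joint_terms(dataset, state, sources, grid, hyper).values()))
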