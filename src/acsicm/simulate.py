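"""Synthetic ground truth and two-modality sensor data.

Emulates the simulation design used to evaluate the optimizers: latent labels
on a regular voxel grid with contiguous active regions, smooth Gaussian-bump
or sinusoidal active-component time courses, per-location sources drawn about
their component mean, a linear two-modality projection through seeded
unit-norm lead fields, and independent per-sensor Gaussian noise whose
variance is a stated fraction (default 5%) of that sensor's noiseless
temporal variance.  Trial-level data for the bootstrap replicates the same
recipe with an independent noise draw per trial.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from .model import InputError, MixtureState, SensorDataset
from .spatial import VoxelGrid

DEFAULT_NOISE_FRAC = 0.05  # noise variance as a fraction of signal variance
# Within-region source variance about the mean course.  The emulated design
# gives every location in an active region a common smooth profile, so the
# per-location jitter is kept small relative to unit peak amplitude.
DEFAULT_ALPHA_TRUE = 0.01


@dataclasses.dataclass
class GroundTruth:
    """Latent truth of one simulated instance.

    ``Z_true`` one-hot voxel labels (component 0 inactive), ``mu_true`` the
    K_true x T component mean courses (row 0 zero), ``S_true`` the P x T
    source field, ``active_mask`` flags locations whose voxel label is active.
    """

    Z_true: np.ndarray
    mu_true: np.ndarray
    S_true: np.ndarray
    active_mask: np.ndarray
    K_true: int

    def __post_init__(self):
        if np.any(self.mu_true[0] != 0.0):
            raise InputError("row 0 of mu_true (inactive component) must be zero")
        if self.Z_true.shape[1] != self.K_true:
            raise InputError("Z_true and K_true disagree")


def make_coords(P: int, seed: int = 0, box: float = 1.0) -> np.ndarray:
    """P uniform random cortical locations inside a cube of side ``box``."""
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box, size=(P, 3))


def make_lead_fields(n_M: int, n_E: int, P: int, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded random lead fields with independent normal entries and unit-norm columns.

    Stand-ins for head-model forward operators, which are out of scope;
    unit column norms put all locations on an equal sensitivity footing.
    """
    if min(n_M, n_E, P) < 1:
        raise InputError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    X_M = rng.standard_normal((n_M, P))
    X_E = rng.standard_normal((n_E, P))
    X_M /= np.linalg.norm(X_M, axis=0, keepdims=True)
    X_E /= np.linalg.norm(X_E, axis=0, keepdims=True)
    return X_M, X_E


def _grow_blocks(grid: VoxelGrid, n_blocks: int, block_size: int, rng: np.random.Generator) -> np.ndarray:
    """Disjoint contiguous voxel blocks grown by BFS from farthest-point seeds.

    Returns per-voxel labels: 0 = inactive, 1..n_blocks = active regions.
    """
    N_v = grid.N_v
    if n_blocks * block_size > N_v:
        raise InputError(
            f"cannot place {n_blocks} contiguous blocks of {block_size} voxels on {N_v} voxels"
        )
    vc = grid.voxel_coords().astype(float)
    # farthest-point seeds over voxel cells, first seed random for variety
    seeds = [int(rng.integers(N_v))]
    dist = np.linalg.norm(vc - vc[seeds[0]], axis=1)
    for _ in range(1, n_blocks):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(vc - vc[nxt], axis=1))

    nbrs = [[] for _ in range(N_v)]
    for i, j in grid.edges:
        nbrs[i].append(j)
        nbrs[j].append(i)

    labels = np.zeros(N_v, dtype=np.int64)
    for b, s in enumerate(seeds, start=1):
        if labels[s] != 0:  # seed swallowed by an earlier block: take a free voxel
            free = np.flatnonzero(labels == 0)
            if free.size == 0:
                raise InputError("grid exhausted while placing active blocks")
            s = int(free[0])
        frontier = [s]
        taken = 0
        while frontier and taken < block_size:
            cur = frontier.pop(0)
            if labels[cur] != 0:
                continue
            labels[cur] = b
            taken += 1
            for nb in nbrs[cur]:
                if labels[nb] == 0:
                    frontier.append(nb)
        if taken == 0:
            raise InputError("could not place all active blocks on the grid")
    return labels


def make_ground_truth(
    grid: VoxelGrid,
    K_true: int,
    T: int,
    signal_kind: str = "gaussian",
    separation: float = 1.0,
    seed: int = 0,
    alpha_true: float = DEFAULT_ALPHA_TRUE,
    block_size: Optional[int] = None,
) -> GroundTruth:
    """Latent labels, mean courses and sources for one simulated instance.

    The K_true - 1 active components occupy disjoint contiguous voxel blocks;
    the rest of the grid is inactive.  Active mean courses are Gaussian bumps
    peaking at staggered times (or sinusoids at staggered frequencies; or
    alternating with ``signal_kind='mixed'``), all with peak amplitude
    ``separation`` — 1.0 emulates the well-separated regime, 0.35 the
    less-separated one.  Sources are drawn location-wise as
    N(mu_label(t), alpha_true) independently over time.
    """
    if K_true < 2:
        raise InputError("K_true must be at least 2")
    if signal_kind not in ("gaussian", "sinusoid", "mixed"):
        raise InputError("signal_kind must be 'gaussian', 'sinusoid' or 'mixed'")
    rng = np.random.default_rng(seed)
    n_blocks = K_true - 1
    if block_size is None:
        block_size = max(1, grid.N_v // (2 * n_blocks))
    labels = _grow_blocks(grid, n_blocks, block_size, rng)

    s = np.linspace(0.0, 1.0, T)
    mu = np.zeros((K_true, T))
    for k in range(1, K_true):
        kind = signal_kind if signal_kind != "mixed" else ("sinusoid" if k % 2 == 0 else "gaussian")
        if kind == "gaussian":
            center = k / K_true
            mu[k] = separation * np.exp(-((s - center) ** 2) / (2 * 0.15**2))
        else:
            mu[k] = separation * np.sin(2.0 * np.pi * k * s)

    Z = np.zeros((grid.N_v, K_true), dtype=np.int8)
    Z[np.arange(grid.N_v), labels] = 1

    loc_labels = labels[grid.v]
    S = mu[loc_labels] + rng.normal(0.0, np.sqrt(alpha_true), size=(grid.P, T))
    return GroundTruth(
        Z_true=Z,
        mu_true=mu,
        S_true=S,
        active_mask=loc_labels != 0,
        K_true=K_true,
    )


def _noise_sd(signal: np.ndarray, noise_frac: float, var_floor: float) -> np.ndarray:
    """Per-sensor noise SD under the fractional-variance rule."""
    var = np.var(signal, axis=1)
    var = np.where(var > 0, var, var_floor)
    return np.sqrt(noise_frac * var)


def simulate_sensors(
    truth: GroundTruth,
    X_M: np.ndarray,
    X_E: np.ndarray,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    seed: int = 0,
    var_floor: float = 1e-6,
    coords: Optional[np.ndarray] = None,
) -> SensorDataset:
    """Project the true sources to both sensor arrays and add fractional noise.

    Each sensor receives i.i.d. Gaussian noise over time with variance equal
    to ``noise_frac`` times the temporal variance of its noiseless signal
    (sensors with zero signal variance fall back to ``var_floor``).
    """
    if noise_frac < 0:
        raise InputError("noise_frac must be nonnegative")
    rng = np.random.default_rng(seed)
    sig_M = X_M @ truth.S_true
    sig_E = X_E @ truth.S_true
    if noise_frac > 0:
        sd_M = _noise_sd(sig_M, noise_frac, var_floor)
        sd_E = _noise_sd(sig_E, noise_frac, var_floor)
        M = sig_M + rng.standard_normal(sig_M.shape) * sd_M[:, None]
        E = sig_E + rng.standard_normal(sig_E.shape) * sd_E[:, None]
    else:
        M, E = sig_M, sig_E
    return SensorDataset(M=M, E=E, X_M=X_M, X_E=X_E, coords=coords)


def make_trials(
    truth: GroundTruth,
    X_M: np.ndarray,
    X_E: np.ndarray,
    n_trials: int,
    noise_frac: float = DEFAULT_NOISE_FRAC,
    seed: int = 0,
    var_floor: float = 1e-6,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trial-replicated sensor tensors (n_trials x sensors x T) for the bootstrap.

    Every trial is the same noiseless projection plus an independent noise
    draw at the per-trial variance, so the across-trial average reproduces
    ``simulate_sensors``'s statistics with noise variance scaled by 1/n_trials.
    """
    if n_trials < 1:
        raise InputError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    sig_M = X_M @ truth.S_true
    sig_E = X_E @ truth.S_true
    out = []
    for sig in (sig_M, sig_E):
        if noise_frac > 0:
            sd = _noise_sd(sig, noise_frac, var_floor)
            noise = rng.standard_normal((n_trials,) + sig.shape) * sd[None, :, None]
            out.append(sig[None] + noise)
        else:
            out.append(np.repeat(sig[None], n_trials, axis=0))
    return out[0], out[1]


def truth_as_state(truth: GroundTruth, T: int, sigma2: float = 1.0) -> MixtureState:
    """Cast a ground truth to a structurally valid MixtureState (for tests/inits)."""
    K = truth.K_true
    return MixtureState(
        Z=truth.Z_true,
        mu=truth.mu_true,
        alpha=np.full(K, DEFAULT_ALPHA_TRUE),
        A=np.zeros((K - 1, K - 1)),
        sigma2_a=sigma2,
        sigma2_E=sigma2,
        sigma2_M=sigma2,
    )
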