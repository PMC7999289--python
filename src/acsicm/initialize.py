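"""Data-driven starting values shared by both optimizers.

Sources are initialized by a ridge-regularized minimum-norm inverse of the
stacked two-modality forward model; voxels are labelled by K-means on their
aggregated initial source time courses, with the lowest-power cluster taken
as the inactive component.  K-means run at a generous K routinely splits one
genuine activity pattern into near-duplicate clusters, and ICM — a
deterministic coordinate ascent — cannot merge such duplicates once their
means and variances have been fit to their members; conversely an
under-split start is never repaired.  The number of initial clusters is
therefore chosen by silhouette score over 2..K, a standard order-selection
device for mixture starts.  Both optimizers are meant to start from the same
initialization so their final objectives are directly comparable.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .model import Hyperparameters, MixtureState, SensorDataset, SourceField
from .spatial import VoxelGrid


def minimum_norm_sources(dataset: SensorDataset, ridge_scale: float = 0.1) -> SourceField:
    """Ridge minimum-norm estimate S = X'(XX' + lambda I)^{-1} Y on stacked modalities."""
    X = np.vstack([dataset.X_M, dataset.X_E])
    Y = np.vstack([dataset.M, dataset.E])
    G = X @ X.T
    lam = ridge_scale * float(np.trace(G)) / G.shape[0]
    S = X.T @ np.linalg.solve(G + lam * np.eye(G.shape[0]), Y)
    return SourceField(S)


def _select_order_by_silhouette(vox: np.ndarray, K: int, seed: int) -> np.ndarray:
    """K-means labels with the cluster count in 2..K chosen by silhouette score."""
    kmax = min(K, vox.shape[0] - 1)
    best_labels, best_score = None, -np.inf
    for k in range(2, kmax + 1):
        km = KMeans(n_clusters=k, n_init=4, random_state=int(seed) % (2**31))
        lab = km.fit_predict(vox)
        if len(np.unique(lab)) < 2:
            continue
        score = silhouette_score(vox, lab)
        if score > best_score:
            best_score, best_labels = score, lab
    if best_labels is None:  # degenerate data: single cluster
        best_labels = np.zeros(vox.shape[0], dtype=np.int64)
    _, compact = np.unique(best_labels, return_inverse=True)
    return compact


def default_init(
    dataset: SensorDataset,
    grid: VoxelGrid,
    hyper: Hyperparameters,
    seed: int = 0,
    ridge_scale: float = 0.1,
) -> Tuple[MixtureState, SourceField]:
    """K-means-on-minimum-norm starting values for ICM / ACS-ICM."""
    K, T = hyper.K, dataset.T
    sources = minimum_norm_sources(dataset, ridge_scale)

    # aggregate initial courses to voxel level (empty voxels -> zero course)
    vox = np.zeros((grid.N_v, T))
    np.add.at(vox, grid.v, sources.S)
    nz = grid.counts > 0
    vox[nz] /= grid.counts[nz, None]

    raw = _select_order_by_silhouette(vox, K, seed)
    n_used = int(raw.max()) + 1

    # order clusters by mean power; weakest becomes the inactive component 0
    power = np.array([
        float(np.mean(np.sum(vox[raw == c] ** 2, axis=1))) if np.any(raw == c) else 0.0
        for c in range(n_used)
    ])
    order = np.argsort(power)          # ascending: order[0] -> component 0
    remap = np.empty(n_used, dtype=np.int64)
    remap[order] = np.arange(n_used)
    lab_vox = remap[raw]

    Z = np.zeros((grid.N_v, K), dtype=np.int8)
    Z[np.arange(grid.N_v), lab_vox] = 1

    # component means from location-level initial sources
    loc_lab = lab_vox[grid.v]
    mu = np.zeros((K, T))
    alpha = np.full(K, 1.0)
    for l in range(1, K):
        sel = loc_lab == l
        if np.any(sel):
            mu[l] = sources.S[sel].mean(axis=0)
            alpha[l] = max(float(np.var(sources.S[sel] - mu[l][None, :])), 1e-3)
    sel0 = loc_lab == 0
    if np.any(sel0):
        alpha[0] = max(float(np.var(sources.S[sel0])), 1e-3)

    rM = dataset.M - dataset.X_M @ sources.S
    rE = dataset.E - dataset.X_E @ sources.S
    sigma2_M = max(float(np.mean(rM**2)), 1e-6)
    sigma2_E = max(float(np.mean(rE**2)), 1e-6)

    state = MixtureState(
        Z=Z,
        mu=mu,
        alpha=alpha,
        A=np.zeros((K - 1, K - 1)),
        sigma2_a=1.0,
        sigma2_E=sigma2_E,
        sigma2_M=sigma2_M,
    )
    return state, sources
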