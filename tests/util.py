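"""Shared builders and independent oracles for the test suite.

The oracle evaluates every density of the joint objective through
scipy.stats, voxel neighbourhoods through brute-force integer-coordinate
comparison, and the Potts kernel by explicit pair enumeration — a route fully
independent of the package's own vectorized implementation.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

import acsicm as m


def random_spd(n: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((n, n))
    return A @ A.T + n * np.eye(n)


def random_instance(
    seed: int,
    n_M: int = 4,
    n_E: int = 4,
    P: int = 10,
    dims=(2, 2, 2),
    T: int = 5,
    K: int = 3,
    identity_H: bool = False,
):
    """A fully random (dataset, state, sources, grid, hyper) tuple."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, (P, 3))
    grid = m.build_grid(coords, dims)
    X_M = rng.standard_normal((n_M, P))
    X_E = rng.standard_normal((n_E, P))
    H_M = None if identity_H else random_spd(n_M, rng)
    H_E = None if identity_H else random_spd(n_E, rng)
    dataset = m.SensorDataset(
        M=rng.standard_normal((n_M, T)),
        E=rng.standard_normal((n_E, T)),
        X_M=X_M,
        X_E=X_E,
        H_M=H_M,
        H_E=H_E,
        coords=coords,
    )
    lab = rng.integers(0, K, grid.N_v)
    Z = np.zeros((grid.N_v, K), dtype=np.int8)
    Z[np.arange(grid.N_v), lab] = 1
    mu = rng.standard_normal((K, T))
    mu[0] = 0.0
    state = m.MixtureState(
        Z=Z,
        mu=mu,
        alpha=rng.uniform(0.5, 2.0, K),
        A=rng.normal(0.0, 0.3, (K - 1, K - 1)),
        sigma2_a=float(rng.uniform(0.5, 2.0)),
        sigma2_E=float(rng.uniform(0.5, 2.0)),
        sigma2_M=float(rng.uniform(0.5, 2.0)),
    )
    sources = m.SourceField(rng.standard_normal((P, T)))
    hyper = m.Hyperparameters(K=K)
    return dataset, state, sources, grid, hyper


def oracle_potts(Z: np.ndarray, beta: float, dims) -> float:
    labels = np.argmax(Z, axis=1)
    coords = np.stack(np.unravel_index(np.arange(Z.shape[0]), dims), axis=1)
    total = 0.0
    for i in range(Z.shape[0]):
        for j in range(i + 1, Z.shape[0]):
            if np.sum(np.abs(coords[i] - coords[j])) == 1:
                total += 1.0 if labels[i] == labels[j] else -1.0
    return beta * total


def oracle_log_joint(dataset, state, sources, grid, hyper) -> float:
    """Term-by-term evaluation of the joint log density via scipy.stats."""
    S, Z, mu, alpha, A = sources.S, state.Z, state.mu, state.alpha, state.A
    T, K = dataset.T, state.K
    total = 0.0
    for t in range(T):
        total += stats.multivariate_normal.logpdf(
            dataset.M[:, t], dataset.X_M @ S[:, t], state.sigma2_M * dataset.H_M
        )
        total += stats.multivariate_normal.logpdf(
            dataset.E[:, t], dataset.X_E @ S[:, t], state.sigma2_E * dataset.H_E
        )
    total += stats.invgamma.logpdf(state.sigma2_M, hyper.a_M, scale=hyper.b_M)
    total += stats.invgamma.logpdf(state.sigma2_E, hyper.a_E, scale=hyper.b_E)

    labels = np.argmax(Z, axis=1)
    for j in range(dataset.P):
        l = labels[grid.v[j]]
        for t in range(T):
            total += stats.norm.logpdf(S[j, t], mu[l, t], np.sqrt(alpha[l]))

    mu_A = mu[1:]
    for t in range(1, T):
        total += stats.multivariate_normal.logpdf(
            mu_A[:, t], A @ mu_A[:, t - 1], state.sigma2_a * np.eye(K - 1)
        )
    total += stats.multivariate_normal.logpdf(
        mu_A[:, 0], np.zeros(K - 1), hyper.sigma2_mu1 * np.eye(K - 1)
    )
    total += oracle_potts(Z, hyper.beta, grid.dims)
    for l in range(K):
        total += stats.invgamma.logpdf(alpha[l], hyper.a_alpha, scale=hyper.b_alpha)
    total += float(np.sum(stats.norm.logpdf(A, 0.0, np.sqrt(hyper.sigma2_A))))
    total += stats.invgamma.logpdf(state.sigma2_a, hyper.a_a, scale=hyper.b_a)
    return float(total)


def make_synthetic(
    seed_noise: int,
    P: int = 100,
    n: int = 20,
    T: int = 30,
    K_true: int = 3,
    dims=(3, 3, 3),
    separation: float = 1.0,
    noise_frac: float = 0.05,
):
    """One replicate of the scaled-down simulation design (shared truth seeds)."""
    coords = m.make_coords(P, seed=0)
    grid = m.build_grid(coords, dims)
    X_M, X_E = m.make_lead_fields(n, n, P, seed=1)
    truth = m.make_ground_truth(grid, K_true, T, separation=separation, seed=2)
    dataset = m.simulate_sensors(truth, X_M, X_E, noise_frac=noise_frac,
                                 seed=seed_noise, coords=coords)
    return dataset, truth, grid
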