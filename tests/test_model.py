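"""Core model types, the joint objective and its named terms."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import gammaln

import acsicm as m
from util import oracle_log_joint, random_instance


def _zero_configuration():
    """All-zero data and sources, unit variances, single voxel, K=2, T=2."""
    T, K = 2, 2
    coords = np.array([[0.5, 0.5, 0.5]])
    grid = m.build_grid(coords, (1, 1, 1))
    dataset = m.SensorDataset(
        M=np.zeros((1, T)), E=np.zeros((1, T)),
        X_M=np.ones((1, 1)), X_E=np.ones((1, 1)), coords=coords,
    )
    state = m.MixtureState(
        Z=np.array([[0, 1]], dtype=np.int8),
        mu=np.zeros((K, T)),
        alpha=np.ones(K),
        A=np.zeros((K - 1, K - 1)),
        sigma2_a=1.0, sigma2_E=1.0, sigma2_M=1.0,
    )
    sources = m.SourceField(np.zeros((1, T)))
    hyper = m.Hyperparameters(K=K)
    return dataset, state, sources, grid, hyper


def test_log_joint_zero_configuration_closed_form():
    """At the all-zero configuration every quadratic form vanishes and the
    objective reduces to a hand-summable constant of normalizers and prior
    densities at their evaluation points."""
    dataset, state, sources, grid, hyper = _zero_configuration()
    ln2pi = np.log(2 * np.pi)

    def ig_at_one(a, b):  # log IG(1; a, b)
        return a * np.log(b) - gammaln(a) - (a + 1) * 0.0 - b

    hand = (
        -0.5 * 2 * (1 + 1) * ln2pi              # two Gaussian likelihoods, T=2
        + 2 * ig_at_one(2.0, 1.0)               # sigma2_M, sigma2_E priors
        - 0.5 * 1 * 2 * ln2pi                   # mixture: P=1, T=2, alpha=1
        - 0.5 * 1 * ln2pi                       # VAR innovation at t=2
        - 0.5 * (ln2pi + np.log(10.0))          # initial active mean, sigma2_mu1=10
        + 0.0                                   # Potts: single voxel, no pairs
        + 2 * ig_at_one(2.0, 1.0)               # two alpha priors
        - 0.5 * ln2pi                           # A entry at 0, sigma2_A=1
        + ig_at_one(2.0, 1.0)                   # sigma2_a prior
    )
    assert m.log_joint(dataset, state, sources, grid, hyper) == pytest.approx(hand, rel=1e-12)


@pytest.mark.parametrize("seed", range(8))
def test_log_joint_matches_independent_oracle(seed):
    dataset, state, sources, grid, hyper = random_instance(seed)
    got = m.log_joint(dataset, state, sources, grid, hyper)
    want = oracle_log_joint(dataset, state, sources, grid, hyper)
    assert got == pytest.approx(want, rel=1e-10)


def test_source_perturbation_changes_only_likelihood_and_mixture_terms():
    dataset, state, sources, grid, hyper = random_instance(3)
    base = m.log_joint_terms(dataset, state, sources, grid, hyper)
    S2 = sources.S.copy()
    S2[4, 2] += 0.7
    pert = m.log_joint_terms(dataset, state, m.SourceField(S2), grid, hyper)
    changed = {"loglik_M", "loglik_E", "mixture"}
    for name in base:
        if name in changed:
            assert base[name] != pert[name]
        else:
            assert base[name] == pert[name]


@pytest.mark.parametrize(
    "labels,beta,expected",
    [
        ([0, 0], 0.3, 0.3),     # two neighbours, same label
        ([0, 1], 0.3, -0.3),    # two neighbours, different labels
    ],
)
def test_potts_two_voxel_examples(labels, beta, expected):
    grid = m.build_grid(np.array([[0.1, 0.5, 0.5], [0.9, 0.5, 0.5]]), (2, 1, 1))
    Z = np.zeros((2, 2), dtype=np.int8)
    Z[np.arange(2), labels] = 1
    assert m.potts_log_kernel(Z, beta, grid) == pytest.approx(expected)


def test_potts_uniform_labels_count_pairs():
    """On a 3x3x3 grid there are 54 first-order pairs, all agreeing."""
    rng = np.random.default_rng(0)
    grid = m.build_grid(rng.uniform(0, 1, (30, 3)), (3, 3, 3))
    Z = np.zeros((27, 2), dtype=np.int8)
    Z[:, 0] = 1
    assert m.potts_log_kernel(Z, 0.1, grid) == pytest.approx(5.4)


@given(st.integers(0, 10_000))
def test_potts_invariant_under_label_permutation(seed):
    rng = np.random.default_rng(seed)
    K = 4
    grid = m.build_grid(rng.uniform(0, 1, (10, 3)), (2, 2, 2))
    lab = rng.integers(0, K, grid.N_v)
    Z = np.zeros((grid.N_v, K), dtype=np.int8)
    Z[np.arange(grid.N_v), lab] = 1
    perm = rng.permutation(K)
    Zp = np.zeros_like(Z)
    Zp[np.arange(grid.N_v), perm[lab]] = 1
    assert m.potts_log_kernel(Z, 0.7, grid) == m.potts_log_kernel(Zp, 0.7, grid)


class TestResiduals:
    def test_zero_sources_return_data(self):
        dataset, _, _, _, _ = random_instance(1)
        eps_E, eps_M = m.residuals(dataset, m.SourceField(np.zeros((dataset.P, dataset.T))))
        np.testing.assert_array_equal(eps_E, dataset.E)
        np.testing.assert_array_equal(eps_M, dataset.M)

    def test_exact_forward_model_gives_zero(self):
        rng = np.random.default_rng(2)
        X_M, X_E = m.make_lead_fields(4, 5, 6, seed=0)
        S = rng.standard_normal((6, 3))
        dataset = m.SensorDataset(M=X_M @ S, E=X_E @ S, X_M=X_M, X_E=X_E)
        eps_E, eps_M = m.residuals(dataset, m.SourceField(S))
        np.testing.assert_allclose(eps_E, 0, atol=1e-12)
        np.testing.assert_allclose(eps_M, 0, atol=1e-12)

    def test_column_by_column_hand_computation(self):
        dataset, _, sources, _, _ = random_instance(4)
        eps_E, eps_M = m.residuals(dataset, sources)
        for t in range(dataset.T):
            np.testing.assert_allclose(eps_M[:, t], dataset.M[:, t] - dataset.X_M @ sources.S[:, t])
            np.testing.assert_allclose(eps_E[:, t], dataset.E[:, t] - dataset.X_E @ sources.S[:, t])

    @given(st.integers(0, 10_000))
    def test_linearity(self, seed):
        """residuals(data, S1 + S2) + X S2 reproduces residuals(data, S1)."""
        rng = np.random.default_rng(seed)
        dataset, _, _, _, _ = random_instance(5)
        S1 = rng.standard_normal((dataset.P, dataset.T))
        S2 = rng.standard_normal((dataset.P, dataset.T))
        eE12, eM12 = m.residuals(dataset, m.SourceField(S1 + S2))
        eE1, eM1 = m.residuals(dataset, m.SourceField(S1))
        np.testing.assert_allclose(eM12 + dataset.X_M @ S2, eM1, atol=1e-10)
        np.testing.assert_allclose(eE12 + dataset.X_E @ S2, eE1, atol=1e-10)


class TestValidation:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(m.InputError, match="n_M"):
            m.SensorDataset(M=np.zeros((3, 4)), E=np.zeros((2, 4)),
                            X_M=np.zeros((4, 5)), X_E=np.zeros((2, 5)))

    def test_single_time_point_rejected(self):
        with pytest.raises(m.InputError, match="T >= 2"):
            m.SensorDataset(M=np.zeros((2, 1)), E=np.zeros((2, 1)),
                            X_M=np.zeros((2, 5)), X_E=np.zeros((2, 5)))

    def test_non_spd_noise_covariance_rejected(self):
        H_bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        with pytest.raises(m.InputError, match="H_M"):
            m.SensorDataset(M=np.zeros((2, 3)), E=np.zeros((2, 3)),
                            X_M=np.zeros((2, 4)), X_E=np.zeros((2, 4)), H_M=H_bad)

    def test_nonzero_inactive_mean_rejected(self):
        with pytest.raises(m.InputError, match="inactive"):
            m.MixtureState(Z=np.array([[1, 0]], dtype=np.int8), mu=np.ones((2, 3)),
                           alpha=np.ones(2), A=np.zeros((1, 1)),
                           sigma2_a=1, sigma2_E=1, sigma2_M=1)

    def test_non_one_hot_labels_rejected(self):
        with pytest.raises(m.InputError, match="one-hot"):
            m.potts_log_kernel(np.array([[1, 1]]), 0.3, None)

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(m.InputError):
            m.Hyperparameters(K=1)
        with pytest.raises(m.InputError):
            m.Hyperparameters(K=3, beta=-0.1)
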