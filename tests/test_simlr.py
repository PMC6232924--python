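import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.cluster import SpectralClustering
from sklearn.metrics import adjusted_rand_score

from morphconn import SIMLR, SimlrConfig, build_kernel_bank, fit_simlr
from morphconn.kernels import KernelBank, KernelParams
from morphconn.simlr import (
    diffuse,
    initial_similarity,
    objective,
    project_rows_to_simplex,
    update_L,
    update_S,
    update_w,
)


def simplex_qp_oracle(a, beta):
    """Generic solver for min_{s in simplex} -a.s + beta ||s||^2."""
    n = len(a)
    res = minimize(
        lambda s: -a @ s + beta * s @ s,
        np.full(n, 1.0 / n),
        jac=lambda s: -a + 2 * beta * s,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda s: s.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x


def single_kernel_bank(K):
    K = np.asarray(K, dtype=float)
    return KernelBank(kernels=K[None], params=[KernelParams(1.0, 1)])


class TestSimplexProjection:
    def test_matches_qp_oracle(self, rng):
        V = rng.standard_normal((8, 8)) * 3
        beta = 0.7
        S = project_rows_to_simplex(V / (2 * beta))
        for i in range(8):
            expected = simplex_qp_oracle(V[i], beta)
            np.testing.assert_allclose(S[i], expected, atol=1e-6)

    def test_rows_on_simplex(self, rng):
        S = project_rows_to_simplex(rng.standard_normal((20, 15)))
        assert np.all(S >= 0)
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-12)


class TestObjective:
    def test_hand_arithmetic_n3_m1(self):
        K = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        bank = single_kernel_bank(K)
        n, c = 3, 2
        S = np.full((n, n), 1.0 / n)
        L = np.eye(n)[:, :c]
        w = np.array([1.0])
        beta, gamma, rho = 0.8, 1.0, 1.0
        # independent hand computation, term by term
        fit_term = -sum(w[0] * K[i, j] * S[i, j] for i in range(n) for j in range(n))
        reg_term = beta * sum(S[i, j] ** 2 for i in range(n) for j in range(n))
        lap = np.eye(n) - S
        lap_term = gamma * np.trace(L.T @ lap @ L)
        ent_term = rho * (1.0 * np.log(1.0))
        expected = fit_term + reg_term + lap_term + ent_term
        assert objective(S, L, w, bank, beta, gamma, rho) == pytest.approx(expected)

    def test_entropy_term_at_uniform_weights(self, rng):
        m, n = 5, 4
        K = np.zeros((n, n))
        bank = KernelBank(kernels=np.zeros((m, n, n)),
                          params=[KernelParams(1.0, 1)] * m)
        S = np.zeros((n, n))
        L = np.linalg.qr(rng.standard_normal((n, 2)))[0]
        w = np.full(m, 1.0 / m)
        rho = 2.5
        # only the gamma tr(L'L) = gamma*c and entropy terms survive
        val = objective(S, L, w, bank, 1.0, 0.0, rho)
        assert val == pytest.approx(rho * np.log(1.0 / m))

    def test_gamma_term_is_sum_of_smallest_laplacian_eigenvalues(self, rng):
        A = np.abs(rng.standard_normal((6, 6)))
        S = (A + A.T) / 2
        S = S / S.sum(axis=1, keepdims=True)
        S = (S + S.T) / 2  # symmetric; rows renormalized below
        S = S / S.sum(axis=1, keepdims=True)
        c = 3
        L = update_L(S, c)
        lam = np.linalg.eigvalsh(np.eye(6) - (S + S.T) / 2)
        gamma_term = np.trace(L.T @ (np.eye(6) - S) @ L)
        assert gamma_term == pytest.approx(np.sum(lam[:c]), abs=1e-10)


class TestUpdateL:
    def test_block_diagonal_gives_zero_gamma_term(self):
        blocks = [np.full((3, 3), 1.0 / 3.0)] * 2
        S = np.block([[blocks[0], np.zeros((3, 3))],
                      [np.zeros((3, 3)), blocks[1]]])
        L = update_L(S, 2)
        assert np.trace(L.T @ (np.eye(6) - S) @ L) == pytest.approx(0.0, abs=1e-10)

    def test_matches_dense_eigendecomposition(self):
        S = np.array([[0.6, 0.4, 0.0, 0.0],
                      [0.4, 0.6, 0.0, 0.0],
                      [0.0, 0.0, 0.7, 0.3],
                      [0.0, 0.0, 0.3, 0.7]])
        L = update_L(S, 2)
        lam, vecs = np.linalg.eigh(np.eye(4) - S)
        # same spanned subspace as the two smallest-eigenvalue eigenvectors
        proj_a = L @ L.T
        proj_b = vecs[:, :2] @ vecs[:, :2].T
        np.testing.assert_allclose(proj_a, proj_b, atol=1e-10)
        np.testing.assert_allclose(L.T @ L, np.eye(2), atol=1e-10)

    def test_objective_invariant_to_column_rotation(self, rng):
        A = np.abs(rng.standard_normal((5, 5)))
        S = A / A.sum(axis=1, keepdims=True)
        bank = single_kernel_bank(np.eye(5))
        L = update_L(S, 2)
        theta = 0.83
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        w = np.array([1.0])
        assert objective(S, L @ R, w, bank, 0.5, 1.3, 1.0) == pytest.approx(
            objective(S, L, w, bank, 0.5, 1.3, 1.0))


class TestUpdateW:
    def test_identical_kernels_give_uniform_weights(self, rng):
        K = np.abs(rng.standard_normal((4, 4)))
        bank = KernelBank(kernels=np.stack([K, K, K]),
                          params=[KernelParams(1.0, 1)] * 3)
        S = np.full((4, 4), 0.25)
        np.testing.assert_allclose(update_w(S, bank, 1.0), np.full(3, 1 / 3))

    def test_large_rho_flattens_weights(self, rng):
        K1 = np.abs(rng.standard_normal((4, 4)))
        K2 = np.abs(rng.standard_normal((4, 4)))
        bank = KernelBank(kernels=np.stack([K1, K2]),
                          params=[KernelParams(1.0, 1)] * 2)
        S = np.full((4, 4), 0.25)
        w = update_w(S, bank, rho=1e6)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_hand_softmax_two_kernels(self):
        # engineer <K1,S> - <K2,S> = rho log 2  ->  w = (2/3, 1/3)
        rho = 0.7
        n = 2
        S = np.full((n, n), 0.5)
        K1 = np.full((n, n), (rho * np.log(2.0)) / (n * n * 0.5))
        K2 = np.zeros((n, n))
        bank = KernelBank(kernels=np.stack([K1, K2]),
                          params=[KernelParams(1.0, 1)] * 2)
        np.testing.assert_allclose(update_w(S, bank, rho), [2 / 3, 1 / 3],
                                   atol=1e-12)


class TestUpdateS:
    def test_uniform_scores_give_uniform_rows(self):
        n = 5
        bank = single_kernel_bank(np.ones((n, n)))
        L = np.zeros((n, 2))
        S = update_S(L, np.array([1.0]), bank, beta=0.8, gamma=1.0)
        np.testing.assert_allclose(S, np.full((n, n), 1.0 / n), atol=1e-12)

    def test_winner_take_all_at_small_beta(self):
        n = 3
        K = np.array([[10.0, 0.1, 0.1], [0.1, 10.0, 0.1], [0.1, 0.1, 10.0]])
        bank = single_kernel_bank(K)
        S = update_S(np.zeros((n, 1)), np.array([1.0]), bank,
                     beta=1e-4, gamma=1.0)
        np.testing.assert_allclose(S, np.eye(n), atol=1e-8)

    def test_matches_generic_qp_oracle(self, rng):
        n, c = 8, 3
        A = np.abs(rng.standard_normal((n, n)))
        bank = single_kernel_bank((A + A.T) / 2)
        L = np.linalg.qr(rng.standard_normal((n, c)))[0]
        w = np.array([1.0])
        beta, gamma = 0.6, 1.2
        S = update_S(L, w, bank, beta, gamma)
        scores = bank.kernels[0] + gamma * (L @ L.T)
        for i in range(n):
            expected = simplex_qp_oracle(scores[i], beta)
            np.testing.assert_allclose(S[i], expected, atol=1e-6)

    def test_nonpositive_beta_rejected(self):
        bank = single_kernel_bank(np.eye(3))
        with pytest.raises(ValueError, match="beta"):
            update_S(np.zeros((3, 1)), np.array([1.0]), bank, beta=0.0, gamma=1.0)


class TestDiffuse:
    def test_zero_steps_identity(self, rng):
        A = np.abs(rng.standard_normal((6, 6)))
        S = A / A.sum(axis=1, keepdims=True)
        np.testing.assert_array_equal(diffuse(S, 3, 0), S)

    def test_block_structure_preserved(self):
        B = np.full((3, 3), 1.0 / 3.0)
        S = np.block([[B, np.zeros((3, 3))], [np.zeros((3, 3)), B]])
        out = diffuse(S, 2, 2)
        np.testing.assert_allclose(out[:3, 3:], 0.0, atol=1e-15)
        np.testing.assert_allclose(out[3:, :3], 0.0, atol=1e-15)

    def test_rows_sum_to_one(self, rng):
        A = np.abs(rng.standard_normal((10, 10)))
        S = A / A.sum(axis=1, keepdims=True)
        out = diffuse(S, 4, 3)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_knn_too_large_rejected(self, rng):
        S = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="knn"):
            diffuse(S, 4, 1)


def two_blob_features(rng, n_per=10, d=5, gap=50.0):
    a = rng.standard_normal((n_per, d))
    b = rng.standard_normal((n_per, d)) + gap
    X = np.vstack([a, b])
    truth = np.array([0] * n_per + [1] * n_per)
    return X, truth


class TestFit:
    def test_constraints_hold_at_every_iteration(self, rng):
        X, _ = two_blob_features(rng)
        bank = build_kernel_bank(X, sigma_grid=[1.0, 2.0], k_grid=[3, 5])
        checked = []

        def cb(it, S, L, w):
            assert np.all(S >= -1e-12)
            np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-8)
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
            checked.append(it)

        fit_simlr(bank, SimlrConfig(c=2, max_iter=10, tol=1e-12), callback=cb)
        assert len(checked) >= 2

    def test_objective_monotone_without_diffusion(self, rng):
        X, _ = two_blob_features(rng)
        bank = build_kernel_bank(X, sigma_grid=[1.0, 1.5], k_grid=[3])
        state = fit_simlr(bank, SimlrConfig(c=2, diffusion_steps=0,
                                            max_iter=40, tol=1e-12))
        diffs = np.diff(state.objective_trace)
        assert np.all(diffs <= 1e-10)

    def test_recovers_separated_groups(self, rng):
        X, truth = two_blob_features(rng, n_per=12)
        model = SIMLR(n_clusters=2, sigma_grid=[1.0, 1.5, 2.0], k_grid=[3, 5],
                      random_state=0)
        labels = model.fit_predict(X)
        assert adjusted_rand_score(truth, labels) == 1.0
        # similarity is near block-diagonal: within-group mass dominates
        S = model.similarity_
        within = S[:12, :12].sum() + S[12:, 12:].sum()
        assert within / S.sum() > 0.95

    def test_identical_subjects_give_uniform_similarity(self):
        X = np.ones((8, 3))
        bank = build_kernel_bank(X, sigma_grid=[1.0], k_grid=[2])
        state = fit_simlr(bank, SimlrConfig(c=2, diffusion_steps=0, max_iter=5))
        np.testing.assert_allclose(state.S, np.full((8, 8), 1.0 / 8.0),
                                   atol=1e-10)

    def test_single_kernel_matches_spectral_clustering(self, rng):
        X, truth = two_blob_features(rng, n_per=10)
        bank = build_kernel_bank(X, sigma_grid=[1.5], k_grid=[4])
        state = fit_simlr(bank, SimlrConfig(c=2, diffusion_steps=0, max_iter=30))
        from morphconn import cluster_latent

        ours = cluster_latent(state.L, 2, seed=0)
        sc = SpectralClustering(n_clusters=2, affinity="precomputed",
                                random_state=0).fit_predict(bank.kernels[0])
        assert adjusted_rand_score(truth, ours) == 1.0
        assert adjusted_rand_score(truth, sc) == 1.0

    def test_initial_similarity_is_row_normalized_average(self, rng):
        X = rng.standard_normal((9, 4))
        bank = build_kernel_bank(X, sigma_grid=[1.0, 2.0], k_grid=[3])
        S0 = initial_similarity(bank)
        expected = bank.kernels.mean(axis=0)
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(S0, expected)
        np.testing.assert_allclose(S0.sum(axis=1), 1.0, atol=1e-12)

    def test_fit_deterministic(self, rng):
        X, _ = two_blob_features(rng)
        m1 = SIMLR(n_clusters=2, sigma_grid=[1.0], k_grid=[3], random_state=0).fit(X)
        m2 = SIMLR(n_clusters=2, sigma_grid=[1.0], k_grid=[3], random_state=0).fit(X)
        np.testing.assert_array_equal(m1.similarity_, m2.similarity_)
        np.testing.assert_array_equal(m1.labels_, m2.labels_)
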