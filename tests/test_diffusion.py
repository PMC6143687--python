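import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from cytotraject.diffusion import (
    DiffusionParams,
    align_signs,
    compute_diffusion_map,
    density_normalized_transition,
    estimate_sigma,
    kernel_matrix,
    pairwise_knn,
    spectral_decompose,
)
from cytotraject.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    IsolatedPointError,
)

from conftest import make_table
from dense_oracle import brute_force_transition, dense_diffusion_map


class TestKnn:
    def test_collinear_union_edges(self):
        X = np.array([[0.0], [1.0], [3.0]])
        g = pairwise_knn(X, k=1)
        edges = {(r, c): d for r, c, d in zip(g.rows, g.cols, g.dists)}
        # 0 and 1 are mutual NNs; 2's NN is 1, symmetrized by union
        assert edges == {(0, 1): 1.0, (1, 0): 1.0, (1, 2): 2.0, (2, 1): 2.0}

    def test_duplicate_points_zero_distance(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        g = pairwise_knn(X, k=1)
        assert np.min(g.dists) == 0.0

    def test_full_graph_matches_dense(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        g = pairwise_knn(X, k=39)
        from scipy.spatial import distance_matrix
        D = distance_matrix(X, X)
        dense = {(i, j): D[i, j] for i in range(40) for j in range(40)
                 if i != j}
        got = {(r, c): d for r, c, d in zip(g.rows, g.cols, g.dists)}
        assert set(got) == set(dense)
        np.testing.assert_allclose(
            [got[k] for k in sorted(got)], [dense[k] for k in sorted(dense)])

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            pairwise_knn(np.zeros((5, 2)), k=5)


class TestSigma:
    def test_unit_line(self):
        X = np.arange(100, dtype=float)[:, None]
        assert estimate_sigma(pairwise_knn(X, 2), k_scale=1) == 1.0

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        s1 = estimate_sigma(pairwise_knn(X, 10), k_scale=5)
        s3 = estimate_sigma(pairwise_knn(3.0 * X, 10), k_scale=5)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-12)

    def test_identical_points_degenerate(self):
        X = np.zeros((20, 2))
        with pytest.raises(DegenerateInputError):
            estimate_sigma(pairwise_knn(X, 5), k_scale=3)

    def test_k_scale_out_of_range(self):
        X = np.arange(10, dtype=float)[:, None]
        with pytest.raises(ValueError):
            estimate_sigma(pairwise_knn(X, 2), k_scale=5)


class TestKernel:
    def test_closed_forms(self):
        X = np.array([[0.0], [1.0], [1.0]])
        g = pairwise_knn(X, 2)
        K = kernel_matrix(g, sigma=1.0 / np.sqrt(2)).toarray()
        # duplicate pair at distance 0 -> kernel 1
        assert K[1, 2] == pytest.approx(1.0)
        # d = sigma * sqrt(2) -> exp(-1)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))
        assert np.all(np.diag(K) == 0)

    def test_diagonal_flag(self):
        X = np.array([[0.0], [1.0]])
        K = kernel_matrix(pairwise_knn(X, 1), 1.0, zero_diagonal=False)
        assert K.toarray()[0, 0] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 5))
        K = kernel_matrix(pairwise_knn(X, 10), 0.7)
        assert abs(K - K.T).max() < 1e-15


class TestTransition:
    def test_alpha_zero_keeps_kernel(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        K = kernel_matrix(pairwise_knn(X, 29), 1.0)
        P, D = density_normalized_transition(K, alpha=0.0)
        np.testing.assert_allclose(
            P.toarray(), K.toarray() / K.toarray().sum(1, keepdims=True),
            atol=1e-15)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 4))
        K = kernel_matrix(pairwise_knn(X, 20), 0.8)
        P, _ = density_normalized_transition(K, alpha=1.0)
        np.testing.assert_allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0,
                                   atol=1e-12)

    def test_three_point_brute_force(self):
        # triangle with side lengths 1, 1, 2 on a line
        X = np.array([[0.0], [1.0], [2.0]])
        K = kernel_matrix(pairwise_knn(X, 2), sigma=1.0)
        P, _ = density_normalized_transition(K, alpha=1.0)
        from scipy.spatial import distance_matrix
        expected = brute_force_transition(distance_matrix(X, X), 1.0, 1.0)
        np.testing.assert_allclose(P.toarray(), expected, atol=1e-12)

    def test_isolated_point_detected(self):
        K = sp.csr_matrix(np.array([[0.0, 1.0, 0.0],
                                    [1.0, 0.0, 0.0],
                                    [0.0, 0.0, 0.0]]))
        with pytest.raises(IsolatedPointError, match="2"):
            density_normalized_transition(K, 1.0)


class TestSpectral:
    def _operator(self, X, sigma=1.0):
        K = kernel_matrix(pairwise_knn(X, X.shape[0] - 1), sigma)
        return density_normalized_transition(K, 1.0)

    def test_markov_chain_top_eigenvalue(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        P, D = self._operator(X)
        evals, psi = spectral_decompose(P, D, 5)
        assert np.all(evals < 1.0 + 1e-8)
        assert np.all(np.diff(evals) <= 1e-12)
        assert psi.shape == (60, 5)
        # returned components exclude the constant eigenvector
        assert all(np.std(psi[:, j]) > 1e-8 for j in range(5))

    def test_disconnected_blobs_sign_separation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 0.1, size=(30, 2))
        b = rng.normal(100.0, 0.1, size=(30, 2))
        X = np.vstack([a, b])
        K = kernel_matrix(pairwise_knn(X, 10), sigma=0.2)
        # cross-blob kernel entries underflow to 0 -> two components
        P, D = density_normalized_transition(K, 1.0)
        evals, psi = spectral_decompose(P, D, 3)
        assert evals[0] == pytest.approx(1.0, abs=1e-8)
        signs = np.sign(psi[:, 0])
        assert len(set(signs[:30])) == 1 and len(set(signs[30:])) == 1
        assert signs[0] != signs[-1]


class TestFullPipeline:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, size=(70, 6)),
                       rng.normal(3, 1, size=(60, 6))])
        sigma = 1.3
        events = make_table(np.clip(X - X.min(), 0, None))
        dmap = compute_diffusion_map(events, DiffusionParams(
            n_components=8, k_neighbors=X.shape[0] - 1, sigma=sigma))
        ref_evals, ref_psi = dense_diffusion_map(events.intensities, sigma, 8)
        np.testing.assert_allclose(dmap.eigenvalues, ref_evals, atol=1e-8)
        aligned = align_signs(ref_psi, dmap.components)
        np.testing.assert_allclose(aligned, ref_psi, atol=1e-8)

    def test_manifold_recovery(self):
        """DC1 tracks the latent coordinate of a noisy 1-D curve in 10-D."""
        rng = np.random.default_rng(8)
        n = 1000
        t = np.sort(rng.uniform(0, 1, n))
        freqs = rng.uniform(0.3, 0.8, 10)
        phases = rng.uniform(0, 2 * np.pi, 10)
        amps = rng.uniform(0.5, 1.5, 10)
        X = amps * np.cos(2 * np.pi * freqs * t[:, None] + phases)
        length = np.sum(np.linalg.norm(np.diff(X, axis=0), axis=1))
        X = X + rng.normal(0, 0.05 * length, X.shape)
        events = make_table(np.clip(X - X.min(), 0, None))
        dmap = compute_diffusion_map(events, DiffusionParams(
            n_components=5, k_neighbors=50))
        rho = spearmanr(dmap.dc(1), t).statistic
        assert abs(rho) >= 0.95

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(80, 5))
        events = make_table(np.clip(X - X.min(), 0, None))
        params = DiffusionParams(n_components=4, k_neighbors=20)
        base = compute_diffusion_map(events, params)
        perm = rng.permutation(80)
        permuted = compute_diffusion_map(events.select(perm), params)
        aligned = align_signs(base.components[perm], permuted.components)
        np.testing.assert_allclose(aligned, base.components[perm], atol=1e-10)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        X = np.abs(rng.normal(size=(60, 4)))
        events = make_table(X)
        params = DiffusionParams(n_components=3, k_neighbors=15)
        a = compute_diffusion_map(events, params)
        b = compute_diffusion_map(events, params)
        np.testing.assert_array_equal(a.components, b.components)
        np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)

    def test_too_few_cells(self):
        with pytest.raises(InsufficientDataError):
            compute_diffusion_map(make_table(np.ones((10, 3))),
                                  DiffusionParams(n_components=10))

    def test_resolved_params_recorded(self):
        rng = np.random.default_rng(11)
        events = make_table(np.abs(rng.normal(size=(50, 4))))
        dmap = compute_diffusion_map(events, DiffusionParams(
            n_components=3, k_neighbors=200))
        assert dmap.params["k_neighbors"] == 49   # capped at n-1
        assert dmap.params["sigma"] > 0
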