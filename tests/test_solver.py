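import numpy as np
import pytest
import scipy.linalg
from scipy.stats import spearmanr

from glspca import (
    GLSPCAParams,
    SolverError,
    alpha_from_beta,
    build_A1,
    fit_glspca,
    knn_affinity,
    l21_norm,
    laplacian,
    make_dataset,
    objective,
    reweight_matrix,
    smallest_eigenvectors,
)


class TestL21Norm:
    @pytest.mark.parametrize(
        "M, expected",
        [
            (np.eye(2), 2.0),
            (np.array([[3.0, 4.0], [0.0, 0.0]]), 5.0),
            (np.zeros((3, 2)), 0.0),
        ],
    )
    def test_examples(self, M, expected):
        assert l21_norm(M) == expected

    def test_matches_row_norm_sum(self, rng):
        M = rng.normal(size=(7, 3))
        assert l21_norm(M) == pytest.approx(
            sum(np.linalg.norm(M[i]) for i in range(7))
        )


class TestReweightMatrix:
    def test_three_four_five_row(self):
        dw = reweight_matrix(np.array([[3.0, 4.0]]))
        assert dw[0] == pytest.approx(0.1)

    def test_zero_row_floor(self):
        dw = reweight_matrix(np.array([[0.0, 0.0]]), eps_row=1e-8)
        assert dw[0] == pytest.approx(5e7)

    def test_unit_row(self):
        dw = reweight_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(dw, 0.5)

    def test_surrogate_identity(self, rng):
        """Tr(H' Dw H) equals half the L2,1 norm when Dw = reweight(H)."""
        for _ in range(20):
            H = rng.normal(size=(8, 3))
            dw = reweight_matrix(H, eps_row=1e-12)
            surrogate = float(np.trace(H.T @ np.diag(dw) @ H))
            assert surrogate == pytest.approx(0.5 * l21_norm(H), abs=1e-10)

    def test_lemma_descent_inequality(self, rng):
        """||a|| - ||a||^2/(2||b||) <= ||b|| - ||b||^2/(2||b||) for any a, b."""
        for _ in range(100):
            a = rng.normal(size=5)
            b = rng.normal(size=5)
            nb = np.linalg.norm(b)
            na = np.linalg.norm(a)
            assert na - na**2 / (2 * nb) <= nb - nb**2 / (2 * nb) + 1e-12


class TestObjective:
    def test_full_rank_orthogonal_reconstruction_is_zero(self, rng):
        X = rng.normal(size=(5, 4))
        H = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        U = X @ H
        assert objective(X, U, H, np.zeros((4, 4)), 0.0, 0.0) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_trace_expansion_identity(self, rng):
        """||X - XHH'||^2 = ||X||^2 - Tr(H'X'XH) for orthonormal H."""
        X = rng.normal(size=(5, 4))
        H = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        direct = objective(X, X @ H, H, np.zeros((4, 4)), 0.0, 0.0)
        expanded = np.sum(X * X) - np.trace(H.T @ X.T @ X @ H)
        assert direct == pytest.approx(expanded)

    def test_pure_penalty_term(self):
        H = np.zeros((4, 2))
        H[0, 0] = H[1, 1] = 1.0
        X = np.zeros((3, 4))
        U = np.zeros((3, 2))
        assert objective(X, U, H, np.zeros((4, 4)), 0.0, 1.0) == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(SolverError, match="shape"):
            objective(rng.normal(size=(3, 4)), rng.normal(size=(3, 2)),
                      rng.normal(size=(5, 2)), np.zeros((5, 5)), 0.0, 0.0)


class TestAlphaFromBeta:
    def test_zero(self):
        assert alpha_from_beta(0.0, 3.0, 5.0) == 0.0

    def test_half_with_equal_etas(self):
        assert alpha_from_beta(0.5, 2.0, 2.0) == pytest.approx(1.0)

    def test_pole_at_one(self):
        with pytest.raises(SolverError):
            alpha_from_beta(1.0, 1.0, 1.0)


class TestBuildA1:
    def test_pure_graph_limit(self, rng):
        X = rng.normal(size=(5, 4))
        L = np.diag([1.0, 2, 2, 1.0])
        L[0, 1] = L[1, 0] = L[1, 2] = L[2, 1] = L[2, 3] = L[3, 2] = -1.0
        A1, _, eta_s = build_A1(X, L, np.ones(4), beta=1.0, gamma=0.0)
        np.testing.assert_allclose(A1, L / eta_s)

    def test_pure_data_limit_recovers_pca(self, rng):
        """At beta=0, gamma=0 the smallest eigenvectors of A1 are the top
        eigenvectors of the Gram matrix X'X."""
        X = rng.normal(size=(6, 5))
        A1, eta_k, _ = build_A1(X, np.zeros((5, 5)), np.ones(5), 0.0, 0.0)
        np.testing.assert_allclose(A1, np.eye(5) - X.T @ X / eta_k, atol=1e-12)
        H = smallest_eigenvectors(A1, 2)
        gram_top = smallest_eigenvectors(-(X.T @ X), 2)
        np.testing.assert_allclose(np.abs(H), np.abs(gram_top), atol=1e-9)

    def test_equivalence_with_raw_form(self, rng):
        """A1 is a positive-scaled, identity-shifted image of
        A = -X'X + alpha L + gamma Dw, so both yield the same eigenvectors
        in the same order."""
        X = rng.normal(size=(5, 4))
        g = laplacian(knn_affinity(rng.normal(size=(3, 4)), k_neighbors=2))
        dw = np.full(4, 0.5)
        beta, gamma = 0.3, 0.1
        A1, eta_k, eta_s = build_A1(X, g.L, dw, beta, gamma)
        alpha = alpha_from_beta(beta, eta_k, eta_s)
        A = -(X.T @ X) + alpha * g.L + gamma * np.diag(dw)
        np.testing.assert_allclose(
            smallest_eigenvectors(A1, 3), smallest_eigenvectors(A, 3), atol=1e-8
        )

    def test_gamma_too_large_rejected(self, rng):
        X = rng.normal(size=(4, 4))
        with pytest.raises(SolverError, match="lower gamma"):
            build_A1(X, np.zeros((4, 4)), np.ones(4), 0.5, 1e9)

    def test_beta_one_with_sparsity_rejected(self, rng):
        X = rng.normal(size=(4, 4))
        with pytest.raises(SolverError, match="not a valid"):
            build_A1(X, np.eye(4), np.ones(4), 1.0, 0.5)


class TestSmallestEigenvectors:
    def test_diagonal_example(self):
        H = smallest_eigenvectors(np.diag([3.0, 1.0, 2.0]), 2)
        np.testing.assert_allclose(H[:, 0], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(H[:, 1], [0, 0, 1], atol=1e-12)

    def test_full_basis_is_orthogonal(self, rng):
        A = rng.normal(size=(5, 5))
        A = A + A.T
        H = smallest_eigenvectors(A, 5)
        np.testing.assert_allclose(H.T @ H, np.eye(5), atol=1e-12)

    def test_rayleigh_quotients_match_full_spectrum(self, rng):
        A = rng.normal(size=(6, 6))
        A = A + A.T
        H = smallest_eigenvectors(A, 3)
        rayleigh = np.sort(np.diag(H.T @ A @ H))
        full = np.sort(scipy.linalg.eigvalsh(A))[:3]
        np.testing.assert_allclose(rayleigh, full, atol=1e-9)

    def test_sign_convention(self, rng):
        A = rng.normal(size=(6, 6))
        A = A + A.T
        H = smallest_eigenvectors(A, 4)
        for col in H.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(SolverError, match="symmetric"):
            smallest_eigenvectors(np.array([[0.0, 1.0], [0.0, 0.0]]), 1)


class TestFit:
    def test_pca_limit_matches_svd(self, small_dataset, small_laplacian):
        """beta=0, gamma=0 spans the top right-singular subspace of X."""
        res = fit_glspca(small_dataset.X, small_laplacian,
                         GLSPCAParams(k_dims=2, beta=0.0, gamma=0.0))
        V = scipy.linalg.svd(small_dataset.X.values, full_matrices=False)[2][:2].T
        angles = scipy.linalg.subspace_angles(res.H, V)
        assert angles.max() < 1e-6

    def test_le_limit_matches_laplacian_eigenvectors(self, small_dataset,
                                                     small_laplacian):
        res = fit_glspca(small_dataset.X, small_laplacian,
                         GLSPCAParams(k_dims=2, beta=1.0, gamma=0.0))
        expected = smallest_eigenvectors(small_laplacian.L, 2)
        np.testing.assert_allclose(res.H, expected, atol=1e-8)

    def test_descent_orthonormality_and_factor_identity(self, small_dataset,
                                                        small_laplacian):
        X = small_dataset.X
        checked = []

        def check(it, H, U, f):
            assert np.abs(H.T @ H - np.eye(2)).max() < 1e-8
            np.testing.assert_array_equal(U, X.values @ H)
            checked.append(f)

        res = fit_glspca(X, small_laplacian,
                         GLSPCAParams(k_dims=2, beta=0.5, gamma=1.0),
                         on_iteration=check)
        assert checked == res.objective_trace
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_trace_recorded_and_converged(self, default_fit):
        assert default_fit.converged
        assert default_fit.n_iter == len(default_fit.objective_trace)
        assert np.isfinite(default_fit.objective_trace).all()

    def test_sparsity_nonincreasing_in_gamma(self, small_dataset,
                                             small_laplacian):
        """The converged ||H||_2,1 trends downward as gamma grows."""
        gammas = [0.0, 1e-2, 1e-1, 1.0, 10.0]
        norms = []
        for gamma in gammas:
            res = fit_glspca(small_dataset.X, small_laplacian,
                             GLSPCAParams(k_dims=2, beta=0.5, gamma=gamma))
            norms.append(l21_norm(res.H))
        rho = spearmanr(gammas, norms).statistic
        assert rho <= 0

    def test_graph_sample_mismatch_rejected(self, small_dataset, rng):
        other = laplacian(knn_affinity(rng.normal(size=(4, 10)), k_neighbors=2))
        with pytest.raises(SolverError, match="samples"):
            fit_glspca(small_dataset.X, other)

    def test_k_dims_bound(self, small_dataset, small_laplacian):
        with pytest.raises(SolverError, match="k_dims"):
            fit_glspca(small_dataset.X, small_laplacian,
                       GLSPCAParams(k_dims=40))


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k_dims=0),
            dict(beta=-0.1),
            dict(beta=1.5),
            dict(beta=1.0, gamma=1.0),
            dict(gamma=-1.0),
            dict(tol=0.0),
        ],
    )
    def test_rejected(self, kwargs):
        with pytest.raises(SolverError):
            GLSPCAParams(**kwargs)
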