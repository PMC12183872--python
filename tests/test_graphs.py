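import numpy as np
import pytest
import scipy.sparse as sp

from spotview.graphs import (block_diagonal, build_multiview_graph, hybridize,
                             knn_expression, knn_spatial, normalize_sym)


class TestKnnSpatial:
    def test_collinear_hand_case(self):
        coords = np.array([[0.0, 0], [1.0, 0], [3.0, 0]])
        A = knn_spatial(coords, 1).toarray()
        expected = np.array([[0, 1, 0], [1, 0, 0], [0, 1, 0]])
        np.testing.assert_array_equal(A, expected)  # asymmetric by design

    def test_row_sums_equal_K(self, rng):
        A = knn_spatial(rng.random((20, 2)), 4)
        np.testing.assert_array_equal(np.asarray(A.sum(axis=1)).ravel(), 4)
        assert A.diagonal().sum() == 0

    def test_unit_grid_interior_rook_neighbors(self):
        # brute-force check on a 5x5 grid: interior spots pick the 4
        # rook-adjacent neighbors at distance 1
        yy, xx = np.meshgrid(range(5), range(5), indexing="ij")
        coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        A = knn_spatial(coords, 4).toarray()
        for i in range(25):
            r, c = divmod(i, 5)
            if 0 < r < 4 and 0 < c < 4:
                rook = {i - 5, i + 5, i - 1, i + 1}
                assert set(np.flatnonzero(A[i])) == rook

    def test_K_bound(self):
        with pytest.raises(ValueError):
            knn_spatial(np.zeros((3, 2)) + np.arange(3)[:, None], 3)


class TestKnnExpression:
    def test_duplicated_rows_mutual_top(self, rng):
        X = rng.standard_normal((5, 4))
        X[3] = X[1]
        A = knn_expression(X, 1).toarray()
        assert A[1, 3] == 1 and A[3, 1] == 1

    def test_correlation_ordering(self):
        h = np.array([1.0, -1, 1, -1])
        orth = np.array([1.0, 1, -1, -1])
        X = np.vstack([h, -h, orth])
        A = knn_expression(X, 1).toarray()
        assert A[0, 2] == 1 and A[0, 1] == 0  # r=0 beats r=-1

    def test_constant_row_errors(self):
        X = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="0"):
            knn_expression(X, 1)


class TestHybridizeNormalize:
    def test_lambda_one_gives_identity(self):
        A = sp.csr_matrix(np.array([[0, 1.0], [1, 0]]))
        np.testing.assert_array_equal(hybridize(A, 1.0).toarray(), np.eye(2))

    def test_default_lambda_hand_case(self):
        A = np.zeros((3, 3))
        A[0, 1] = 1
        H = hybridize(sp.csr_matrix(A), 0.3).toarray()
        assert H[0, 1] == pytest.approx(0.7)
        assert H[0, 0] == pytest.approx(0.3)

    def test_lambda_zero_identity_op(self):
        A = sp.csr_matrix(np.array([[0, 1.0], [1, 0]]))
        np.testing.assert_array_equal(hybridize(A, 0.0).toarray(), A.toarray())

    def test_normalize_identity_fixed_point(self):
        np.testing.assert_array_equal(
            normalize_sym(sp.identity(3, format="csr")).toarray(), np.eye(3))

    def test_normalize_rowsum_one_fixed_point(self):
        A = sp.csr_matrix(np.array([[0.3, 0.7], [0.7, 0.3]]))
        np.testing.assert_allclose(normalize_sym(A).toarray(), A.toarray(),
                                   atol=1e-12)

    def test_spectral_radius_at_most_one(self, rng):
        for _ in range(5):
            B = rng.random((6, 6))
            A = sp.csr_matrix((B + B.T) / 2)
            At = normalize_sym(A).toarray()
            rad = np.abs(np.linalg.eigvals(At)).max()
            assert rad <= 1 + 1e-10

    def test_zero_pattern_preserved(self, rng):
        A = sp.random(8, 8, density=0.3, random_state=1, format="csr")
        H = hybridize(A, 0.3)
        N = normalize_sym(H)
        np.testing.assert_array_equal(N.toarray() != 0, H.toarray() != 0)


class TestBlockDiagonal:
    def test_single_spot_slices(self):
        out = block_diagonal([sp.csr_matrix([[1.0]]), sp.csr_matrix([[1.0]])])
        np.testing.assert_array_equal(out.toarray(), np.eye(2))

    def test_single_slice_identity_op(self, rng):
        A = sp.random(5, 5, density=0.4, random_state=0, format="csr")
        np.testing.assert_array_equal(block_diagonal([A]).toarray(), A.toarray())

    def test_blocks_recoverable_and_cross_slice_zero(self, rng):
        A1 = sp.random(4, 4, density=0.5, random_state=1, format="csr")
        A2 = sp.random(3, 3, density=0.5, random_state=2, format="csr")
        out = block_diagonal([A1, A2]).toarray()
        np.testing.assert_array_equal(out[:4, :4], A1.toarray())
        np.testing.assert_array_equal(out[4:, 4:], A2.toarray())
        assert np.all(out[:4, 4:] == 0) and np.all(out[4:, :4] == 0)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            block_diagonal([])


def test_hybridized_row_sums(rng):
    K, lam = 3, 0.3
    A = knn_spatial(rng.random((15, 2)), K)
    H = hybridize(A, lam)
    np.testing.assert_allclose(np.asarray(H.sum(axis=1)).ravel(),
                               lam + (1 - lam) * K, atol=1e-12)


def test_multiview_graph_never_mixes_slices(rng):
    coords = [rng.random((10, 2)), rng.random((8, 2))]
    X = rng.standard_normal((18, 5))
    g = build_multiview_graph(coords, X, np.array([10, 8]), 3, 3, 0.3)
    for A in (g.A_spa_norm, g.A_expr_norm):
        dense = A.toarray()
        assert np.all(dense[:10, 10:] == 0) and np.all(dense[10:, :10] == 0)
        assert np.all(np.asarray(A.sum(axis=1)).ravel() > 0)
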