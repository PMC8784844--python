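import numpy as np
import pytest

import lssd
from lssd.clusternum import (
    estimate_C,
    laplacian_eigenvectors,
    optimal_rotation,
    rotation_cost,
)

from conftest import block_affinity


def indicator(n_per_cluster, C):
    """Exact indicator matrix: one nonzero per row."""
    Z = np.zeros((n_per_cluster * C, C))
    for c in range(C):
        Z[c * n_per_cluster : (c + 1) * n_per_cluster, c] = 1.0
    return Z


class TestLaplacianEigenvectors:
    def test_disconnected_two_block_null_space(self):
        W = block_affinity(2, 15)
        vecs, lam = laplacian_eigenvectors(W, 4, return_values=True)
        assert lam[0] == pytest.approx(0.0, abs=1e-8)
        assert lam[1] == pytest.approx(0.0, abs=1e-8)
        assert lam[2] > 1e-3

    def test_columns_orthonormal(self):
        W = block_affinity(3, 10)
        vecs = laplacian_eigenvectors(W, 5)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(5), atol=1e-8)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        S = rng.random((10, 10))
        S = (S + S.T) / 2.0 + 10 * np.eye(10)
        vecs, lam = laplacian_eigenvectors(S, 10, return_values=True)
        # independent oracle: full eigendecomposition of the normalized Laplacian
        d = S.sum(axis=1)
        L = np.eye(10) - S / np.sqrt(np.outer(d, d))
        lam_ref = np.sort(np.linalg.eigvalsh((L + L.T) / 2.0))
        np.testing.assert_allclose(lam, lam_ref, atol=1e-8)
        # and the eigenvector property L v = lambda v
        for j in range(10):
            np.testing.assert_allclose(L @ vecs[:, j], lam[j] * vecs[:, j], atol=1e-7)

    def test_zero_degree_cell_named(self):
        S = np.eye(3)
        S[1] = 0.0
        S[:, 1] = 0.0
        with pytest.raises(ValueError, match="1"):
            laplacian_eigenvectors(S, 2)

    def test_sign_convention_deterministic(self):
        W = block_affinity(2, 10)
        v1 = laplacian_eigenvectors(W, 3)
        v2 = laplacian_eigenvectors(W, 3)
        np.testing.assert_array_equal(v1, v2)
        for j in range(3):
            i = np.argmax(np.abs(v1[:, j]))
            assert v1[i, j] > 0


class TestRotationCost:
    def test_indicator_is_minimum_n(self):
        Z = indicator(7, 3)
        assert rotation_cost(Z) == pytest.approx(21.0)

    def test_all_ones_is_n_times_C(self):
        assert rotation_cost(np.ones((5, 4))) == pytest.approx(20.0)

    def test_row_scaling_invariant(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(8, 3))
        scaled = Z * rng.uniform(0.1, 10.0, size=(8, 1))
        assert rotation_cost(scaled) == pytest.approx(rotation_cost(Z))

    def test_cost_at_least_n(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            Z = rng.normal(size=(12, 4))
            assert rotation_cost(Z) >= 12.0 - 1e-9

    def test_column_permutation_and_sign_invariant(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(9, 4))
        perm = rng.permutation(4)
        flipped = Z[:, perm] * np.array([1, -1, 1, -1.0])
        assert rotation_cost(flipped) == pytest.approx(rotation_cost(Z))

    def test_zero_row_rejected(self):
        Z = np.ones((3, 2))
        Z[1] = 0.0
        with pytest.raises(ValueError):
            rotation_cost(Z)


class TestOptimalRotation:
    def test_indicator_already_optimal(self):
        Z = indicator(10, 3)
        R, J, converged = optimal_rotation(Z)
        assert J == pytest.approx(30.0, abs=1e-6)
        np.testing.assert_allclose(np.abs(R), np.eye(3), atol=1e-3)

    def test_never_worse_than_unrotated(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = rng.normal(size=(30, 3))
            _, J, _ = optimal_rotation(X)
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            assert J <= rotation_cost(X / norms) + 1e-9

    def test_recovers_known_30_degree_mixing(self):
        # rotate an exact 2-column indicator by 30 degrees; the optimizer
        # must recover the unmixed cost n
        Z = indicator(12, 2)
        a = np.deg2rad(30.0)
        R_mix = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        _, J, _ = optimal_rotation(Z @ R_mix)
        assert J == pytest.approx(24.0, abs=1e-4)

    def test_rotation_is_orthogonal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 4))
        R, _, _ = optimal_rotation(X)
        np.testing.assert_allclose(R @ R.T, np.eye(4), atol=1e-10)


class TestEstimateC:
    @pytest.mark.parametrize("k", [2, 3, 6])
    def test_block_diagonal_recovery(self, k):
        curve = estimate_C(block_affinity(k, 20), 2, 12)
        assert curve.chosen_C == k

    def test_six_block_curve_minimum_at_six(self):
        curve = estimate_C(block_affinity(6, 20), 2, 12)
        assert curve.chosen_C == 6
        assert curve.J_values[curve.candidates.index(6)] == pytest.approx(120.0, rel=1e-6)

    def test_J_at_least_n(self):
        curve = estimate_C(block_affinity(3, 20), 2, 10)
        assert np.all(curve.J_values >= 60.0 - 1e-6)

    def test_three_blob_pipeline_recovery(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(c, 0.3, size=(40, 5)) for c in (0, 4, 8)])
        S = lssd.diffuse_matrix(pts)
        assert estimate_C(S, 2, 10).chosen_C == 3

    def test_permutation_invariance(self):
        # connected graph: eigenvalues are simple, so the scan is well-defined
        # and permuting cells cannot change the chosen C
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(c, 0.4, size=(30, 5)) for c in (0, 3, 6, 9)])
        S = lssd.diffuse_matrix(pts)
        perm = np.random.default_rng(9).permutation(S.shape[0])
        assert estimate_C(S, 2, 10).chosen_C == estimate_C(
            S[np.ix_(perm, perm)], 2, 10
        ).chosen_C == 4

    def test_bad_ranges_rejected(self):
        W = block_affinity(2, 10)
        with pytest.raises(ValueError):
            estimate_C(W, 5, 4)
        with pytest.raises(ValueError):
            estimate_C(W, 2, 15)  # > n/2 for n=20
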