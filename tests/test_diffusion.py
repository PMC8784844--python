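import numpy as np
import pytest

from lssd.affinity import AffinityGraph, build_affinity
from lssd.diffusion import build_transition, self_diffuse, symmetrize


def _graph(W):
    W = np.asarray(W, dtype=float)
    return AffinityGraph(W=W, sigma=np.ones(W.shape[0]), K_scale=1)


class TestBuildTransition:
    W3 = np.array([
        [1.0, 0.6, 0.2],
        [0.6, 1.0, 0.3],
        [0.2, 0.3, 1.0],
    ])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        W = build_affinity(rng.random((30, 5))).W
        P = build_transition(W, 7).P
        np.testing.assert_allclose(np.asarray(P.sum(axis=1)).ravel(), 1.0, atol=1e-10)

    def test_hand_computed_3x3(self):
        # K_nn=2 with self excluded: row 0 keeps cols {1,2}, weights 0.6, 0.2
        P = build_transition(self.W3, 2).P.toarray()
        np.testing.assert_allclose(P[0], [0.0, 0.75, 0.25])
        np.testing.assert_allclose(P[1], [2.0 / 3.0, 0.0, 1.0 / 3.0])
        np.testing.assert_allclose(P[2], [0.4, 0.6, 0.0])

    def test_zero_diagonal_and_sparsity(self):
        P = build_transition(self.W3, 1).P
        assert np.all(P.diagonal() == 0)
        assert P.nnz == 3  # one neighbor per row

    def test_full_support_limit(self):
        # K_nn = n-1 -> row-normalized W with zeroed diagonal
        W = self.W3
        P = build_transition(W, 2).P.toarray()
        ref = W.copy()
        np.fill_diagonal(ref, 0.0)
        ref /= ref.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(P, ref)

    def test_knn_bounds(self):
        with pytest.raises(ValueError):
            build_transition(self.W3, 3)


class TestSelfDiffuse:
    def test_t0_returns_W(self):
        rng = np.random.default_rng(1)
        W = build_affinity(rng.random((10, 3)))
        P = build_transition(W, 3)
        S = self_diffuse(W, P, t=0)
        np.testing.assert_array_equal(S.S, W.W)

    def test_one_step_from_identity(self):
        # S0 = I, tau = 0.5  ->  S1 = 0.5 P + 0.5 I, rows sum to 1
        P = build_transition(TestBuildTransition.W3, 2)
        S = self_diffuse(_graph(np.eye(3)), P, t=1, tau=0.5)
        np.testing.assert_allclose(S.S, 0.5 * P.P.toarray() + 0.5 * np.eye(3))
        np.testing.assert_allclose(S.S.sum(axis=1), 1.0)

    def test_row_sum_recursion(self):
        # row_sum(S_{t+1}) = tau * row_sum(S_t P) + (1 - tau) at every step
        rng = np.random.default_rng(2)
        W = build_affinity(rng.random((25, 4)))
        P = build_transition(W, 6)
        tau = 0.8
        S_prev = W.W
        for t in range(1, 6):
            S_next = self_diffuse(W, P, t=t, tau=tau).S
            expected = tau * np.asarray((S_prev @ P.P)).sum(axis=1) + (1 - tau)
            np.testing.assert_allclose(S_next.sum(axis=1), expected, atol=1e-9)
            S_prev = S_next

    def test_entries_stay_nonnegative(self):
        rng = np.random.default_rng(3)
        W = build_affinity(rng.random((20, 4)))
        P = build_transition(W, 5)
        for t in (1, 4, 10):
            assert self_diffuse(W, P, t=t).S.min() >= 0

    def test_tau_bounds(self):
        W = _graph(np.eye(3))
        P = build_transition(TestBuildTransition.W3, 2)
        for tau in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                self_diffuse(W, P, t=1, tau=tau)

    def test_provenance_recorded(self):
        rng = np.random.default_rng(4)
        W = build_affinity(rng.random((10, 3)))
        P = build_transition(W, 4)
        S = self_diffuse(W, P, t=3, tau=0.7)
        assert (S.t, S.tau, S.K_nn) == (3, 0.7, 4)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.random((18, 4))
        perm = rng.permutation(18)
        W = build_affinity(X)
        S = self_diffuse(W, build_transition(W, 5), t=4).S
        Wp = build_affinity(X[perm])
        Sp = self_diffuse(Wp, build_transition(Wp, 5), t=4).S
        np.testing.assert_allclose(Sp, S[np.ix_(perm, perm)], atol=1e-10)

    def test_denoising_two_blocks(self, two_blobs):
        # after t=4, the within/between mean-similarity ratio must not decrease;
        # the transition support must be local relative to the block size
        # (10 neighbors for 20-cell blocks) for truncation to suppress noise
        X, labels = two_blobs
        W = build_affinity(X)
        P = build_transition(W, 10)
        S = symmetrize(self_diffuse(W, P, t=4))
        a, b = labels == 0, labels == 1

        def ratio(M):
            return M[np.ix_(a, a)].mean() / max(M[np.ix_(a, b)].mean(), 1e-300)

        assert ratio(S) >= ratio(W.W)


class TestSymmetrize:
    def test_symmetric_unchanged(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        np.testing.assert_array_equal(symmetrize(M), M)

    def test_output_symmetric_and_entrywise_mean(self):
        M = np.array([[1.0, 0.2], [0.8, 1.0]])
        out = symmetrize(M)
        np.testing.assert_array_equal(out, out.T)
        assert out[0, 1] == pytest.approx(0.5)
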