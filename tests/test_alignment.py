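"""Eigenvector embedding and alignment-angle properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegalign as ea
from eegalign.alignment import Embedding

from conftest import brute_force_alignment


def _random_connectivity(n, seed):
    rng = np.random.default_rng(seed)
    W = rng.uniform(0, 1, (n, n))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0)
    return W


class TestEmbed:
    def test_two_block_cliques_second_eigenvector_separates(self):
        """Disconnected cliques: eigenvectors localise per block, angles split them."""
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 0.8
        np.fill_diagonal(W, 0)
        emb = ea.embed(W, eig_indices=(1, 2))
        # v1 is the heavy clique's Perron vector, v2 the light clique's
        v2 = emb.coords[:, 1]
        assert np.all(np.abs(v2[:4]) < 1e-9)
        assert np.all(v2[4:] > 0.1)
        theta = ea.alignment_angles(emb).theta
        assert np.all(theta[:4, :4] < 1e-6)
        assert np.all(theta[np.ix_(range(4), range(4, 8))] > 89.0)

    def test_scale_invariance(self):
        W = _random_connectivity(12, 3)
        a = ea.eigenvector_alignment(W).theta
        b = ea.eigenvector_alignment(2.0 * W).theta
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_requested_rank_exceeding_dimension(self):
        with pytest.raises(ValueError, match="exceeds"):
            ea.embed(_random_connectivity(3, 0), eig_indices=(2, 3, 4))

    def test_non_symmetric_rejected(self):
        W = _random_connectivity(5, 1)
        W[0, 1] += 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ea.embed(W)

    def test_degenerate_complete_graph_deterministic(self):
        """Complete graph has an (n-1)-fold degenerate eigenvalue; ties break stably."""
        W = np.ones((6, 6)) - np.eye(6)
        a = ea.eigenvector_alignment(W).theta
        b = ea.eigenvector_alignment(W.copy()).theta
        np.testing.assert_array_equal(a, b)


class TestAlignmentAngles:
    def test_hand_computed_angles(self):
        emb = Embedding(
            np.array([[1.0, 0, 0], [0, 1.0, 0], [1, 1, 0], [-1, -1, 0]]),
            (2, 3, 4),
            np.ones(3),
            ["a", "b", "c", "d"],
        )
        th = ea.alignment_angles(emb).theta
        assert th[0, 0] == 0.0
        assert th[0, 1] == pytest.approx(90.0)
        assert th[2, 3] == pytest.approx(180.0)

    def test_zero_norm_row_flagged_not_zeroed(self):
        emb = Embedding(
            np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]]), (2, 3, 4), np.ones(3), list("abc")
        )
        th = ea.alignment_angles(emb).theta
        assert np.isnan(th[1, 0]) and np.isnan(th[1, 1]) and np.isnan(th[1, 2])
        assert th[0, 2] == pytest.approx(90.0)

    def test_all_zero_embedding_errors(self):
        emb = Embedding(np.zeros((3, 3)), (2, 3, 4), np.zeros(3), list("abc"))
        with pytest.raises(ValueError, match="zero norm"):
            ea.alignment_angles(emb)

    def test_sign_flip_invariance(self):
        W = _random_connectivity(10, 7)
        emb = ea.embed(W)
        base = ea.alignment_angles(emb).theta
        for col in range(emb.coords.shape[1]):
            flipped = Embedding(
                emb.coords * np.where(np.arange(3) == col, -1.0, 1.0),
                emb.eig_indices,
                emb.eigenvalues,
                emb.channel_labels,
            )
            np.testing.assert_allclose(ea.alignment_angles(flipped).theta, base, atol=1e-9)


class TestEigenvectorAlignment:
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_oracle_equivalence_small_matrices(self, n):
        """Matches a brute-force full-eigendecomposition arccos loop to 1e-9 degrees."""
        for seed in range(3):
            W = _random_connectivity(n, 100 * n + seed)
            ranks = (2, 3, 4) if n >= 4 else (2, 3)
            got = ea.eigenvector_alignment(W, ranks).theta
            ref = brute_force_alignment(W, ranks)
            np.testing.assert_allclose(got, ref, atol=1e-9)

    def test_planted_communities_within_below_between_noise_free(self):
        """Noise-free 3-block matrix, community-contrast eigenvectors (2, 3):
        every within-community angle is below every between-community angle."""
        labels = np.asarray([i // 10 for i in range(30)])
        W = ea.planted_connectivity(30, labels, 0.8, 0.1, 0.0, seed=0)
        th = ea.eigenvector_alignment(W, eig_indices=(2, 3)).theta
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(30, dtype=bool)
        assert th[same & off].max() < th[~same].min()

    def test_planted_communities_separate_distributionally(self, planted_3comm):
        """With weight noise and the default 3-D embedding the separation is
        distributional: within-community angles are much smaller on average."""
        W, labels = planted_3comm
        th = ea.eigenvector_alignment(W).theta
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(30, dtype=bool)
        assert th[same & off].mean() < 0.5 * th[~same].mean()

    def test_permutation_equivariance(self):
        W = _random_connectivity(9, 5)
        perm = np.random.default_rng(0).permutation(9)
        a = ea.eigenvector_alignment(W).theta[np.ix_(perm, perm)]
        b = ea.eigenvector_alignment(W[np.ix_(perm, perm)]).theta
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_weak_direct_weight_can_still_align(self):
        """Close alignment needs similar connectivity patterns, not a strong
        direct edge: nearly erasing one within-community edge leaves its pair
        closely aligned."""
        labels = np.asarray([i // 10 for i in range(30)])
        W = ea.planted_connectivity(30, labels, 0.8, 0.1, 0.0, seed=0)
        A = W.W.copy()
        A[0, 1] = A[1, 0] = 0.01
        th = ea.eigenvector_alignment(A, eig_indices=(2, 3)).theta
        same = labels[:, None] == labels[None, :]
        assert th[0, 1] < 1.0
        assert th[0, 1] < th[~same].min()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_spherical_metric_on_random_triples(self, seed):
        """theta is symmetric, zero on the diagonal, and satisfies the triangle inequality."""
        rng = np.random.default_rng(seed)
        th = ea.eigenvector_alignment(_random_connectivity(8, seed)).theta
        np.testing.assert_allclose(th, th.T, atol=1e-9)
        assert np.all(np.diag(th) == 0)
        i, j, k = rng.choice(8, size=3, replace=False)
        assert th[i, k] <= th[i, j] + th[j, k] + 1e-9
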