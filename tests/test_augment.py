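import itertools

import numpy as np
import pytest

from spascl import augment as aug
from conftest import knn_oracle


def sym_binary(n, density, seed):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < density).astype(float)
    A = np.triu(A, 1)
    return A + A.T


class TestTileAndEmbed:
    def test_constant_image_identical_rows(self):
        img = np.full((60, 60, 3), 17.0)
        coords = np.array([[10, 10], [30, 30], [50, 20]])
        feats = aug.tile_and_embed(img, coords, patch_size=10, resize_to=10,
                                   extractor_id="pixel_mean")
        for row in feats.X_I:
            np.testing.assert_allclose(row, feats.X_I[0])

    def test_identical_coords_identical_rows(self):
        rng = np.random.default_rng(0)
        img = rng.random((80, 80, 3)) * 255
        coords = np.array([[40, 40], [40, 40]])
        feats = aug.tile_and_embed(img, coords, patch_size=20, resize_to=32,
                                   extractor_id="random_projection")
        np.testing.assert_array_equal(feats.X_I[0], feats.X_I[1])

    def test_two_color_halves_mean_extractor(self):
        img = np.zeros((100, 200, 3))
        img[:, :100] = [240.0, 8.0, 8.0]
        img[:, 100:] = [8.0, 8.0, 240.0]
        coords = np.array([[50, 50], [150, 50]])
        feats = aug.tile_and_embed(img, coords, patch_size=50, resize_to=50,
                                   extractor_id="pixel_mean")
        np.testing.assert_allclose(feats.X_I[0], [240.0, 8.0, 8.0])
        np.testing.assert_allclose(feats.X_I[1], [8.0, 8.0, 240.0])

    def test_out_of_bounds_without_padding_raises(self):
        img = np.zeros((50, 50))
        with pytest.raises(ValueError):
            aug.tile_and_embed(img, np.array([[2, 2]]), patch_size=20,
                               resize_to=20, pad=False)

    def test_edge_patch_zero_padded(self):
        img = np.full((50, 50), 100.0)
        feats = aug.tile_and_embed(img, np.array([[0, 0]]), patch_size=20,
                                   resize_to=20, extractor_id="pixel_mean")
        # three quarters of the corner patch lie outside the image
        assert feats.X_I[0, 0] == pytest.approx(25.0)


class TestMorphologyKnn:
    def test_one_hot_domains_separate(self):
        X_I = np.repeat(np.eye(3), 4, axis=0) * 5.0
        A = aug.morphology_knn(aug.MorphologyFeatures(X_I, "t"), 1)
        domains = np.repeat(np.arange(3), 4)
        r, c = np.nonzero(A)
        assert np.all(domains[r] == domains[c])

    def test_matches_exhaustive_oracle(self):
        X_I = np.random.default_rng(5).random((15, 4))
        A = aug.morphology_knn(aug.MorphologyFeatures(X_I, "t"), 3)
        np.testing.assert_array_equal(A, knn_oracle(X_I, 3))


class TestSampleMaskL:
    def test_rate_zero_all_zeros(self):
        A, AI = sym_binary(8, 0.4, 0), sym_binary(8, 0.4, 1)
        L = aug.sample_mask_L(8, A, AI, 0.0, seed=0)
        np.testing.assert_array_equal(L.L, np.zeros((8, 8)))

    def test_rate_one_covers_disagreements(self):
        A, AI = sym_binary(8, 0.4, 0), sym_binary(8, 0.4, 1)
        L = aug.sample_mask_L(8, A, AI, 1.0, seed=0)
        np.testing.assert_array_equal(L.L, (A != AI).astype(float))

    def test_agreeing_graphs_give_empty_mask(self):
        A = sym_binary(8, 0.4, 0)
        L = aug.sample_mask_L(8, A, A, 1.0, seed=0)
        np.testing.assert_array_equal(L.L, np.zeros((8, 8)))

    def test_symmetric_and_reproducible(self):
        A, AI = sym_binary(10, 0.3, 2), sym_binary(10, 0.3, 3)
        L1 = aug.sample_mask_L(10, A, AI, 0.5, seed=7)
        L2 = aug.sample_mask_L(10, A, AI, 0.5, seed=7)
        np.testing.assert_array_equal(L1.L, L2.L)
        np.testing.assert_array_equal(L1.L, L1.L.T)
        assert np.all(np.diag(L1.L) == 0)

    def test_bad_rate_raises(self):
        A = sym_binary(5, 0.4, 0)
        with pytest.raises(ValueError):
            aug.sample_mask_L(5, A, A, 1.5, seed=0)


def all_three_node_graphs():
    """All symmetric binary zero-diagonal 3-node matrices (8 each)."""
    graphs = []
    for bits in itertools.product([0.0, 1.0], repeat=3):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = bits[0]
        A[0, 2] = A[2, 0] = bits[1]
        A[1, 2] = A[2, 1] = bits[2]
        graphs.append(A)
    return graphs


class TestEdgePerturbPrior:
    def test_l_zero_is_identity(self):
        A, AI = sym_binary(8, 0.4, 0), sym_binary(8, 0.4, 1)
        np.testing.assert_array_equal(
            aug.edge_perturb_prior(A, AI, np.zeros((8, 8))), A)

    def test_l_ones_gives_prior_graph(self):
        A, AI = sym_binary(8, 0.4, 0), sym_binary(8, 0.4, 1)
        L = 1.0 - np.eye(8)
        np.testing.assert_array_equal(aug.edge_perturb_prior(A, AI, L), AI)

    def test_hand_example_edge_dropped(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        AI = np.zeros((2, 2))
        L = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(aug.edge_perturb_prior(A, AI, L),
                                      np.zeros((2, 2)))

    def test_exhaustive_three_node_algebra(self):
        """Perturbation only touches entries where A and A_I disagree;
        output stays binary and symmetric for every 3-node configuration."""
        for A in all_three_node_graphs():
            for AI in all_three_node_graphs():
                for L in all_three_node_graphs():
                    out = aug.edge_perturb_prior(A, AI, L)
                    assert np.isin(out, (0.0, 1.0)).all()
                    np.testing.assert_array_equal(out, out.T)
                    agree = A == AI
                    np.testing.assert_array_equal(out[agree], A[agree])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            aug.edge_perturb_prior(sym_binary(4, 0.5, 0),
                                   sym_binary(5, 0.5, 0), np.zeros((4, 4)))


class TestRandomEdgePerturb:
    def test_rate_zero_identity(self):
        A = sym_binary(10, 0.3, 0)
        np.testing.assert_array_equal(aug.random_edge_perturb(A, 0.0, 1), A)

    def test_rate_one_complete_graph_empties(self):
        A = 1.0 - np.eye(6)
        out = aug.random_edge_perturb(A, 1.0, 1)
        np.testing.assert_array_equal(out, np.zeros((6, 6)))

    def test_deterministic_under_seed(self):
        A = sym_binary(12, 0.3, 4)
        np.testing.assert_array_equal(aug.random_edge_perturb(A, 0.4, 9),
                                      aug.random_edge_perturb(A, 0.4, 9))

    def test_edge_count_preserved_when_room(self):
        A = sym_binary(20, 0.2, 5)
        out = aug.random_edge_perturb(A, 0.5, 3)
        assert out.sum() == A.sum()
        np.testing.assert_array_equal(out, out.T)


class TestAttributeMask:
    def test_rate_zero_identity(self):
        X = np.random.default_rng(0).random((5, 7))
        np.testing.assert_array_equal(aug.attribute_mask(X, 0.0, 1), X)

    def test_rate_one_zero_matrix(self):
        X = np.random.default_rng(0).random((5, 7))
        np.testing.assert_array_equal(aug.attribute_mask(X, 1.0, 1),
                                      np.zeros((5, 7)))

    def test_half_rate_masks_exact_count(self):
        X = np.ones((4, 6))
        out = aug.attribute_mask(X, 0.5, seed=3)
        zero_rows = np.all(out == 0, axis=1)
        assert zero_rows.sum() == 2
        np.testing.assert_array_equal(out[~zero_rows], X[~zero_rows])


class TestShuffleNegative:
    def test_single_spot_unchanged(self):
        X = np.array([[1.0], [2.0]])
        np.testing.assert_array_equal(aug.shuffle_negative(X, 0), X)

    def test_column_multiset_preserved(self):
        X = np.random.default_rng(1).random((4, 9))
        out = aug.shuffle_negative(X, 5)
        np.testing.assert_allclose(np.sort(out.sum(axis=0)),
                                   np.sort(X.sum(axis=0)))
        # exact column multiset, not just sums
        orig = {tuple(c) for c in X.T}
        assert {tuple(c) for c in out.T} == orig

    def test_seed_reproducible(self):
        X = np.random.default_rng(1).random((4, 9))
        np.testing.assert_array_equal(aug.shuffle_negative(X, 8),
                                      aug.shuffle_negative(X, 8))


class TestBuildViews:
    def test_hs_image_requires_morphology(self):
        A = sym_binary(6, 0.5, 0)
        X = np.random.default_rng(0).random((4, 6))
        with pytest.raises(ValueError):
            aug.build_views(X, A, None, 0.2, 0.2, 0, edge_aug="HS_image")

    def test_views_have_expected_shapes(self):
        A = sym_binary(6, 0.5, 0)
        AI = sym_binary(6, 0.5, 1)
        X = np.random.default_rng(0).random((4, 6))
        vb = aug.build_views(X, A, AI, 0.25, 0.3, 0, edge_aug="HS_image")
        assert vb.X1_pos.shape == X.shape
        assert vb.X_neg.shape == X.shape
        np.testing.assert_array_equal(vb.A1_pos, A)
        np.testing.assert_array_equal(vb.A2_pos, vb.A2_pos.T)

    def test_weighted_blend_binarised_for_perturbation(self):
        A = 0.3 * sym_binary(6, 0.5, 0)
        AI = sym_binary(6, 0.5, 1)
        vb = aug.build_views(np.ones((3, 6)), A, AI, 0.0, 0.0, 0)
        np.testing.assert_array_equal(vb.A2_pos, (A > 0).astype(float))
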