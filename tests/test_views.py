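import numpy as np
import pytest
import scipy.sparse as sp

from hmivae.io_ingest import PixelStack, SegmentationMask
from hmivae.views import (
    MORPHOLOGY_FEATURE_NAMES,
    N_MORPHOLOGY_FEATURES,
    background_covariates,
    centroids,
    extract_views,
    mean_expression,
    morphology,
    nuclear_localization,
    one_hot,
    spatial_context,
    spatial_neighbours,
)

from .conftest import make_channel_map, make_random_sample


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_mean_expression(stack, mask, chmap):
    ids = np.unique(mask.labels)
    ids = ids[ids > 0]
    out = np.zeros((ids.size, chmap.protein_indices.size))
    for i, cid in enumerate(ids):
        ys, xs = np.where(mask.labels == cid)
        for j, ch in enumerate(chmap.protein_indices):
            vals = [stack.pixels[y, x, ch] for y, x in zip(ys, xs)]
            out[i, j] = sum(vals) / len(vals)
    return out


def oracle_nuclear_localization(stack, mask, chmap):
    ids = np.unique(mask.labels)
    ids = ids[ids > 0]
    d1, d2 = chmap.dna_indices
    out = np.zeros((ids.size, chmap.protein_indices.size))
    for i, cid in enumerate(ids):
        ys, xs = np.where(mask.labels == cid)
        nuc = np.array([(stack.pixels[y, x, d1] + stack.pixels[y, x, d2]) / 2 for y, x in zip(ys, xs)])
        for j, ch in enumerate(chmap.protein_indices):
            prot = np.array([stack.pixels[y, x, ch] for y, x in zip(ys, xs)])
            if len(prot) < 3 or np.std(prot) == 0 or np.std(nuc) == 0:
                out[i, j] = 0.0
            else:
                out[i, j] = np.corrcoef(nuc, prot)[0, 1]
    return out


def oracle_spatial_context(Y, S, M, D):
    feats = np.hstack([Y, S, M]).astype(float)
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    scaled = np.zeros_like(feats)
    for j in range(feats.shape[1]):
        if sd[j] > 0:
            scaled[:, j] = (feats[:, j] - mu[j]) / sd[j]
    Dd = np.asarray(D.todense())
    out = np.zeros_like(scaled)
    for i in range(feats.shape[0]):
        nb = np.flatnonzero(Dd[i])
        if nb.size:
            out[i] = scaled[nb].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# mean expression
# ---------------------------------------------------------------------------


class TestMeanExpression:
    def test_two_pixel_cell(self):
        mask = np.zeros((4, 4), int)
        mask[1, 1] = mask[1, 2] = 1
        pixels = np.zeros((4, 4, 4))
        pixels[1, 1, 0], pixels[1, 2, 0] = 2.0, 4.0
        chmap = make_channel_map(n_proteins=2, n_background=0)
        Y = mean_expression(
            PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap
        )
        assert Y[0, 0] == pytest.approx(3.0)

    def test_uniform_image_gives_constant(self):
        mask = np.zeros((8, 8), int)
        mask[0:2, 0:2] = 1
        mask[4:7, 4:7] = 2
        pixels = np.full((8, 8, 5), 7.5)
        chmap = make_channel_map(n_proteins=3, n_background=0)
        Y = mean_expression(PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap)
        np.testing.assert_allclose(Y, 7.5)

    def test_matches_brute_force_oracle(self):
        stack, mask, chmap = make_random_sample(seed=11, n_cells=8)
        Y = mean_expression(stack, mask, chmap)
        np.testing.assert_allclose(Y, oracle_mean_expression(stack, mask, chmap), atol=1e-12)

    def test_all_background_mask_errors(self):
        stack, _, chmap = make_random_sample(seed=0)
        empty = SegmentationMask(np.zeros((20, 20), int), "s")
        with pytest.raises(ValueError, match="no cells"):
            mean_expression(stack, empty, chmap)


class TestNuclearLocalization:
    def test_identical_to_nuclear_stain_gives_one(self):
        rng = np.random.default_rng(2)
        mask = np.zeros((6, 6), int)
        mask[1:4, 1:4] = 1
        pixels = np.zeros((6, 6, 4))
        sig = rng.uniform(1, 10, size=(6, 6))
        pixels[:, :, 0] = sig  # protein
        pixels[:, :, 2] = sig  # DNA1
        pixels[:, :, 3] = sig  # DNA2 -> mean nuclear stain == protein
        chmap = make_channel_map(n_proteins=2, n_background=0)
        S = nuclear_localization(PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap)
        assert S[0, 0] == pytest.approx(1.0)

    def test_negated_about_mean_gives_minus_one(self):
        rng = np.random.default_rng(3)
        mask = np.zeros((6, 6), int)
        mask[1:4, 1:4] = 1
        sig = rng.uniform(1, 10, size=(6, 6))
        pixels = np.zeros((6, 6, 4))
        pixels[:, :, 0] = 2 * sig.mean() - sig
        pixels[:, :, 2] = sig
        pixels[:, :, 3] = sig
        chmap = make_channel_map(n_proteins=2, n_background=0)
        S = nuclear_localization(PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap)
        assert S[0, 0] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self):
        stack, mask, chmap = make_random_sample(seed=17, n_cells=10)
        S = nuclear_localization(stack, mask, chmap)
        np.testing.assert_allclose(S, oracle_nuclear_localization(stack, mask, chmap), atol=1e-10)

    def test_bounded_and_dna_swap_invariant(self):
        stack, mask, chmap = make_random_sample(seed=23, n_cells=10)
        S = nuclear_localization(stack, mask, chmap)
        assert np.all(S >= -1) and np.all(S <= 1)
        # swap the two DNA channels
        swapped = stack.pixels.copy()
        d1, d2 = chmap.dna_indices
        swapped[:, :, [d1, d2]] = swapped[:, :, [d2, d1]]
        S2 = nuclear_localization(PixelStack(swapped, "s"), mask, chmap)
        np.testing.assert_allclose(S, S2, atol=1e-12)

    def test_degenerate_constant_protein_is_zero(self):
        mask = np.zeros((6, 6), int)
        mask[1:4, 1:4] = 1
        pixels = np.random.default_rng(0).uniform(1, 5, size=(6, 6, 4))
        pixels[:, :, 0] = 3.0  # constant protein
        chmap = make_channel_map(n_proteins=2, n_background=0)
        S = nuclear_localization(PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap)
        assert S[0, 0] == 0.0


class TestMorphology:
    def test_filled_square_area(self):
        mask = np.zeros((8, 8), int)
        mask[2:6, 2:6] = 1
        M = morphology(SegmentationMask(mask, "s"))
        assert M.shape == (1, N_MORPHOLOGY_FEATURES)
        assert M[0, MORPHOLOGY_FEATURE_NAMES.index("area")] == 16

    def test_convex_cell_has_zero_concavity(self):
        mask = np.zeros((10, 10), int)
        mask[2:5, 1:9] = 1  # filled rectangle
        M = morphology(SegmentationMask(mask, "s"))
        assert M[0, MORPHOLOGY_FEATURE_NAMES.index("concavity")] == pytest.approx(0.0)

    def test_concave_cell_has_positive_concavity(self):
        mask = np.zeros((10, 10), int)
        mask[2:8, 2:8] = 1
        mask[2:6, 4:6] = 0  # notch
        M = morphology(SegmentationMask(mask, "s"))
        assert M[0, MORPHOLOGY_FEATURE_NAMES.index("concavity")] > 0.05

    def test_exactly_five_features(self, small_dataset):
        _, mask, _ = small_dataset.samples[0]
        M = morphology(mask)
        assert M.shape[1] == 5

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        blob = (rng.uniform(size=(5, 5)) > 0.4).astype(int)
        blob[2, 2] = 1
        base = np.zeros((20, 20), int)
        base[2:7, 2:7] = blob
        shifted = np.zeros((20, 20), int)
        shifted[10:15, 11:16] = blob
        M1 = morphology(SegmentationMask(base, "s"))
        M2 = morphology(SegmentationMask(shifted, "s"))
        np.testing.assert_allclose(M1, M2, atol=1e-12)


class TestSpatialNeighbours:
    def test_three_collinear_cells_k1(self):
        cents = np.array([[0.0, 0.0], [0.0, 3.0], [0.0, 10.0]])
        D = spatial_neighbours(cents, np.array(["a"] * 3), k=1)
        assert D[1, 0] == 1 and D[1, 2] == 0  # middle picks the nearer endpoint

    def test_row_sums_equal_k(self):
        rng = np.random.default_rng(6)
        cents = rng.uniform(0, 100, size=(30, 2))
        sids = np.array(["a"] * 15 + ["b"] * 15)
        D = spatial_neighbours(cents, sids, k=10)
        np.testing.assert_array_equal(np.asarray(D.sum(axis=1)).ravel(), 10)

    def test_no_self_loops_and_no_cross_sample(self):
        rng = np.random.default_rng(7)
        cents = rng.uniform(0, 50, size=(20, 2))
        sids = np.array(["a"] * 10 + ["b"] * 10)
        D = spatial_neighbours(cents, sids, k=3).todense()
        assert np.all(np.diag(D) == 0)
        assert np.all(D[:10, 10:] == 0) and np.all(D[10:, :10] == 0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        cents = rng.uniform(0, 40, size=(12, 2))
        sids = np.array(["a"] * 12)
        k = 4
        D = np.asarray(spatial_neighbours(cents, sids, k=k).todense())
        for i in range(12):
            d = np.array([np.hypot(*(cents[i] - cents[j])) for j in range(12)])
            d[i] = np.inf
            expected = set(np.argsort(d, kind="stable")[:k])
            assert set(np.flatnonzero(D[i])) == expected

    def test_single_cell_sample_zero_row(self):
        cents = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        sids = np.array(["a", "a", "b"])
        D = spatial_neighbours(cents, sids, k=2)
        assert D[2].sum() == 0

    def test_k_shortfall_uses_all_available(self):
        cents = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        D = spatial_neighbours(cents, np.array(["a"] * 3), k=10)
        np.testing.assert_array_equal(np.asarray(D.sum(axis=1)).ravel(), 2)


class TestSpatialContext:
    def _fixture(self, seed=9, n=15):
        rng = np.random.default_rng(seed)
        Y = rng.gamma(2, 2, size=(n, 3))
        S = rng.uniform(-1, 1, size=(n, 3))
        M = rng.gamma(3, 1, size=(n, 5))
        cents = rng.uniform(0, 30, size=(n, 2))
        D = spatial_neighbours(cents, np.array(["a"] * n), k=4)
        return Y, S, M, D

    def test_single_neighbour_copies_scaled_row(self):
        Y, S, M, _ = self._fixture()
        n = Y.shape[0]
        D = sp.csr_matrix(([1.0], ([0], [3])), shape=(n, n))
        C = spatial_context(Y, S, M, D)
        feats = np.hstack([Y, S, M])
        z = (feats - feats.mean(0)) / feats.std(0)
        np.testing.assert_allclose(C[0], z[3], atol=1e-12)

    def test_identical_features_give_zero_context(self):
        n = 10
        Y = np.full((n, 3), 4.0)
        S = np.full((n, 3), 0.5)
        M = np.full((n, 5), 2.0)
        D = sp.csr_matrix(np.ones((n, n)) - np.eye(n))
        np.testing.assert_allclose(spatial_context(Y, S, M, D), 0.0)

    def test_matches_loop_oracle(self):
        Y, S, M, D = self._fixture(seed=10)
        np.testing.assert_allclose(
            spatial_context(Y, S, M, D), oracle_spatial_context(Y, S, M, D), atol=1e-12
        )

    def test_constant_shift_invariance(self):
        Y, S, M, D = self._fixture(seed=12)
        C1 = spatial_context(Y, S, M, D)
        Y2 = Y.copy()
        Y2[:, 1] += 123.0  # location shift of one protein channel
        C2 = spatial_context(Y2, S, M, D)
        np.testing.assert_allclose(C1, C2, atol=1e-10)

    def test_width_is_2p_plus_5(self):
        Y, S, M, D = self._fixture()
        assert spatial_context(Y, S, M, D).shape[1] == 2 * Y.shape[1] + 5


class TestBackgroundCovariates:
    def test_uniform_image_mean_intensity(self):
        mask = np.zeros((6, 6), int)
        mask[1:3, 1:3] = 1
        mask[4:6, 4:6] = 2
        pixels = np.full((6, 6, 5), 3.25)
        chmap = make_channel_map(n_proteins=3, n_background=0)
        vals, names = background_covariates(
            PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap
        )
        assert vals[names.index("mean_sample_intensity")] == pytest.approx(3.25)

    def test_no_background_channels_zero_background_pixels(self):
        mask = np.zeros((6, 6), int)
        mask[1:3, 1:3] = 1
        pixels = np.zeros((6, 6, 5))
        pixels[1:3, 1:3, :] = 5.0  # signal only inside the cell
        chmap = make_channel_map(n_proteins=3, n_background=0)
        vals, names = background_covariates(
            PixelStack(pixels, "s"), SegmentationMask(mask, "s"), chmap
        )
        bg_means = [v for v, n in zip(vals, names) if n.startswith("bg_mean_")]
        np.testing.assert_allclose(bg_means, 0.0)

    def test_background_channel_mode_matches_loop_oracle(self):
        stack, mask, chmap = make_random_sample(seed=31, n_cells=8)
        vals, names = background_covariates(stack, mask, chmap)
        assert vals[names.index("mean_sample_intensity")] == pytest.approx(
            stack.pixels.mean()
        )
        bg = chmap.background_indices
        assert vals[names.index("mean_background_intensity")] == pytest.approx(
            stack.pixels[:, :, bg].mean()
        )
        # correlation oracle
        ids = mask.cell_ids()
        bg_img = stack.pixels[:, :, bg].mean(axis=2)
        bg_cell = np.array([bg_img[mask.labels == c].mean() for c in ids])
        Y = oracle_mean_expression(stack, mask, chmap)
        for j, p in enumerate(chmap.protein_names):
            expected = np.corrcoef(bg_cell, Y[:, j])[0, 1]
            assert vals[names.index(f"bg_corr_{p}")] == pytest.approx(expected, abs=1e-10)

    def test_fewer_than_three_cells_zero_correlations(self):
        stack, _, chmap = make_random_sample(seed=33, n_cells=5)
        mask = np.zeros((20, 20), int)
        mask[1:3, 1:3] = 1
        mask[6:8, 6:8] = 2
        vals, names = background_covariates(stack, SegmentationMask(mask, "s"), chmap)
        corr = [v for v, n in zip(vals, names) if n.startswith("bg_corr_")]
        np.testing.assert_allclose(corr, 0.0)


class TestOneHot:
    def test_single_sample_column_of_ones(self):
        out, order = one_hot(np.array(["x"] * 4))
        np.testing.assert_array_equal(out, np.ones((4, 1)))
        assert order == ["x"]

    def test_three_samples_two_cells_each(self):
        sids = np.array(["b", "b", "a", "a", "c", "c"])
        out, order = one_hot(sids)
        assert out.shape == (6, 3)
        assert order == ["a", "b", "c"]
        np.testing.assert_array_equal(out.sum(axis=0), [2, 2, 2])
        np.testing.assert_array_equal(out.sum(axis=1), 1)

    def test_permutation_permutes_rows(self):
        rng = np.random.default_rng(14)
        sids = np.array(["a", "b", "c", "a", "b", "c", "a"])
        out, _ = one_hot(sids)
        perm = rng.permutation(sids.size)
        out_p, _ = one_hot(sids[perm])
        np.testing.assert_array_equal(out_p, out[perm])


class TestExtractViews:
    def test_shapes_and_finiteness(self, small_views, small_dataset):
        cv = small_views
        p = cv.n_proteins
        assert cv.C.shape[1] == 2 * p + 5
        assert cv.M.shape[1] == 5
        assert np.all(np.isfinite(cv.Y)) and np.all(np.isfinite(cv.C))
        n_expected = sum(m.cell_ids().size for _, m, _ in small_dataset.samples)
        assert cv.n_cells == n_expected

    def test_one_hot_block_rows_sum_to_one(self, small_views):
        r = len(small_views.sample_dims)
        onehot = small_views.b[:, -r:]
        np.testing.assert_allclose(onehot.sum(axis=1), 1.0)

    def test_centroids_match_mask_means(self, small_dataset):
        stack, mask, _ = small_dataset.samples[0]
        cents = centroids(mask)
        for i, cid in enumerate(mask.cell_ids()):
            ys, xs = np.where(mask.labels == cid)
            np.testing.assert_allclose(cents[i], [ys.mean(), xs.mean()], atol=1e-12)
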