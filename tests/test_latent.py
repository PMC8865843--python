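"""Latent PCs space, embeddings, centroids, distance matrices, t-SNE."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from hapticode import latent as la


class TestLatentPCA:
    def test_rank_deficient_codes_need_exactly_their_rank(self):
        rng = np.random.default_rng(0)
        codes = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 8))
        pcs = la.fit_latent_pca(codes, variance_threshold=0.95)
        assert pcs.k_ == 3

    def test_isotropic_codes_need_all_dimensions(self):
        codes = np.random.default_rng(1).standard_normal((4000, 16))
        pcs = la.fit_latent_pca(codes, variance_threshold=0.95)
        assert pcs.k_ == 16

    def test_threshold_definition_holds(self):
        rng = np.random.default_rng(2)
        codes = rng.standard_normal((300, 10)) * np.linspace(3, 0.2, 10)
        pcs = la.fit_latent_pca(codes, variance_threshold=0.9)
        cum = np.cumsum(pcs.explained_variance_ratio_)
        assert cum[pcs.k_ - 1] >= 0.9
        if pcs.k_ > 1:
            assert cum[pcs.k_ - 2] < 0.9

    def test_variance_ratios_sum_to_one_and_decrease(self):
        codes = np.random.default_rng(3).standard_normal((100, 6)) * np.arange(1, 7)[::-1]
        pcs = la.fit_latent_pca(codes)
        ratios = pcs.explained_variance_ratio_
        assert ratios.sum() == pytest.approx(1.0)
        assert (np.diff(ratios) <= 1e-12).all()

    def test_full_reconstruction_is_lossless(self):
        codes = np.random.default_rng(4).standard_normal((50, 5))
        pcs = la.fit_latent_pca(codes, variance_threshold=1.0)
        full_proj = pcs.pca_.transform(codes)
        np.testing.assert_allclose(pcs.inverse_transform_full(full_proj), codes, atol=1e-10)

    @pytest.mark.parametrize("thr", [0.0, 1.5, -0.2])
    def test_invalid_threshold_rejected(self, thr):
        with pytest.raises(ValueError):
            la.fit_latent_pca(np.zeros((10, 2)), variance_threshold=thr)

    def test_needs_more_samples_than_dims(self):
        with pytest.raises(ValueError):
            la.fit_latent_pca(np.zeros((5, 8)))


def _toy_space():
    rng = np.random.default_rng(5)
    codes = rng.standard_normal((30, 4))
    meta = pd.DataFrame({
        "material_id": np.repeat([f"m{i}" for i in range(6)], 5),
        "category_id": np.repeat([0, 0, 1, 1, 2, 2], 5),
        "participant_id": 0,
        "segment_index": np.tile(range(5), 6),
    })
    pcs = la.fit_latent_pca(codes, variance_threshold=1.0)
    return pcs, meta


class TestEmbeddings:
    def test_embedding_is_mean_of_projections(self):
        pcs, meta = _toy_space()
        emb, labels = la.material_embeddings(pcs, meta)
        manual = pcs.projections_[:5].mean(axis=0)
        np.testing.assert_allclose(emb.loc["m0"].values, manual)
        assert list(labels.values) == [0, 0, 1, 1, 2, 2]

    def test_one_row_per_material(self):
        pcs, meta = _toy_space()
        emb, _ = la.material_embeddings(pcs, meta)
        assert emb.shape == (6, pcs.k_)

    def test_missing_material_named_in_error(self):
        pcs, meta = _toy_space()
        with pytest.raises(ValueError, match="m99"):
            la.material_embeddings(pcs, meta, materials=[f"m{i}" for i in range(6)] + ["m99"])


class TestCentroids:
    def test_singleton_category_centroid_is_its_embedding(self):
        emb = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
                           index=["a", "b", "c"], columns=["pc1", "pc2"])
        cents = la.category_centroids(emb, pd.Series([0, 1, 1], index=emb.index))
        np.testing.assert_allclose(cents.loc[0].values, [1.0, 2.0])
        np.testing.assert_allclose(cents.loc[1].values, [4.0, 5.0])

    def test_order_invariance(self):
        emb = pd.DataFrame(np.random.default_rng(6).standard_normal((6, 3)),
                           index=[f"m{i}" for i in range(6)])
        labels = pd.Series([0, 1, 0, 1, 0, 1], index=emb.index)
        shuffled = emb.sample(frac=1.0, random_state=1)
        a = la.category_centroids(emb, labels)
        b = la.category_centroids(shuffled, labels.reindex(shuffled.index))
        pd.testing.assert_frame_equal(a, b)


class TestDistanceMatrix:
    def test_two_points_at_known_distance(self):
        cents = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=[0, 1])
        dm = la.centroid_distance_matrix(cents)
        assert dm.values[0, 1] == pytest.approx(5.0)
        assert dm.values[0, 0] == 0.0

    def test_symmetry_zero_diagonal_and_pair_count(self):
        cents = pd.DataFrame(np.random.default_rng(7).standard_normal((7, 4)),
                             index=list(range(7)))
        dm = la.centroid_distance_matrix(cents)
        np.testing.assert_allclose(dm.values, dm.values.T)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)
        assert dm.n_pairs == 21

    def test_identical_centroids_give_zero_matrix(self):
        cents = pd.DataFrame(np.ones((3, 2)), index=[0, 1, 2])
        assert np.allclose(la.centroid_distance_matrix(cents).values, 0.0)

    def test_asymmetric_values_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            la.DistanceMatrix(labels=[0, 1], values=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMatrixCorrelation:
    def _dm(self, values, labels=(0, 1, 2)):
        return la.DistanceMatrix(labels=list(labels), values=np.asarray(values, float))

    def test_self_correlation_is_one(self):
        a = self._dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        assert la.matrix_correlation(a, a) == pytest.approx(1.0)

    def test_affine_invariance(self):
        a = self._dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        b = self._dm(2 * a.values + 3)
        assert la.matrix_correlation(a, b) == pytest.approx(1.0)

    def test_hand_computed_three_by_three(self):
        a = self._dm([[0, 1, 2], [1, 0, 4], [2, 4, 0]])
        b = self._dm([[0, 2, 1], [2, 0, 5], [1, 5, 0]])
        expected = pearsonr([1, 2, 4], [2, 1, 5])[0]
        assert la.matrix_correlation(a, b) == pytest.approx(expected)

    def test_label_mismatch_rejected(self):
        a = self._dm(np.zeros((3, 3)), labels=[0, 1, 2])
        b = self._dm(np.zeros((3, 3)), labels=[0, 2, 1])
        with pytest.raises(ValueError, match="labels"):
            la.matrix_correlation(a, b)


class TestTSNE:
    def test_perplexity_must_be_below_material_count(self):
        emb = pd.DataFrame(np.random.default_rng(8).standard_normal((8, 3)))
        with pytest.raises(ValueError, match="perplexity"):
            la.tsne_embed(emb, perplexity=8)

    def test_fixed_seed_reproducible(self):
        emb = pd.DataFrame(np.random.default_rng(9).standard_normal((30, 4)))
        a = la.tsne_embed(emb, seed=1, perplexity=5)
        b = la.tsne_embed(emb, seed=1, perplexity=5)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_rows_land_close(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((15, 4))
        emb = pd.DataFrame(np.vstack([base, base[:1]]))
        coords = la.tsne_embed(emb, seed=0, perplexity=5)
        d_dup = np.linalg.norm(coords.iloc[0] - coords.iloc[15])
        typical = np.median(
            [np.linalg.norm(coords.iloc[i] - coords.iloc[j])
             for i in range(15) for j in range(i + 1, 15)]
        )
        assert d_dup < 0.2 * typical
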