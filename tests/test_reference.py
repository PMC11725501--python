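"""Subspace construction, MNN machinery, merging, embedding and clustering."""

import numpy as np
import pytest

import embryomap as em
from embryomap.containers import UnitMatrix
from embryomap.errors import EmbryoMapError, ValidationError

from conftest import ORDER


def brute_force_mnn(A, B, k_a, k_b):
    """Exhaustive O(n^2) mutual-nearest-neighbor oracle with (distance, index)
    tie-breaks, independent of the implementation under test."""
    from scipy.spatial.distance import cdist

    D = cdist(A, B)
    k_b_eff, k_a_eff = min(k_b, B.shape[0]), min(k_a, A.shape[0])
    pairs = set()
    nn_a = {a: sorted(range(B.shape[0]), key=lambda b: (D[a, b], b))[:k_b_eff]
            for a in range(A.shape[0])}
    nn_b = {b: sorted(range(A.shape[0]), key=lambda a: (D[a, b], a))[:k_a_eff]
            for b in range(B.shape[0])}
    for a in range(A.shape[0]):
        for b in nn_a[a]:
            if a in nn_b[b]:
                pairs.add((a, b))
    return pairs


def units_from(values, batch="b"):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"{batch}{i}" for i in range(values.shape[1])]
    return UnitMatrix(genes, cells, values)


class TestMultibatchPCA:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        basis = np.linalg.qr(rng.normal(size=(20, 2)))[0]
        X = basis @ rng.normal(size=(2, 50))  # data in a 2-plane
        space = em.multibatch_pca([units_from(X)], 2)
        recon = space.rotation @ space.coords.T + space.grand_centers[:, None]
        assert np.abs(recon - X).max() < 1e-8

    def test_coords_centered(self):
        rng = np.random.default_rng(1)
        space = em.multibatch_pca([units_from(rng.normal(size=(30, 40)) + 3)], 5)
        assert np.abs(space.coords.mean(axis=0)).max() < 1e-8

    def test_duplicating_cells_preserves_subspace(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 30))
        s1 = em.multibatch_pca([units_from(X)], 4)
        s2 = em.multibatch_pca([units_from(np.concatenate([X, X], axis=1))], 4)
        P1 = s1.rotation @ s1.rotation.T
        P2 = s2.rotation @ s2.rotation.T
        assert np.abs(P1 - P2).max() < 1e-8

    def test_rank_deficient_reduces_dimension(self):
        X = np.outer(np.arange(10.0), np.ones(12))  # rank 1 after centering -> rank 0
        X += np.outer(np.ones(10), np.arange(12.0))
        with pytest.warns(UserWarning, match="rank"):
            space = em.multibatch_pca([units_from(X)], 5)
        assert space.rotation.shape[1] < 5


class TestFindMNNPairs:
    def test_single_identical_point(self):
        ia, ib = em.find_mnn_pairs(np.zeros((1, 2)), np.zeros((1, 2)), 1, 1)
        assert list(zip(ia, ib)) == [(0, 0)]

    def test_nearest_of_two(self):
        A = np.array([[0.0, 0.0]])
        B = np.array([[1.0, 0.0], [2.0, 0.0]])
        ia, ib = em.find_mnn_pairs(A, B, k_a=1, k_b=1)
        assert list(zip(ia, ib)) == [(0, 0)]

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_matches_brute_force_oracle(self, k):
        rng = np.random.default_rng(10 + k)
        A = rng.normal(size=(50, 2))
        B = rng.normal(size=(50, 2))
        ia, ib = em.find_mnn_pairs(A, B, k, k)
        assert set(zip(ia.tolist(), ib.tolist())) == brute_force_mnn(A, B, k, k)

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(20)
        A, B = rng.normal(size=(30, 3)), rng.normal(size=(40, 3))
        ia, ib = em.find_mnn_pairs(A, B, 4, 6)
        ja, jb = em.find_mnn_pairs(B, A, 6, 4)
        assert set(zip(ia.tolist(), ib.tolist())) == set(zip(jb.tolist(), ja.tolist()))

    def test_empty_input(self):
        ia, ib = em.find_mnn_pairs(np.empty((0, 2)), np.ones((3, 2)), 2, 2)
        assert len(ia) == 0 and len(ib) == 0


class TestCorrectionField:
    def test_single_pair_single_cell_exact(self):
        A = np.array([[2.0, 1.0]])
        B = np.array([[0.0, 0.0]])
        corr, _ = em.compute_correction_field((np.array([0]), np.array([0])), A, B,
                                              adjust_variance=False)
        assert np.allclose(corr, [[2.0, 1.0]])

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(80, 4))
        c = np.array([5.0, -2.0, 0.5, 1.0])
        A = B + c
        ia = ib = np.arange(80)
        corr, _ = em.compute_correction_field((ia, ib), A, B, adjust_variance=False)
        assert np.abs(corr - c).max() < 1e-6

    def test_equal_spread_scaling_near_one(self):
        rng = np.random.default_rng(4)
        B = rng.normal(size=(100, 3))
        A = B + np.array([3.0, 0.0, 0.0])
        ia = ib = np.arange(100)
        _, info = em.compute_correction_field((ia, ib), A, B, adjust_variance=True)
        assert abs(info["mean_scale"] - 1.0) < 0.05

    def test_no_pairs_is_error(self):
        with pytest.raises(ValidationError):
            em.compute_correction_field((np.array([], int), np.array([], int)),
                                        np.ones((2, 2)), np.ones((2, 2)))


class TestOrthogonalize:
    def test_already_orthogonal_unchanged(self):
        coords = np.array([[0.0, 1.0], [0.0, -2.0]])
        out = em.orthogonalize_along_vector(coords, np.array([1.0, 0.0]), 0.0)
        assert np.allclose(out, coords)

    def test_projection_variance_zero(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(200, 6))
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        out = em.orthogonalize_along_vector(coords, v, 1.5)
        proj = out @ v
        assert proj.var() < 1e-10 and abs(proj.mean() - 1.5) < 1e-10

    def test_arithmetic_example(self):
        out = em.orthogonalize_along_vector(np.array([[2.0, 0.0]]), np.array([1.0, 0.0]), 0.5)
        assert np.allclose(out, [[0.5, 0.0]])

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValidationError):
            em.orthogonalize_along_vector(np.ones((2, 2)), np.array([2.0, 0.0]))


class TestMergeBatches:
    def _cfg(self):
        return em.Config(n_pcs=4, latent_dim=2, umap_neighbors=10, subsample_size=200)

    def test_constant_offset_collapsed(self):
        rng = np.random.default_rng(6)
        A = np.concatenate([rng.normal(size=(60, 4)),
                            rng.normal(size=(60, 4)) + [6, 0, 0, 0]])
        offset = np.array([0.0, 8.0, 0.0, 0.0])
        B = A + offset
        merged, batch_of, records = em.merge_batches({"A": A, "B": B}, ["A", "B"], self._cfg())
        a_idx = np.array([b == "A" for b in batch_of])
        from scipy.spatial.distance import cdist
        before = cdist(A, B).min(axis=1).mean()
        after = cdist(merged[a_idx], merged[~a_idx]).min(axis=1).mean()
        assert after < 0.2 * before
        assert len(records) == 1

    def test_single_batch_no_records(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(30, 3))
        merged, batch_of, records = em.merge_batches({"A": A}, ["A"], self._cfg())
        assert records == [] and np.array_equal(merged, A)

    def test_identical_batches_near_identity(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(50, 4))
        # with k=1 every cell pairs only with its exact copy: zero pair vectors,
        # a degenerate batch direction, and the merge is the exact identity
        cfg1 = em.Config(n_pcs=4, latent_dim=2, umap_neighbors=10, k_mnn_ref=1)
        merged, _, recs = em.merge_batches({"A": A, "B": A.copy(), "C": A.copy()},
                                           ["A", "B", "C"], cfg1)
        assert all(r.degenerate for r in recs)
        assert np.abs(merged[:50] - merged[50:100]).max() < 1e-6
        assert np.abs(merged[:50] - merged[100:]).max() < 1e-6
        # at the default k the kernel field averages nonzero cross-cell pair
        # vectors, so the merge is only near-identity relative to the data scale
        merged20, _, _ = em.merge_batches({"A": A, "B": A.copy(), "C": A.copy()},
                                          ["A", "B", "C"], self._cfg())
        assert np.abs(merged20[:50] - merged20[100:]).max() < 0.05 * A.std()

    def test_merged_projection_variance_zero_after_each_step(self):
        rng = np.random.default_rng(9)
        spaces = {f"b{i}": rng.normal(size=(40, 5)) + i * np.array([4, 0, 0, 0, 0.0])
                  for i in range(3)}
        for upto in (2, 3):
            order = [f"b{i}" for i in range(upto)]
            merged, _, records = em.merge_batches(
                {k: spaces[k] for k in order}, order, self._cfg())
            last = records[-1]
            proj = merged @ last.batch_vector
            assert proj.var() < 1e-10

    def test_disjoint_batches_zero_pairs_error(self):
        # k is capped at set size so pairs always exist with finite points;
        # force the failure with an empty incoming batch
        A = np.zeros((5, 2))
        B = np.empty((0, 2))
        with pytest.raises(EmbryoMapError, match="merge step"):
            em.merge_batches({"A": A, "B": B}, ["A", "B"], self._cfg())

    def test_wrong_order_rejected(self):
        with pytest.raises(ValidationError):
            em.merge_batches({"A": np.ones((3, 2))}, ["A", "B"], self._cfg())


class TestEmbeddingAndClustering:
    def _blobs(self, rng, n=120, sep=25.0, d=6):
        X = rng.normal(size=(n, d))
        X[n // 2:, 0] += sep
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, labels

    def test_same_seed_identical_embeddings(self):
        rng = np.random.default_rng(11)
        X, _ = self._blobs(rng)
        cfg = em.Config(n_pcs=6, latent_dim=2, umap_neighbors=10, rng_seed=3)
        m1 = em.fit_embedding_models(X, [2], cfg)[2]
        m2 = em.fit_embedding_models(X, [2], cfg)[2]
        assert np.array_equal(m1.embedding_, m2.embedding_)

    def test_separated_blobs_stay_separated(self):
        rng = np.random.default_rng(12)
        X, labels = self._blobs(rng)
        cfg = em.Config(n_pcs=6, latent_dim=2, umap_neighbors=10, rng_seed=3)
        emb = em.fit_embedding_models(X, [2], cfg)[2].embedding_
        c0, c1 = emb[labels == 0], emb[labels == 1]
        gap = np.linalg.norm(c0.mean(axis=0) - c1.mean(axis=0))
        r0 = np.quantile(np.linalg.norm(c0 - c0.mean(axis=0), axis=1), 0.95)
        r1 = np.quantile(np.linalg.norm(c1 - c1.mean(axis=0), axis=1), 0.95)
        assert gap > max(r0, r1)

    def test_dim_above_subspace_rejected(self):
        cfg = em.Config(n_pcs=4, latent_dim=2)
        with pytest.raises(ValidationError):
            em.fit_embedding_models(np.random.default_rng(0).normal(size=(30, 4)), [5], cfg)

    def test_leiden_two_blobs(self):
        rng = np.random.default_rng(13)
        X, labels = self._blobs(rng, n=100)
        cfg = em.Config(n_pcs=6, latent_dim=2, umap_neighbors=10, leiden_resolution=0.5,
                        rng_seed=1)
        cl = em.leiden_cluster(X, cfg)
        assert len(set(cl)) == 2
        # each blob maps to a single cluster
        agreement = max(
            np.mean((cl == cl[0]) == (labels == 0)),
            np.mean((cl == cl[0]) == (labels == 1)),
        )
        assert agreement >= 0.99

    def test_leiden_one_tight_blob_low_resolution(self):
        rng = np.random.default_rng(14)
        X = rng.normal(scale=0.1, size=(60, 4))
        cfg = em.Config(n_pcs=4, latent_dim=2, umap_neighbors=10, leiden_resolution=0.1,
                        rng_seed=1)
        assert len(set(em.leiden_cluster(X, cfg))) == 1

    def test_leiden_order_invariant_up_to_relabel(self):
        rng = np.random.default_rng(15)
        X, _ = self._blobs(rng, n=80)
        cfg = em.Config(n_pcs=6, latent_dim=2, umap_neighbors=10, leiden_resolution=0.5,
                        rng_seed=1)
        cl = em.leiden_cluster(X, cfg)
        perm = rng.permutation(len(X))
        cl_p = em.leiden_cluster(X[perm], cfg)
        # compare partitions as co-membership relations
        def comembership(c):
            c = np.asarray(c)
            return c[:, None] == c[None, :]
        assert np.array_equal(comembership(cl[perm]), comembership(cl_p))


class TestBuildReference:
    def test_bookkeeping_and_determinism(self, reference_model, ref_split, pipe_cfg):
        train, _, _, _ = ref_split
        assert len(reference_model.merge_records) == 2
        assert sorted(reference_model.classifiers.lineages) == sorted(
            ["Prelineage", "TE", "ICM", "Epiblast", "Hypoblast"])
        rebuilt = em.build_reference(train, ORDER, pipe_cfg)
        assert np.array_equal(rebuilt.corrected_coords, reference_model.corrected_coords)
        assert rebuilt.lineages == reference_model.lineages

    def test_unlabeled_cells_rejected(self, ref_split, pipe_cfg):
        train, _, _, _ = ref_split
        import pandas as pd
        labels = pd.concat([b.cell_meta["label"] for b in train]).iloc[:-5]
        with pytest.raises(ValidationError, match="unlabeled"):
            em.build_reference(train, ORDER, pipe_cfg, lineage_labels=labels)

    def test_batch_effect_reduced(self, reference_model):
        # mean inter-batch NN distance after merging is far below the
        # lineage-structure scale: batches overlap per lineage
        from scipy.spatial.distance import cdist
        coords = reference_model.corrected_coords
        ds = np.asarray(reference_model.dataset_of_cell)
        lin = np.asarray(reference_model.lineages)
        b0, b1 = coords[ds == "batch0"], coords[ds == "batch1"]
        nn = cdist(b0, b1).min(axis=1)
        within = cdist(coords[lin == "TE"], coords[lin == "Epiblast"]).min(axis=1)
        assert nn.mean() < within.mean()
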