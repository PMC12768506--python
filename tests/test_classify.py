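import numpy as np
import pytest

from mrsifp.classify import (
    UmapParams,
    centroid_scores,
    feature_importance,
    kmeans_subtypes,
    loo_umap,
    roc_auc,
)


def _blob_data(rng, n_patients=6, voxels_per_patient=30, sep=8.0):
    """Three well-separated Gaussian blobs in 5-D, two patients per blob."""
    centers = np.eye(3, 5) * sep
    feats, pids, subs = [], [], []
    for p in range(n_patients):
        blob = p % 3
        feats.append(rng.normal(centers[blob], 1.0, size=(voxels_per_patient, 5)))
        pids += [f"P{p}"] * voxels_per_patient
        subs += [["AC", "OG", "GBM"][blob]] * voxels_per_patient
    return np.vstack(feats), np.array(pids), np.array(subs)


@pytest.fixture(scope="module")
def embedded():
    rng = np.random.default_rng(0)
    feats, pids, subs = _blob_data(rng)
    emb = loo_umap(feats, pids, UmapParams(seed=0))
    return feats, pids, subs, emb


class TestLooUmap:
    def test_fold_structure(self, embedded):
        feats, pids, subs, emb = embedded
        # every voxel's fold is its own patient: no self-trained embedding
        np.testing.assert_array_equal(emb.fold_id, pids)
        assert emb.coords.shape == (len(pids), 2)
        assert np.all(np.isfinite(emb.coords))

    def test_needs_two_patients(self):
        with pytest.raises(ValueError):
            loo_umap(np.ones((10, 3)), np.array(["P0"] * 10))

    def test_duplicate_voxels_embed_identically(self):
        rng = np.random.default_rng(1)
        feats, pids, _ = _blob_data(rng, n_patients=3, voxels_per_patient=25)
        feats[1] = feats[0]  # duplicates within patient 0
        emb = loo_umap(feats, pids, UmapParams(seed=0))
        np.testing.assert_allclose(emb.coords[0], emb.coords[1], atol=1e-5)

    def test_separation_of_separable_blobs(self, embedded):
        """Between-subtype centroid distances exceed mean within-subtype spread."""
        _, _, subs, emb = embedded
        names = np.unique(subs)
        cents = {n: emb.coords[subs == n].mean(axis=0) for n in names}
        spread = np.mean([
            np.linalg.norm(emb.coords[subs == n] - cents[n], axis=1).mean()
            for n in names
        ])
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                assert np.linalg.norm(cents[names[a]] - cents[names[b]]) > spread


class TestKmeans:
    def test_separable_clouds_perfect_accuracy(self, embedded):
        _, _, subs, emb = embedded
        res = kmeans_subtypes(emb.coords, subs, k=3, seed=0, n_boot=100)
        assert res.accuracy == 100.0
        assert set(res.mapping.values()) == {"AC", "OG", "GBM"}
        assert res.quality["silhouette"] > 0.5
        assert res.quality["davies_bouldin"] < 1.0

    def test_single_cluster_degenerate(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(40, 2))
        res = kmeans_subtypes(coords, np.array(["AC"] * 40), k=1, seed=0, n_boot=50)
        assert res.accuracy == 100.0
        assert np.isnan(res.quality["silhouette"])

    def test_accuracy_invariant_under_label_permutation(self, embedded):
        """Hungarian mapping makes the result independent of k-means label ids,
        so a permuted-seed rerun gives the same mapped accuracy."""
        _, _, subs, emb = embedded
        a = kmeans_subtypes(emb.coords, subs, k=3, seed=0, n_boot=50)
        b = kmeans_subtypes(emb.coords, subs, k=3, seed=99, n_boot=50)
        assert a.accuracy == b.accuracy

    def test_permutation_null_matches_majority_fraction(self, embedded):
        """With randomly permuted subtype labels the mapped accuracy collapses
        toward the best achievable by label-count matching."""
        _, _, subs, emb = embedded
        rng = np.random.default_rng(3)
        acc = [
            kmeans_subtypes(emb.coords, rng.permutation(subs), k=3, seed=0,
                            n_boot=10).accuracy
            for _ in range(20)
        ]
        # three balanced classes: chance level ~33%, far below the true 100%
        assert np.mean(acc) < 60.0


class TestRoc:
    def test_perfect_ordering(self):
        labels = np.array(["pos"] * 2 + ["neg"] * 2)
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.1, 0.9]])
        res = roc_auc(scores, labels, ["pos", "neg"])
        assert res.per_class_auc["pos"] == 1.0
        fpr, tpr = res.curves["pos"]
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        labels = np.where(rng.random(n) < 0.5, "a", "b")
        scores = rng.random((n, 2))
        res = roc_auc(scores, labels, ["a", "b"])
        assert res.per_class_auc["a"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        res = roc_auc(np.ones((5, 1)), np.array(["a"] * 5), ["a"])
        assert np.isnan(res.macro_auc)

    def test_centroid_scores_recover_clusters(self, embedded):
        _, _, subs, emb = embedded
        scores, names = centroid_scores(emb.coords, subs)
        res = roc_auc(scores, subs, names)
        assert min(res.per_class_auc.values()) > 0.99


class TestFeatureImportance:
    def test_exact_linear_recovery(self, rng):
        S = rng.normal(size=(200, 4))
        S = (S - S.mean(0)) / S.std(0)
        coords = np.column_stack([2.0 * S[:, 0], S[:, 1]])
        coef = feature_importance(S, coords)
        np.testing.assert_allclose(coef[:, 0], [2, 0, 0, 0], atol=1e-10)

    def test_orthogonal_sum(self, rng):
        S = np.linalg.qr(rng.normal(size=(100, 3)))[0] * 10
        S = (S - S.mean(0)) / S.std(0)
        coords = np.column_stack([S[:, 0] + S[:, 1], S[:, 2]])
        coef = feature_importance(S, coords)
        np.testing.assert_allclose(coef[:, 0], [1, 1, 0], atol=1e-8)

    def test_permuted_coordinate_near_zero(self, rng):
        S = rng.normal(size=(500, 3))
        coords = np.column_stack([S[:, 0], S[:, 1]])
        coords = coords[rng.permutation(500)]
        coef = feature_importance(S, coords)
        assert np.abs(coef).max() < 0.2
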