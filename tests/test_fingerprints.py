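import numpy as np
import pandas as pd
import pytest

from mrsifp.fingerprints import (
    FingerprintMatrix,
    entropy_score,
    to_newick,
    upgma_cluster,
    zscore_matrix,
)


def _voxel_table(patients):
    """patients: dict patient -> (subtype, tumor source values, healthy values)."""
    rows = []
    for pid, (sub, tumor, healthy) in patients.items():
        for v in tumor:
            rows.append({"patient_id": pid, "subtype": sub, "region": "tumor",
                         "source_1": v})
        for v in healthy:
            rows.append({"patient_id": pid, "subtype": sub, "region": "healthy",
                         "source_1": v})
    return pd.DataFrame(rows)


class TestZscore:
    def test_hand_arithmetic(self):
        # tumor (3,5): mean 4; healthy (1,2,3): mean 2, sample sd 1 -> z = 2
        t = _voxel_table({"P1": ("AC", [3.0, 5.0], [1.0, 2.0, 3.0])})
        fm = zscore_matrix(t)
        assert fm.z.loc["P1", "source_1"] == pytest.approx(2.0)

    def test_simple_ratio(self):
        t = _voxel_table({"P1": ("AC", [2.0], [0.5, 1.0, 1.5])})
        # healthy mean 1.0, sd 0.5 -> z = 2.0
        fm = zscore_matrix(t)
        assert fm.z.loc["P1", "source_1"] == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        t = _voxel_table({"P1": ("AC", [2.0], [1.0, 2.0, 3.0])})
        assert zscore_matrix(t).z.loc["P1", "source_1"] == pytest.approx(0.0)

    def test_zero_healthy_sd_is_nan(self):
        t = _voxel_table({"P1": ("AC", [2.0], [1.0, 1.0, 1.0])})
        assert np.isnan(zscore_matrix(t).z.loc["P1", "source_1"])

    def test_patient_without_healthy_excluded(self):
        t = _voxel_table({
            "P1": ("AC", [2.0], []),
            "P2": ("OG", [2.0], [1.0, 2.0]),
        })
        fm = zscore_matrix(t)
        assert list(fm.z.index) == ["P2"]

    def test_affine_invariance(self):
        """z is unchanged when one source is rescaled a*H+b across a patient."""
        t = _voxel_table({"P1": ("AC", [3.0, 5.0], [1.0, 2.0, 3.0])})
        t2 = t.copy()
        t2["source_1"] = 7.0 * t2["source_1"] + 2.0
        assert zscore_matrix(t).z.iloc[0, 0] == pytest.approx(
            zscore_matrix(t2).z.iloc[0, 0])


def _fingerprints(z, subtypes):
    z = pd.DataFrame(z, index=[f"P{i}" for i in range(len(z))],
                     columns=[f"source_{j+1}" for j in range(len(z[0]))])
    return FingerprintMatrix(
        z=z, subtypes=pd.Series(subtypes, index=z.index),
        healthy_stats=pd.DataFrame())


class TestUpgma:
    def test_identical_patients_merge_at_zero(self):
        fm = _fingerprints([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                           ["AC", "AC", "GBM"])
        res = upgma_cluster(fm)
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_rectangle_hand_oracle(self):
        """4 points at rectangle corners (sides 3 and 4): UPGMA merges the two
        side-3 pairs at height 3, then joins them at the average of the
        remaining distances (4,5,5,4)/4 = 4.5."""
        pts = [[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [3.0, 4.0]]
        fm = _fingerprints(pts, ["a", "a", "b", "b"])
        res = upgma_cluster(fm, scale_sources=False)
        heights = sorted(res.linkage[:, 2])
        assert heights == pytest.approx([3.0, 3.0, 4.5])

    def test_merge_heights_nondecreasing(self, rng):
        fm = _fingerprints(rng.normal(size=(10, 4)).tolist(), ["a"] * 5 + ["b"] * 5)
        res = upgma_cluster(fm)
        assert np.all(np.diff(res.linkage[:, 2]) >= -1e-12)
        assert sorted(res.leaf_order) == sorted(fm.z.index)

    def test_inter_group_distance_hand_value(self):
        fm = _fingerprints([[0.0], [2.0], [10.0]], ["a", "a", "b"])
        res = upgma_cluster(fm, scale_sources=False)
        # mean pairwise a<->b distance: (10 + 8) / 2 = 9
        assert res.inter_group_distance[("a", "b")] == pytest.approx(9.0)

    def test_nan_cells_use_pairwise_complete(self):
        fm = _fingerprints([[0.0, 0.0, 0.0], [np.nan, 3.0, 0.0], [4.0, 0.0, 1.0]],
                           ["a", "a", "b"])
        res = upgma_cluster(fm, scale_sources=False)
        D = res.distance_matrix.to_numpy()
        # P0-P1 share the last two coordinates: sqrt((9 + 0) * 3/2)
        assert D[0, 1] == pytest.approx(np.sqrt(13.5))

    def test_heatmap_written(self, tmp_path):
        from mrsifp.fingerprints import plot_heatmap

        fm = _fingerprints([[0.0, 1.0], [1.0, 2.0], [5.0, 0.0]], ["a", "a", "b"])
        res = upgma_cluster(fm)
        out = tmp_path / "heatmap.png"
        plot_heatmap(fm, res, str(out))
        assert out.stat().st_size > 0

    def test_newick_roundtrip(self):
        fm = _fingerprints([[0.0], [1.0], [5.0]], ["a", "a", "b"])
        nwk = to_newick(upgma_cluster(fm))
        assert nwk.endswith(";") and "P2" in nwk
        import io
        from Bio import Phylo
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert tree.count_terminals() == 3


class TestEntropy:
    def test_point_mass_is_zero(self):
        assert entropy_score(np.full((3, 4), 2.5)) == 0.0

    def test_uniform_over_bins(self):
        # values filling 4 bins uniformly -> 2 bits; 32 bins -> 5 bits
        assert entropy_score(np.arange(4.0), n_bins=4) == pytest.approx(2.0)
        assert entropy_score(np.arange(32.0), n_bins=32) == pytest.approx(5.0)

    def test_bounded_by_log2_bins(self, rng):
        vals = rng.normal(size=(6, 7))
        assert entropy_score(vals, n_bins=16) <= 4.0 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy_score(np.array([]))
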