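"""Classical MDS, max-standardization, clustering, and partition recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

import metafinger as mf

from conftest import make_dataset


def procrustes_rmse(X, Y):
    """RMSE between configurations after centering and optimal rotation."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R, _ = orthogonal_procrustes(Yc, Xc)
    return float(np.sqrt(np.mean((Yc @ R - Xc) ** 2)))


class TestClassicalMDS:
    def test_exact_recovery_of_unit_square(self):
        corners = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        D = pd.DataFrame(squareform(pdist(corners)), index=list("abcd"), columns=list("abcd"))
        result = mf.classical_mds(D, dims=2)
        emb = result.coordinates.to_numpy()
        np.testing.assert_allclose(squareform(pdist(emb)), D.to_numpy(), atol=1e-9)
        assert procrustes_rmse(corners, emb) < 1e-9

    def test_equilateral_triangle_from_equal_distances(self):
        D = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        result = mf.classical_mds(D, dims=2)
        emb_dists = pdist(result.coordinates.to_numpy())
        np.testing.assert_allclose(emb_dists, 1.0, atol=1e-9)

    def test_eigenvalues_sorted_and_negatives_reported(self, rng):
        ds, _ = mf.simulate_dataset(mf.prunella_preset(organs=("stems",)), seed=3)
        result = mf.classical_mds(mf.distance_matrix(ds), dims=2)
        assert np.all(np.diff(result.eigenvalues) <= 1e-9)
        # the weighted Manhattan statistic is not Euclidean in general
        assert result.n_negative >= 0

    def test_beats_random_configurations(self, rng):
        """On fingerprint distances with real group structure, the Torgerson
        embedding's stress beats 100 random 2-D configurations. (On
        unstructured near-equidistant distances classical scaling shrinks
        coordinates and the comparison is not meaningful.)"""
        design = mf.prunella_preset(
            organs=("stems",), n_replicates=2, group_effect_sd=1.2, replicate_cv=0.2
        )
        ds, _ = mf.simulate_dataset(design, seed=12)
        D = mf.distance_matrix(ds)
        result = mf.classical_mds(D, dims=2)
        ours = mf.mds_stress(D, result.coordinates)
        scale = float(D.to_numpy().max())
        for _ in range(100):
            random_coords = rng.uniform(-scale, scale, (10, 2))
            assert ours <= mf.mds_stress(D, random_coords)

    def test_missing_distances_rejected(self):
        D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="missing"):
            mf.classical_mds(D)

    def test_replicates_embed_closer_than_other_accessions(self):
        """Strong accession-group effects make replicates cluster together
        in the 2-D embedding: mean within-accession distance is below mean
        between-accession distance."""
        design = mf.prunella_preset(
            organs=("vegetative organs of shoots",),
            group_effect_sd=1.0,
            replicate_cv=0.2,
        )
        ds, _ = mf.simulate_dataset(design, seed=10)
        result = mf.classical_mds(mf.distance_matrix(ds), dims=2)
        coords = result.coordinates
        accession = ds.samples.loc[coords.index, "accession"].to_numpy()
        emb = squareform(pdist(coords.to_numpy()))
        same = accession[:, None] == accession[None, :]
        off = ~np.eye(len(accession), dtype=bool)
        assert emb[same & off].mean() < emb[~same].mean()


class TestStandardizeMax:
    def test_feature_divided_by_its_max(self):
        ds = make_dataset({"a_r1": [2.0], "b_r1": [4.0], "c_r1": [8.0]})
        out = mf.standardize_max(ds)
        np.testing.assert_allclose(out.to_numpy(), [[0.25, 0.5, 1.0]])

    def test_every_feature_attains_one(self, rng):
        ds, _ = mf.simulate_dataset(mf.prunella_preset(organs=("flowers",)), seed=5)
        out = mf.standardize_max(ds)
        np.testing.assert_allclose(out.max(axis=1).to_numpy(), 1.0)
        assert float(out.to_numpy().min()) >= 0.0

    def test_idempotent(self):
        ds = make_dataset({"a_r1": [2.0, 1.0], "b_r1": [4.0, 3.0]})
        once = mf.standardize_max(ds)
        twice = mf.standardize_max(
            mf.Dataset(once, ds.samples, ds.features.loc[once.index])
        )
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_feature_dropped_with_warning(self):
        ds = make_dataset({"a_r1": [1.0, 0.0], "b_r1": [2.0, 0.0]})
        with pytest.warns(UserWarning, match="dropped"):
            out = mf.standardize_max(ds)
        assert list(out.index) == ["f1"]


class TestKMeans:
    def test_recovers_two_separated_groups(self, rng):
        left = rng.normal(0.0, 0.05, (20, 6))
        right = rng.normal(1.0, 0.05, (20, 6))
        values = np.clip(np.hstack([left, right]), 0, None)
        ds = make_dataset({f"s{j}_r1": values[:, j] for j in range(12)})
        std = mf.standardize_max(ds)
        result = mf.kmeans_cluster(std, k=2, seed=0)
        truth = [0] * 6 + [1] * 6
        assert mf.adjusted_rand_index(result.assignments, truth) == 1.0

    def test_k_one_wcss_equals_total_ss(self, rng):
        values = rng.gamma(2.0, 3.0, (15, 8))
        ds = make_dataset({f"s{j}_r1": values[:, j] for j in range(8)})
        std = mf.standardize_max(ds)
        result = mf.kmeans_cluster(std, k=1, seed=0)
        X = std.to_numpy().T
        total_ss = float(((X - X.mean(axis=0)) ** 2).sum())
        assert result.within_ss == pytest.approx(total_ss, rel=1e-9)

    def test_same_seed_same_assignment(self, rng):
        values = rng.gamma(2.0, 3.0, (20, 9))
        ds = make_dataset({f"s{j}_r1": values[:, j] for j in range(9)})
        std = mf.standardize_max(ds)
        a = mf.kmeans_cluster(std, k=3, seed=7).assignments
        b = mf.kmeans_cluster(std, k=3, seed=7).assignments
        pd.testing.assert_series_equal(a, b)

    def test_k_exceeding_samples_rejected(self, tiny_dataset):
        std = mf.standardize_max(tiny_dataset)
        with pytest.raises(ValueError):
            mf.kmeans_cluster(std, k=10)


class TestHierarchical:
    def test_recovers_three_planted_accession_groups(self):
        """One distinct group, three co-generated accessions, one independent
        accession: cutting at k=3 recovers the planted partition exactly."""
        design = mf.prunella_preset(
            organs=("vegetative organs of shoots",),
            group_effect_sd=1.0,
            replicate_cv=0.2,
        )
        ds, truth = mf.simulate_dataset(design, seed=0)
        std = mf.standardize_max(ds)
        result = mf.hierarchical_cluster(std, k=3)
        labels_true = truth.group_of_sample.loc[result.assignments.index]
        assert mf.adjusted_rand_index(result.assignments, labels_true) == 1.0

    def test_identical_samples_merge_first_at_height_zero(self, rng):
        values = rng.gamma(2.0, 3.0, 10)
        ds = make_dataset(
            {"a_r1": values, "b_r1": values, "c_r1": values + 5.0}
        )
        std = mf.standardize_max(ds)
        result = mf.hierarchical_cluster(std, k=2)
        first_merge = result.merge_tree[0]
        assert first_merge[2] == 0.0
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_single_linkage_merge_heights_equal_mst_edges(self, rng):
        values = rng.gamma(2.0, 3.0, (12, 6))
        ds = make_dataset({f"s{j}_r1": values[:, j] for j in range(6)})
        std = mf.standardize_max(ds)
        result = mf.hierarchical_cluster(std, k=2, linkage="single")
        D = squareform(pdist(std.to_numpy().T))
        mst = minimum_spanning_tree(D).toarray()
        mst_weights = np.sort(mst[mst > 0])
        np.testing.assert_allclose(np.sort(result.merge_tree[:, 2]), mst_weights, rtol=1e-12)

    def test_precomputed_distance_input(self):
        ds, _ = mf.simulate_dataset(mf.prunella_preset(organs=("stems",)), seed=2)
        D = mf.distance_matrix(ds)
        result = mf.hierarchical_cluster(D, k=3, precomputed=True)
        assert set(result.assignments.index) == set(D.index)
        assert result.assignments.nunique() == 3

    def test_invalid_linkage_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            mf.hierarchical_cluster(mf.standardize_max(tiny_dataset), k=2, linkage="ward2")


class TestARI:
    def test_identical_partitions(self):
        assert mf.adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_singletons_vs_one_cluster_is_chance(self):
        assert mf.adjusted_rand_index([0, 1, 2, 3], [0, 0, 0, 0]) == 0.0

    def test_hand_contingency_case(self):
        # contingency (2,1;1,2) on 6 items: closed form gives -1/9
        ari = mf.adjusted_rand_index([0, 0, 0, 1, 1, 1], [0, 0, 1, 0, 1, 1])
        assert ari == pytest.approx(-1.0 / 9.0, abs=1e-12)

    def test_label_permutation_invariance(self, rng):
        labels = rng.integers(0, 4, 40)
        mapping = {0: "d", 1: "c", 2: "b", 3: "a"}
        renamed = [mapping[v] for v in labels]
        assert mf.adjusted_rand_index(labels, renamed) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mf.adjusted_rand_index([1, 2], [1, 2, 3])
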