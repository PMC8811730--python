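"""Clustering: distances, k-means, DBSCAN, k-selection criteria."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import phenoclust as pc
from phenoclust.cluster import PhenotypeDBSCAN, PhenotypeKMeans
from _helpers import dbscan_reachability_oracle as _dbscan_reachability_oracle
from _helpers import silhouette_oracle as _silhouette_oracle


class TestDistances:
    def test_sed_hand_values(self):
        assert pc.dist_sed([1, 2], [1, 2]) == 0
        assert pc.dist_sed([1, 0], [0, 1]) == pytest.approx(2.0)

    def test_sed_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u, v = rng.normal(size=(2, 7))
            oracle = sum((a - b) ** 2 for a, b in zip(u, v))
            assert pc.dist_sed(u, v) == pytest.approx(oracle, rel=1e-12)

    def test_cd_parallel_orthogonal_antiparallel(self):
        u = np.array([1.0, 2.0, -1.0])
        assert pc.dist_cd(u, 3 * u) == pytest.approx(0.0, abs=1e-12)
        assert pc.dist_cd([1, 0], [0, 1]) == pytest.approx(1.0)
        assert pc.dist_cd(u, -u) == pytest.approx(2.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            pc.dist_cd([0, 0], [1, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pc.dist_sed([1], [1, 2])


class TestKMeans:
    def test_separable_blobs_recovered(self, blobs):
        X, labels = blobs
        est = PhenotypeKMeans(3, "sed", n_replicates=5, random_state=0).fit(X)
        assert adjusted_rand_score(labels, est.labels_) == 1.0

    def test_objective_matches_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 3))
        est = PhenotypeKMeans(2, "sed", n_replicates=20, random_state=0).fit(X)
        best = np.inf
        for mask in itertools.product([0, 1], repeat=6):
            if len(set(mask)) < 2:
                continue
            obj = 0.0
            for side in (0, 1):
                members = X[np.array(mask) == side]
                obj += ((members - members.mean(axis=0)) ** 2).sum()
            best = min(best, obj)
        assert est.inertia_ == pytest.approx(best, rel=1e-9)

    def test_k_equals_n_gives_zero_objective(self):
        X = np.random.default_rng(2).normal(size=(5, 3))
        est = PhenotypeKMeans(5, "sed", n_replicates=3, random_state=0).fit(X)
        assert est.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_objective_never_increases(self, zscored):
        _, Z = zscored
        for metric in ("sed", "cd"):
            est = PhenotypeKMeans(5, metric, n_replicates=1, random_state=4).fit(Z)
            hist = np.array(est.objective_history_)
            assert np.all(np.diff(hist) <= 1e-9)

    def test_best_of_replicates_no_worse_than_single(self, zscored):
        _, Z = zscored
        multi = PhenotypeKMeans(6, "cd", n_replicates=10, random_state=7).fit(Z)
        single = PhenotypeKMeans(6, "cd", n_replicates=1, random_state=7).fit(Z)
        assert multi.inertia_ <= single.inertia_ + 1e-12

    def test_deterministic_given_seed(self, zscored):
        _, Z = zscored
        a = PhenotypeKMeans(4, "cd", 3, random_state=11).fit(Z)
        b = PhenotypeKMeans(4, "cd", 3, random_state=11).fit(Z)
        assert np.array_equal(a.labels_, b.labels_)
        assert a.inertia_ == b.inertia_

    def test_spherical_kmeans_equals_sed_on_unit_vectors(self, zscored):
        """1 - cos(theta) = ||u - v||^2 / 2 on unit vectors, so cosine
        k-means and SED k-means on the normalized data must agree."""
        _, Z = zscored
        Zu = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        a = PhenotypeKMeans(5, "cd", 5, random_state=3).fit(Z)
        b = PhenotypeKMeans(5, "sed", 5, random_state=3).fit(Zu)
        assert np.array_equal(a.labels_, b.labels_)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="n_clusters"):
            PhenotypeKMeans(10, "sed").fit(np.zeros((3, 2)))

    def test_planted_archetypes_recovered(self, cd_model, zscored, dataset_noisy):
        """cd k-means at the true k separates the five planted phenotypes."""
        kept, _ = zscored
        _, truth = dataset_noisy
        labels_true = pc.truth_labels_for(kept, truth)
        pred = [l for l, t in zip(cd_model.labels, labels_true) if t != "mixed"]
        true = [t for t in labels_true if t != "mixed"]
        assert adjusted_rand_score(true, pred) > 0.9

    def test_raw_centroids_are_recomputable_medians(self, cd_model, zscored, registry):
        kept, _ = zscored
        raw = pc.vectors_to_matrix(kept, registry)
        for cl in range(1, cd_model.k + 1):
            members = raw[cd_model.labels == cl]
            assert np.allclose(
                cd_model.raw_centroids[cl - 1], np.median(members, axis=0)
            )

    def test_label_permutation_leaves_centroid_set_unchanged(self, zscored, registry):
        kept, Z = zscored
        m1 = pc.kmeans_cluster(Z, kept, 4, "cd", 5, seed=1, registry=registry)
        m2 = pc.kmeans_cluster(Z, kept, 4, "cd", 5, seed=99, registry=registry)
        # same partition up to relabeling -> same centroid rows as a set
        if adjusted_rand_score(m1.labels, m2.labels) == 1.0:
            s1 = {tuple(np.round(r, 9)) for r in m1.raw_centroids}
            s2 = {tuple(np.round(r, 9)) for r in m2.raw_centroids}
            assert s1 == s2


class TestDBSCAN:
    def test_single_blob_fully_clustered(self):
        X = np.random.default_rng(0).normal(size=(40, 3)) * 0.1
        est = PhenotypeDBSCAN(eps=1.0, min_samples=5, metric="sed").fit(X)
        assert est.n_clusters_ == 1
        assert est.frac_clustered_ == 1.0

    def test_default_min_samples_is_twice_dimensionality(self):
        assert pc.default_np_min(11) == 22
        est = PhenotypeDBSCAN(eps=0.5).fit(np.zeros((30, 11)) + np.arange(30)[:, None])
        assert est.min_samples_ == 22

    @pytest.mark.parametrize("metric", ["sed", "cd"])
    def test_labels_match_reachability_oracle(self, metric):
        rng = np.random.default_rng(8)
        X = np.vstack(
            [rng.normal(0, 0.3, (12, 4)), rng.normal(4, 0.3, (12, 4)),
             rng.normal([0, 8, 0, 8], 0.3, (6, 4))]
        )
        eps = 0.8 if metric == "sed" else 0.02
        est = PhenotypeDBSCAN(eps=eps, min_samples=4, metric=metric).fit(X)
        oracle = _dbscan_reachability_oracle(X, eps, 4, metric)
        # identical noise sets and identical partitions of clustered points
        assert np.array_equal(est.labels_ == -1, oracle == -1)
        assert adjusted_rand_score(oracle[oracle != -1],
                                   est.labels_[est.labels_ != -1]) == 1.0

    def test_outlier_detected_as_noise(self):
        X = np.vstack([np.random.default_rng(1).normal(0, 0.2, (30, 3)),
                       [[50.0, 50.0, 50.0]]])
        est = PhenotypeDBSCAN(eps=1.0, min_samples=5, metric="sed").fit(X)
        assert est.labels_[-1] == pc.NOISE
        assert est.frac_clustered_ < 1.0

    def test_sweep_tabulates_one_row_per_eps(self, zscored):
        _, Z = zscored
        table = pc.sweep_dbscan(Z, [0.02, 0.05, 0.1], np_min=5, metric="cd")
        assert len(table) == 3
        assert set(table.columns) == {
            "eps", "n_clusters", "frac_clustered", "frac_in_cluster1"
        }

    def test_tiny_eps_on_spread_data_finds_nothing(self):
        X = np.random.default_rng(3).uniform(-5, 5, (50, 4))
        table = pc.sweep_dbscan(X, [1e-6], np_min=4, metric="sed")
        assert table.loc[0, "n_clusters"] == 0
        assert table.loc[0, "frac_clustered"] == 0.0


class TestEvaluateK:
    def test_silhouette_picks_three_blobs(self, blobs):
        X, _ = blobs
        table, optimal = pc.evaluate_k(X, "silhouette", "sed", k_max=6, seed=0)
        assert optimal == 3
        assert list(table["k"]) == [2, 3, 4, 5, 6]

    def test_silhouette_matches_hand_formula(self, blobs):
        from sklearn.metrics import silhouette_score

        X, labels = blobs
        for metric, sk in (("sed", "sqeuclidean"), ("cd", "cosine")):
            assert silhouette_score(X, labels, metric=sk) == pytest.approx(
                _silhouette_oracle(X, labels, metric), rel=1e-9
            )

    def test_gap_criterion_picks_three_blobs(self, blobs):
        X, _ = blobs
        _, optimal = pc.evaluate_k(X, "gap", "sed", k_max=5, seed=0, gap_b=20)
        assert optimal == 3

    @pytest.mark.parametrize("criterion", ["davies_bouldin", "calinski_harabasz"])
    def test_euclidean_only_criteria_reject_cosine(self, criterion):
        with pytest.raises(ValueError, match="only defined with metric 'sed'"):
            pc.evaluate_k(np.zeros((10, 2)), criterion, "cd")

    @pytest.mark.parametrize("criterion", ["davies_bouldin", "calinski_harabasz"])
    def test_euclidean_criteria_pick_three_blobs(self, blobs, criterion):
        X, _ = blobs
        _, optimal = pc.evaluate_k(X, criterion, "sed", k_max=6, seed=0)
        assert optimal == 3

    def test_true_k_found_on_study_dataset(self, zscored):
        _, Z = zscored
        _, optimal = pc.evaluate_k(Z, "silhouette", "cd", k_max=8, seed=2)
        assert optimal == 5


class TestModelPersistence:
    def test_save_load_round_trip(self, cd_model, tmp_path):
        cd_model.save(tmp_path / "model")
        again = pc.ClusterModel.load(tmp_path / "model")
        assert again.k == cd_model.k
        assert again.metric == cd_model.metric
        assert np.array_equal(again.labels, cd_model.labels)
        assert np.allclose(again.raw_centroids, cd_model.raw_centroids)
        assert again.index == cd_model.index
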