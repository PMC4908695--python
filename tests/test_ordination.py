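"""PCA, Procrustes, DAPC, clustering, RDA, and PERMANOVA behaviour."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from lekstruct.ordination import (
    dapc_fit,
    find_clusters,
    optimize_a_score,
    pair_sharing_distance_test,
    permanova,
    procrustes_correlation,
    procrustes_permutation_test,
    rda_fit,
    run_pca,
)


class TestPca:
    def test_identical_rows_have_zero_variance(self):
        x = np.tile([1.0, 2.0, 3.0], (5, 1))
        res = run_pca(x, 2)
        assert np.allclose(res.axis_variance_fraction, 0)
        assert np.allclose(res.scores, 0)

    def test_two_point_toy_puts_all_variance_on_pc1(self):
        res = run_pca(np.array([[0.0, 2.0], [2.0, 0.0]]), 1)
        assert res.axis_variance_fraction[0] == pytest.approx(1.0)
        # hand SVD: centered rows (-1,1),(1,-1) -> scores +-sqrt(2)
        assert np.allclose(np.sort(np.abs(res.scores[:, 0])), [np.sqrt(2)] * 2)

    def test_variance_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        res = run_pca(rng.standard_normal((20, 40)), 10)
        assert np.all(np.diff(res.axis_variance_fraction) <= 1e-12)
        assert res.axis_variance_fraction.sum() <= 1 + 1e-12

    def test_full_rank_scores_preserve_euclidean_distances(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 7))
        res = run_pca(x, 12)
        assert np.allclose(pdist(res.scores), pdist(x - x.mean(axis=0)), atol=1e-8)

    def test_requesting_too_many_axes_truncates_with_warning(self):
        with pytest.warns(UserWarning):
            res = run_pca(np.random.default_rng(0).standard_normal((4, 10)), 9)
        assert res.n_axes == 4


class TestProcrustes:
    def test_similarity_transform_gives_perfect_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((25, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        y = 3.5 * x @ rot + np.array([10.0, -4.0])
        assert procrustes_correlation(x, y) == pytest.approx(1.0, abs=1e-10)

    def test_statistic_is_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x = rng.standard_normal((15, 2))
            y = rng.standard_normal((15, 2))
            assert procrustes_correlation(x, y) == pytest.approx(
                procrustes_correlation(y, x), abs=1e-12
            )

    def test_matches_scipy_orthogonal_procrustes_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 2))
        y = 0.4 * x + 0.3 * rng.standard_normal((30, 2))
        _, _, disparity = scipy_procrustes(x, y)
        assert procrustes_correlation(x, y) == pytest.approx(
            np.sqrt(1 - disparity), abs=1e-10
        )

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            procrustes_correlation(np.zeros((10, 2)), np.random.default_rng(0).standard_normal((10, 2)))

    def test_perfect_correspondence_reaches_minimal_p(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((12, 2))
        res = procrustes_permutation_test(x, 2.0 * x, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_p_value_in_half_open_unit_interval(self):
        rng = np.random.default_rng(7)
        res = procrustes_permutation_test(
            rng.standard_normal((15, 2)), rng.standard_normal((15, 2)), n_perm=99, seed=2
        )
        assert 0 < res.p_value <= 1


class TestPairSharing:
    def test_tight_clusters_reach_minimal_p(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        labels = np.repeat(["a", "b", "c"], 8)
        scores = centers[np.repeat(np.arange(3), 8)] + 0.1 * rng.standard_normal((24, 2))
        res = pair_sharing_distance_test(scores, labels, n_perm=1000, seed=3)
        assert res.p_value == pytest.approx(1 / 1001)

    def test_label_shuffle_destroys_significance(self):
        rng = np.random.default_rng(9)
        centers = np.array([[0, 0], [50, 0], [0, 50]])
        labels = np.repeat(["a", "b", "c"], 8)
        scores = centers[np.repeat(np.arange(3), 8)] + 0.1 * rng.standard_normal((24, 2))
        shuffled = rng.permutation(labels)
        res = pair_sharing_distance_test(scores, shuffled, n_perm=500, seed=4)
        assert res.p_value > 0.05

    def test_no_sharing_pairs_rejected(self):
        with pytest.raises(ValueError):
            pair_sharing_distance_test(np.zeros((3, 2)), ["a", "b", "c"], 10, 0)

    def test_label_permutation_null_available(self):
        rng = np.random.default_rng(10)
        scores = rng.standard_normal((20, 2))
        labels = np.repeat(["a", "b"], 10)
        res = pair_sharing_distance_test(scores, labels, 199, 0, null_method="labels")
        assert 0 < res.p_value <= 1


class TestDapc:
    def test_separated_groups_fully_reassigned(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((40, 30))
        x[:20, 0] += 50.0
        labels = np.repeat(["north", "south"], 20)
        model = dapc_fit(x, labels, n_pcs=5)
        assert model.reassignment_overall == 1.0
        assert np.allclose(model.assignment_probs.sum(axis=1), 1.0)
        assert model.df_scores.shape[1] <= 1  # k - 1 discriminant functions

    def test_singleton_group_rejected(self):
        x = np.random.default_rng(12).standard_normal((5, 10))
        with pytest.raises(ValueError):
            dapc_fit(x, ["a", "a", "a", "a", "b"], n_pcs=2)

    def test_random_labels_reassign_near_chance(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((60, 50))
        labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
        model = dapc_fit(x, labels, n_pcs=2)
        # with only 2 retained PCs and no structure, reassignment stays near 1/3
        assert model.reassignment_overall < 0.65

    def test_hierarchical_complex_assignment_beats_lek(self, hierarchical_dosage, hierarchical_truth):
        s = hierarchical_truth.samples
        lek = dapc_fit(hierarchical_dosage, s.leks, n_pcs=15)
        cx = dapc_fit(hierarchical_dosage, s.complexes, n_pcs=15)
        assert cx.reassignment_overall > lek.reassignment_overall


class TestAlphaScore:
    def test_pure_noise_alpha_near_zero(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((45, 60))
        labels = np.repeat(["a", "b", "c"], 15)
        res = optimize_a_score(x, labels, candidates=[2, 5, 10], n_replicates=8, seed=1)
        assert abs(res["alpha_mean"]) < 0.35

    def test_structured_data_yields_positive_alpha_and_replicate_sd(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal((45, 60))
        x[:15, :3] += 4.0
        x[15:30, 3:6] += 4.0
        labels = np.repeat(["a", "b", "c"], 15)
        res = optimize_a_score(x, labels, candidates=[1, 2, 4, 8], n_replicates=6, seed=2)
        assert res["alpha_mean"] > 0.3
        assert res["n_replicates"] == 6
        assert res["alpha_sd"] >= 0


class TestFindClusters:
    def test_two_blobs_select_k_two(self):
        # separation on one axis embedded in noise dimensions: the BIC
        # penalty can only win when extra splits stop reducing noise WSS
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(30 + seed)
            x = rng.standard_normal((40, 25))
            x[:20, 0] += 10.0
            res = find_clusters(x, k_max=6, n_pcs_for_kmeans=24, seed=seed)
            hits += res["best_k"] == 2
        assert hits >= 4

    def test_assignments_partition_all_individuals(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal((30, 8))
        res = find_clusters(x, k_max=4, n_pcs_for_kmeans=4, seed=0)
        assert len(res["assignments"]) == 30

    def test_homogeneous_blob_prefers_small_k(self):
        prefer_small = 0
        for seed in range(5):
            rng = np.random.default_rng(50 + seed)
            x = rng.standard_normal((40, 25))
            res = find_clusters(x, k_max=5, n_pcs_for_kmeans=24, seed=seed)
            prefer_small += res["best_k"] <= 2
        assert prefer_small >= 3


class TestRda:
    def test_linear_response_fully_constrained(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal((30, 2))
        y = x @ rng.standard_normal((2, 15))
        res = rda_fit(y, x)
        assert res.axis_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_predictors_explain_nothing(self):
        rng = np.random.default_rng(18)
        n = 400
        x = rng.standard_normal((n, 2))
        y = rng.standard_normal((n, 5))
        res = rda_fit(y, x)
        assert res.axis_variance_fraction.sum() < 0.05

    def test_constrained_variance_bounded_by_pca(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            y = rng.standard_normal((25, 12))
            x = rng.standard_normal((25, 2))
            rda = rda_fit(y, x)
            pca = run_pca(y, 2)
            assert rda.axis_variance_fraction.sum() <= pca.axis_variance_fraction.sum() + 1e-10

    def test_constant_predictor_rejected(self):
        y = np.random.default_rng(20).standard_normal((10, 4))
        with pytest.raises(ValueError):
            rda_fit(y, np.ones((10, 1)))

    def test_collinear_predictors_warn(self):
        rng = np.random.default_rng(21)
        x1 = rng.standard_normal(30)
        x = np.column_stack([x1, x1 + 0.01 * rng.standard_normal(30)])
        with pytest.warns(UserWarning):
            rda_fit(rng.standard_normal((30, 5)), x)


class TestPermanova:
    def test_separated_clusters_give_r2_near_one_and_minimal_p(self):
        rng = np.random.default_rng(22)
        centers = np.array([[0, 0], [100, 0], [0, 100]])
        labels = np.repeat(["a", "b", "c"], 10)
        scores = centers[np.repeat(np.arange(3), 10)] + 0.1 * rng.standard_normal((30, 2))
        r2, f, res = permanova(scores, labels, n_perm=999, seed=1)
        assert r2 > 0.99
        assert res.p_value == pytest.approx(1 / 1000)

    def test_r2_matches_direct_anova_partition(self):
        # Euclidean equivalence: distance-based SS equals the ANOVA partition
        rng = np.random.default_rng(23)
        scores = rng.standard_normal((24, 2))
        labels = rng.choice(["a", "b", "c"], size=24, p=[0.5, 0.3, 0.2])
        r2, f, _ = permanova(scores, labels, n_perm=19, seed=2)
        grand = scores.mean(axis=0)
        ss_total = np.sum((scores - grand) ** 2)
        ss_within = sum(
            np.sum((scores[labels == g] - scores[labels == g].mean(axis=0)) ** 2)
            for g in set(labels)
        )
        assert r2 == pytest.approx((ss_total - ss_within) / ss_total, abs=1e-10)

    def test_matches_skbio_pseudo_f(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(24)
        scores = rng.standard_normal((18, 2))
        labels = list(np.repeat(["a", "b", "c"], 6))
        d = np.sqrt(((scores[:, None] - scores[None]) ** 2).sum(-1))
        ref = skbio_permanova(DistanceMatrix(d), grouping=labels, permutations=9)
        _, f, _ = permanova(scores, np.array(labels), n_perm=9, seed=0)
        assert f == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((5, 2)), ["a"] * 5, 9, 0)
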