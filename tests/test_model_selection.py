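"""Validity metrics against independent references; selection heuristics."""

import dataclasses

import numpy as np
import pytest
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from mmclust.clustering import kmodes_fit, lca_fit
from mmclust.model_selection import (
    MetricUndefinedError,
    ValidityReport,
    aggregate_repeats,
    bic_select,
    calinski_harabasz,
    cluster_size_summary,
    davies_bouldin,
    evaluate_model,
    scree_elbow,
    select_best,
    silhouette,
)

from conftest import planted_matrix, random_condition_matrix


def make_report(method="kmodes", ch=10.0, db=1.0, sil=0.2, **kw):
    base = dict(
        method=method,
        k=4,
        calinski_harabasz=ch,
        davies_bouldin=db,
        silhouette=sil,
        n_singleton_clusters=0,
        median_cluster_size=10.0,
        min_cluster_size=5,
        max_cluster_size=20,
    )
    base.update(kw)
    return ValidityReport(**base)


class TestCalinskiHarabasz:
    def test_matches_sklearn_reference(self, rng):
        for seed in range(4):
            local = np.random.default_rng(seed)
            X = random_condition_matrix(local, 50, 8)
            labels = local.integers(0, 3, 50)
            if len(np.unique(labels)) < 2:
                continue
            ours = calinski_harabasz(X, labels)
            ref = calinski_harabasz_score(X.values.astype(float), labels)
            assert ours == pytest.approx(ref, abs=1e-10)


class TestDaviesBouldin:
    def test_matches_sklearn_reference(self):
        for seed in range(4):
            local = np.random.default_rng(10 + seed)
            X = random_condition_matrix(local, 50, 8)
            labels = local.integers(0, 3, 50)
            if len(np.unique(labels)) < 2:
                continue
            ours = davies_bouldin(X, labels, dissimilarity="euclidean_binary")
            ref = davies_bouldin_score(X.values.astype(float), labels)
            assert ours == pytest.approx(ref, abs=1e-10)


class TestSilhouette:
    def test_matches_direct_computation(self):
        """Equals the O(n^2) textbook formula under matching dissimilarity."""
        local = np.random.default_rng(3)
        X = random_condition_matrix(local, 100, 10)
        labels = local.integers(0, 3, 100)
        ours = silhouette(X, labels, dissimilarity="matching")
        D = (X.values[:, None, :] != X.values[None, :, :]).sum(axis=2).astype(float)
        vals = []
        for i in range(100):
            same = (labels == labels[i]) & (np.arange(100) != i)
            if same.sum() == 0:
                vals.append(0.0)
                continue
            a = D[i, same].mean()
            b = min(
                D[i, labels == other].mean()
                for other in np.unique(labels)
                if other != labels[i]
            )
            vals.append((b - a) / max(a, b))
        assert ours == pytest.approx(np.mean(vals), abs=1e-12)

    def test_matches_sklearn_euclidean(self):
        local = np.random.default_rng(4)
        X = random_condition_matrix(local, 80, 9)
        labels = local.integers(0, 3, 80)
        ours = silhouette(X, labels, dissimilarity="euclidean_binary")
        ref = silhouette_score(X.values.astype(float), labels, metric="euclidean")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_perfectly_separated_patterns_score_one(self):
        X_rows = [[1, 1, 0, 0]] * 5 + [[0, 0, 1, 1]] * 5
        from test_clustering import as_cm

        labels = np.array([0] * 5 + [1] * 5)
        assert silhouette(as_cm(X_rows), labels) == pytest.approx(1.0)

    def test_subsampling_contract(self):
        """Full computation below the threshold; seeded subsample above it."""
        local = np.random.default_rng(5)
        X = random_condition_matrix(local, 200, 8)
        labels = local.integers(0, 4, 200)
        full = silhouette(X, labels, subsample_threshold=1000)
        sub_a = silhouette(X, labels, subsample_threshold=100, subsample_size=120, seed=1)
        sub_b = silhouette(X, labels, subsample_threshold=100, subsample_size=120, seed=1)
        assert sub_a == sub_b
        assert abs(sub_a - full) < 0.1

    def test_single_cluster_is_undefined(self, small_matrix):
        with pytest.raises(MetricUndefinedError):
            silhouette(small_matrix, np.zeros(small_matrix.n_persons, dtype=int))


class TestDegenerateMetricCases:
    def test_ch_infinite_for_pointmass_clusters(self):
        from test_clustering import as_cm

        X = as_cm([[1, 0, 0]] * 4 + [[0, 1, 1]] * 4)
        labels = np.array([0] * 4 + [1] * 4)
        assert calinski_harabasz(X, labels) == np.inf

    def test_db_near_zero_for_tight_separated(self):
        from test_clustering import as_cm

        rows = [[1, 1, 1, 0, 0, 0]] * 9 + [[1, 1, 1, 1, 0, 0]] + [
            [0, 0, 0, 1, 1, 1]
        ] * 9 + [[0, 0, 1, 1, 1, 1]]
        labels = np.array([0] * 10 + [1] * 10)
        assert davies_bouldin(as_cm(rows), labels) < 0.25

    def test_db_infinite_for_coincident_centroids(self):
        from test_clustering import as_cm

        X = as_cm([[1, 0], [0, 1], [1, 0], [0, 1]])
        labels = np.array([0, 0, 1, 1])  # identical centroids (0.5, 0.5)
        assert davies_bouldin(X, labels) == np.inf

    def test_metrics_undefined_for_k1_or_kn(self, small_matrix):
        n = small_matrix.n_persons
        with pytest.raises(MetricUndefinedError):
            calinski_harabasz(small_matrix, np.zeros(n, dtype=int))
        with pytest.raises(MetricUndefinedError):
            calinski_harabasz(small_matrix, np.arange(n))

    def test_label_permutation_invariance(self):
        local = np.random.default_rng(8)
        X = random_condition_matrix(local, 60, 8)
        labels = local.integers(0, 3, 60)
        perm = np.array([2, 0, 1])
        for fn in (calinski_harabasz, davies_bouldin, silhouette):
            assert fn(X, labels) == pytest.approx(fn(X, perm[labels]), rel=1e-12)

    def test_column_duplication_scale_invariance(self):
        """Duplicating every condition column scales all matching distances by
        two and leaves silhouette (and DB ratios) unchanged."""
        from mmclust.clustering import ConditionMatrix

        local = np.random.default_rng(9)
        X = random_condition_matrix(local, 50, 6)
        labels = local.integers(0, 3, 50)
        doubled = ConditionMatrix(
            np.hstack([X.values, X.values]),
            X.condition_names + [f"{c}_dup" for c in X.condition_names],
            X.person_ids,
        )
        assert silhouette(X, labels) == pytest.approx(
            silhouette(doubled, labels), abs=1e-12
        )
        assert davies_bouldin(X, labels, "matching") == pytest.approx(
            davies_bouldin(doubled, labels, "matching"), rel=1e-12
        )


class TestScreeElbow:
    def test_distance_to_chord_picks_the_knee(self):
        assert scree_elbow({1: 100, 2: 40, 3: 35, 4: 33, 5: 32}) == 2

    def test_linear_decline_warns_and_returns_smallest(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            k = scree_elbow({2: 30, 3: 20, 4: 10})
        assert k == 2
        assert any("no elbow" in r.message for r in caplog.records)

    def test_single_drop_then_flat(self):
        assert scree_elbow({1: 10, 2: 2, 3: 2, 4: 2}) == 2

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            scree_elbow({2: 5, 3: 4})


class TestBICSelect:
    def test_argmin_and_tie_rule(self):
        assert bic_select({2: 500.0, 3: 480.0, 4: 495.0}) == 3
        assert bic_select({2: 480.0, 3: 480.0}) == 2

    def test_planted_k_recovered_on_most_replicates(self):
        """BIC finds the planted class count on a clearly separated cohort."""
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            X, _ = planted_matrix(
                800, seed=300 + rep, block_p=0.7, background_p=0.05, n_classes=3
            )
            models = {
                k: lca_fit(X, k, n_starts=2, seed=rep) for k in (2, 3, 4, 5)
            }
            hits += bic_select(models) == 3
        assert hits >= 0.8 * n_rep


class TestAggregateAndSelect:
    def test_identical_reports_have_zero_sd(self):
        agg = aggregate_repeats([make_report()] * 5)
        assert agg.ch_sd == 0.0 and agg.aggregated_as == "mean_sd"

    def test_sample_sd_uses_n_minus_1(self):
        agg = aggregate_repeats([make_report(ch=10.0), make_report(ch=20.0)])
        assert agg.calinski_harabasz == 15.0
        assert agg.ch_sd == pytest.approx(7.0710678, abs=1e-6)

    def test_single_report_passes_through(self):
        agg = aggregate_repeats([make_report()])
        assert agg.aggregated_as == "single" and agg.ch_sd is None

    def test_mixed_methods_error(self):
        with pytest.raises(ValueError, match="mixed"):
            aggregate_repeats([make_report("kmodes"), make_report("lca")])

    def test_single_candidate_selected(self):
        result = select_best([make_report(seed=3)])
        assert result.chosen_method == "kmodes" and result.chosen_seed == 3

    def test_highest_ch_run_chosen_within_method(self):
        reports = [
            make_report(ch=c, seed=s)
            for s, c in enumerate([6079.0, 5000.0, 4800.0, 5500.0, 5900.0])
        ]
        result = select_best(reports)
        assert result.chosen_seed == 0
        assert result.rationale["chosen_run_calinski_harabasz"] == 6079.0

    def test_singleton_pathology_is_flagged_not_vetoed(self):
        pathological = make_report(
            ch=100.0, db=0.1, sil=0.9, n_singleton_clusters=3, min_cluster_size=1
        )
        weak = make_report("lca", ch=10.0, db=2.0, sil=0.1)
        result = select_best([pathological, weak])
        assert result.chosen_method == "kmodes"
        assert any("singleton" in c for c in result.rationale["singleton_caveats"])

    def test_better_metrics_win_the_method_comparison(self):
        good = [make_report("kmodes", ch=100.0, db=0.5, sil=0.5, seed=s) for s in range(3)]
        bad = [make_report("ahc", ch=10.0, db=3.0, sil=0.05, seed=None)]
        assert select_best(good + bad).chosen_method == "kmodes"


class TestEvaluateModel:
    def test_report_fields_consistent_with_partition(self):
        X, truth = planted_matrix(400, seed=21)
        model = kmodes_fit(X, 4, init="cao")
        report = evaluate_model(X, model)
        sizes = cluster_size_summary(model.labels)
        assert report.n_singleton_clusters == sizes["n_singleton_clusters"]
        assert report.min_cluster_size <= report.median_cluster_size
        assert -1 <= report.silhouette <= 1

    def test_planted_truth_ch_peaks_at_true_k(self):
        """Calinski-Harabasz at the planted k exceeds its value at k=2 and the
        recovered partition matches the planted one."""
        X, truth = planted_matrix(1000, seed=22)
        m_true = kmodes_fit(X, 4, init="cao")
        m_under = kmodes_fit(X, 2, init="cao")
        assert calinski_harabasz(X, m_true.labels) > calinski_harabasz(
            X, m_under.labels
        )
        assert adjusted_rand_score(truth, m_true.labels) >= 0.9
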