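"""Clustering methods against exhaustive, closed-form and naive oracles."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from mmclust.clustering import (
    ClusteringError,
    ConditionMatrix,
    ahc_fit,
    kmedoids_fit,
    kmodes_cost,
    kmodes_fit,
    lca_fit,
    matching_dissimilarity,
    pairwise_matching,
    run_repeats,
)

from conftest import planted_matrix, random_condition_matrix


def as_cm(rows):
    X = np.asarray(rows, dtype=np.int8)
    return ConditionMatrix(
        X, [f"c{j}" for j in range(X.shape[1])], [f"P{i}" for i in range(X.shape[0])]
    )


class TestMatchingDissimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 1, 1), (0, 1, 1), 0),
            ((0, 0, 0), (1, 1, 1), 3),
            ((1, 0, 1, 0), (1, 1, 0, 0), 2),
        ],
    )
    def test_counts_mismatches(self, a, b, expected):
        assert matching_dissimilarity(a, b) == expected

    def test_symmetry_and_identity(self, rng):
        a = rng.integers(0, 2, 12)
        b = rng.integers(0, 2, 12)
        assert matching_dissimilarity(a, b) == matching_dissimilarity(b, a)
        assert matching_dissimilarity(a, a) == 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ClusteringError):
            matching_dissimilarity([0, 1], [0, 1, 1])

    def test_pairwise_blocks_equal_full_matrix(self, rng):
        X = rng.integers(0, 2, (37, 9)).astype(np.int8)
        full = pairwise_matching(X, block_size=4096)
        blocked = pairwise_matching(X, block_size=8)
        assert np.array_equal(full, blocked)
        assert np.array_equal(full, (squareform(pdist(X, "hamming")) * 9).round())


class TestConditionMatrix:
    def test_rejects_non_binary_and_zero_rows(self):
        with pytest.raises(ClusteringError):
            as_cm([[0, 2], [1, 0]])
        with pytest.raises(ClusteringError, match="at least one condition"):
            as_cm([[0, 0], [1, 0]])


class TestKModes:
    def test_separable_patterns_reach_zero_cost(self):
        X = as_cm([[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 4)
        model = kmodes_fit(X, 2)
        assert model.objective == 0.0
        labels = model.labels
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_k1_mode_is_column_majority(self, rng):
        X = random_condition_matrix(rng, 25, 6)
        model = kmodes_fit(X, 1)
        counts = X.values.sum(axis=0)
        majority = (2 * counts > X.n_persons).astype(int)  # ties resolve to 0
        assert np.array_equal(model.centers["modes"][0], majority)
        assert model.objective == float((X.values != majority).sum())

    def test_exhaustive_two_partition_optimum_n8(self, rng):
        """Initialised at the optimal partition's modes, k-modes keeps the
        globally optimal cost found by enumerating all 2-partitions of 8 rows."""
        for seed in range(3):
            local = np.random.default_rng(seed)
            X = random_condition_matrix(local, 8, 4)
            best_cost, best_labels = np.inf, None
            for mask in range(1, 2**7):  # fix row 0 in part 0; skip empty part
                labels = np.array([0] + [(mask >> i) & 1 for i in range(7)])
                cost = kmodes_cost(X, labels, 2)
                if cost < best_cost:
                    best_cost, best_labels = cost, labels
            modes = np.stack(
                [
                    (2 * X.values[best_labels == j].sum(0) > (best_labels == j).sum())
                    for j in range(2)
                ]
            ).astype(np.int8)
            model = kmodes_fit(X, 2, init_modes=modes)
            assert model.objective == best_cost

    def test_cost_trace_non_increasing(self, rng):
        for seed in range(5):
            X = random_condition_matrix(np.random.default_rng(seed), 60, 10)
            model = kmodes_fit(X, 4, init="random", seed=seed)
            trace = model.objective_trace
            assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_column_permutation_permutes_modes_not_labels(self, rng):
        X = random_condition_matrix(rng, 40, 8)
        perm = np.random.default_rng(0).permutation(8)
        Xp = ConditionMatrix(
            X.values[:, perm], [X.condition_names[j] for j in perm], X.person_ids
        )
        a = kmodes_fit(X, 3, init="random", seed=5)
        b = kmodes_fit(Xp, 3, init_modes=a.centers["modes"][:, perm])
        assert adjusted_rand_score(a.labels, b.labels) == 1.0
        assert a.objective == b.objective

    def test_k_out_of_range_errors(self, small_matrix):
        with pytest.raises(ClusteringError):
            kmodes_fit(small_matrix, 0)
        with pytest.raises(ClusteringError):
            kmodes_fit(small_matrix, small_matrix.n_persons + 1)


class TestKMedoids:
    def test_duplicate_rows_reach_zero_cost(self):
        X = as_cm([[1, 0, 0]] * 3 + [[0, 1, 0]] * 3 + [[0, 0, 1]] * 3)
        model = kmedoids_fit(X, 3)
        assert model.objective == 0.0

    def test_k_equals_n_gives_singletons(self, rng):
        X = random_condition_matrix(rng, 7, 5)
        model = kmedoids_fit(X, 7)
        assert model.objective == 0.0
        assert len(set(model.labels.tolist())) == 7
        assert (model.cluster_sizes() == 1).all()

    def test_exhaustive_medoid_pair_optimum_n10(self):
        """The swap phase reaches the global PAM optimum over all medoid pairs."""
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X = random_condition_matrix(rng, 10, 5)
            D = pairwise_matching(X.values)
            best = min(
                D[:, list(pair)].min(axis=1).sum()
                for pair in itertools.combinations(range(10), 2)
            )
            model = kmedoids_fit(X, 2)
            assert model.objective == float(best)
            # starting from the optimum it must also stay there
            opt_pair = min(
                itertools.combinations(range(10), 2),
                key=lambda pair: D[:, list(pair)].min(axis=1).sum(),
            )
            again = kmedoids_fit(X, 2, init_medoids=opt_pair)
            assert again.objective == float(best)

    def test_cost_trace_non_increasing(self, rng):
        X = random_condition_matrix(rng, 50, 8)
        model = kmedoids_fit(X, 5)
        trace = model.objective_trace
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_medoids_are_actual_persons(self, rng):
        X = random_condition_matrix(rng, 30, 6)
        model = kmedoids_fit(X, 4)
        for idx in model.centers["medoid_indices"]:
            assert 0 <= idx < 30


class TestLCA:
    def test_k1_matches_closed_form(self, rng):
        X = random_condition_matrix(rng, 40, 6)
        model = lca_fit(X, 1, seed=0)
        counts = X.values.sum(axis=0)
        n = X.n_persons
        p_hat = np.clip(counts / n, 1e-6, 1 - 1e-6)
        closed = float(
            (counts * np.log(p_hat) + (n - counts) * np.log(1 - p_hat)).sum()
        )
        assert model.objective == pytest.approx(closed, abs=1e-9)
        assert np.allclose(model.centers["item_probs"][0], p_hat)

    def test_well_separated_classes_recovered(self):
        rng = np.random.default_rng(42)
        truth = rng.integers(0, 2, 1000)
        probs = np.where(truth[:, None] == 0, 0.9, 0.1)
        draws = (rng.random((1000, 10)) < probs).astype(np.int8)
        for i in np.flatnonzero(draws.sum(axis=1) == 0):
            draws[i, rng.integers(10)] = 1
        X = as_cm(draws)
        model = lca_fit(X, 2, seed=1)
        agreement = max(
            (model.labels == truth).mean(), (model.labels != truth).mean()
        )
        assert agreement >= 0.99

    def test_loglik_trace_non_decreasing(self, rng):
        for seed in range(5):
            X = random_condition_matrix(np.random.default_rng(seed), 80, 8)
            model = lca_fit(X, 3, n_starts=1, seed=seed)
            trace = model.objective_trace
            assert all(b >= a - 1e-7 for a, b in zip(trace, trace[1:]))

    def test_item_probs_stay_clamped(self):
        X = as_cm([[1, 1]] * 10 + [[1, 0]] * 2)
        model = lca_fit(X, 2, seed=0)
        theta = model.centers["item_probs"]
        assert (theta >= 1e-6).all() and (theta <= 1 - 1e-6).all()

    def test_bic_formula(self, rng):
        X = random_condition_matrix(rng, 60, 7)
        model = lca_fit(X, 3, seed=0)
        n_free = (3 - 1) + 3 * 7
        assert model.bic == pytest.approx(
            -2 * model.objective + n_free * np.log(60), rel=1e-12
        )


class TestAHC:
    def test_identical_pairs_merge_first(self):
        X = as_cm([[1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0], [0, 1, 1, 0]])
        model = ahc_fit(X, 2)
        assert model.labels[0] == model.labels[1]
        assert model.labels[2] == model.labels[3]
        assert model.labels[0] != model.labels[2]

    def test_k_equals_n_gives_singletons(self, rng):
        X = random_condition_matrix(rng, 6, 4)
        model = ahc_fit(X, 6)
        assert len(set(model.labels.tolist())) == 6

    def test_matches_naive_average_linkage_n12(self):
        """Flat cuts agree with a brute-force agglomeration that recomputes all
        pairwise average cluster distances at each merge step."""
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            X = random_condition_matrix(rng, 12, 6)
            D = pairwise_matching(X.values).astype(float)
            clusters = [[i] for i in range(12)]
            snapshots = {}
            while len(clusters) > 1:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        d = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
                        if best is None or d < best[0]:
                            best = (d, i, j)
                _, i, j = best
                clusters[i] = clusters[i] + clusters[j]
                del clusters[j]
                labels = np.empty(12, dtype=int)
                for lab, members in enumerate(clusters):
                    labels[members] = lab
                snapshots[len(clusters)] = labels
            for k in (2, 3, 5):
                model = ahc_fit(X, k)
                assert adjusted_rand_score(model.labels, snapshots[k]) == 1.0

    def test_unknown_linkage_errors(self, small_matrix):
        with pytest.raises(ClusteringError, match="linkage"):
            ahc_fit(small_matrix, 2, linkage_method="single_file")


class TestRunRepeats:
    def test_stochastic_methods_give_one_model_per_seed(self, small_matrix):
        models = run_repeats("kmodes", small_matrix, 3, seeds=[1, 2, 3, 4, 5])
        assert len(models) == 5
        assert [m.seed for m in models] == [1, 2, 3, 4, 5]

    def test_deterministic_methods_run_once(self, small_matrix, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="mmclust.clustering"):
            models = run_repeats("ahc", small_matrix, 3, n_repeats=5)
        assert len(models) == 1
        assert any("deterministic" in r.message for r in caplog.records)

    def test_identical_seeds_give_identical_models(self, small_matrix):
        a, b = run_repeats("lca", small_matrix, 2, seeds=[9]), run_repeats(
            "lca", small_matrix, 2, seeds=[9]
        )
        assert a[0].objective == b[0].objective
        assert np.array_equal(a[0].labels, b[0].labels)


class TestPlantedRecovery:
    def test_all_methods_recover_separated_blocks(self):
        """With block probability 0.8 vs background 0.05 (separation 0.75),
        every method at the true k recovers the planted classes (ARI >= 0.9)."""
        X, truth = planted_matrix(2000, seed=11, block_p=0.8, background_p=0.05)
        for model in (
            kmodes_fit(X, 4, init="cao"),
            kmedoids_fit(X, 4),
            lca_fit(X, 4, seed=0),
            ahc_fit(X, 4),
        ):
            assert adjusted_rand_score(truth, model.labels) >= 0.9, model.method
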