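"""Annealed clustering, consensus summaries and outlier pruning."""

import numpy as np
import pytest

from burstkit.sabec import (ConsensusMatrix, assignment_probabilities,
                            cluster_log_likelihood, consensus_matrix,
                            consensus_partition, corrected_rand, pac_score,
                            prune_outliers, sabec_consensus,
                            sabec_single_run, variation_of_information)
from burstkit.synthetic import sample_stationary_counts


def two_population_data(seed, n=60, genes=3):
    """Well-separated bimodal vs burst-like populations."""
    a = np.column_stack([
        sample_stationary_counts((0.5, 0.5, 100), n, 7000 + seed * 10 + i)
        for i in range(genes)])
    b = np.column_stack([
        sample_stationary_counts((4.0, 1.0, 20), n, 9000 + seed * 10 + i)
        for i in range(genes)])
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestAssignmentProbabilities:
    def test_symmetry(self):
        assert np.allclose(assignment_probabilities([-10, -10], 10, 0),
                           [0.5, 0.5])

    def test_unit_gap_softmax(self):
        p = assignment_probabilities([-10, -11], 10, 0)
        e = np.e
        assert np.allclose(p, [e / (e + 1), 1 / (e + 1)], atol=1e-12)

    def test_annealing_hardens_assignment(self):
        p = assignment_probabilities([-10, -11], 10, 3)
        assert p[0] >= 1 - 1e-12
        assert p[1] <= 1e-12

    def test_sharpens_monotonically(self):
        probs = [assignment_probabilities([-10, -10.2, -11], 4, t)[0]
                 for t in range(4)]
        assert np.all(np.diff(probs) > 0)

    def test_degenerate_input(self):
        with pytest.warns(UserWarning):
            p = assignment_probabilities([-np.inf, -np.inf], 10, 0)
        assert np.allclose(p, [0.5, 0.5])
        with pytest.raises(ValueError):
            assignment_probabilities([-1.0], 10, 0)
        with pytest.raises(ValueError):
            assignment_probabilities([-1, -2], 0.5, 0)


class TestClusterLogLikelihood:
    def test_additive_over_genes(self, small_table):
        cell = [3, 40, 0]
        params = [(1.0, 1.0, 20.0), (0.5, 0.5, 50.0), (2.0, 4.0, 5.0)]
        total = cluster_log_likelihood(cell, params, small_table)
        parts = [cluster_log_likelihood([c], [p], small_table)
                 for c, p in zip(cell, params)]
        assert total == pytest.approx(sum(parts), rel=1e-12)

    def test_equals_table_lookup(self, small_table):
        val = cluster_log_likelihood([7], [(1.0, 2.0, 50.0)], small_table)
        r = small_table.row_for_params((1, 2, 50))
        assert val == small_table.log_pmf[r, 7]

    def test_gene_mismatch_rejected(self, small_table):
        with pytest.raises(ValueError):
            cluster_log_likelihood([1, 2], [(1, 1, 5)], small_table)


class TestConsensus:
    def test_identical_runs_give_binary_matrix(self):
        run = np.array([0, 0, 1, 1, 2])
        cm = consensus_matrix([run] * 50)
        assert cm.n_runs == 50
        assert set(np.unique(cm.co_count)) <= {0, 50}
        assert np.array_equal(np.diag(cm.co_count), [50] * 5)
        assert np.array_equal(cm.co_count, cm.co_count.T)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(5)
        runs = [rng.integers(0, 3, 12) for _ in range(7)]
        cm = consensus_matrix(runs)
        for i in range(12):
            for j in range(12):
                brute = sum(r[i] == r[j] for r in runs)
                assert cm.co_count[i, j] == brute

    def test_pac_extremes(self):
        stable = consensus_matrix([np.array([0, 0, 1, 1])] * 10)
        assert pac_score(stable) == 0.0
        co = np.full((4, 4), 5)
        np.fill_diagonal(co, 10)
        assert pac_score(ConsensusMatrix(co, 10)) == 1.0

    def test_pac_matches_brute_force(self):
        rng = np.random.default_rng(6)
        runs = [rng.integers(0, 2, 10) for _ in range(20)]
        cm = consensus_matrix(runs)
        freq = cm.frequency
        brute = np.mean([0.1 < freq[i, j] < 0.9
                         for i in range(10) for j in range(i + 1, 10)])
        assert pac_score(cm) == pytest.approx(brute)


class TestPartitionMetrics:
    def test_vi_identical_is_zero(self):
        a = np.array([0, 0, 1, 1, 2])
        assert variation_of_information(a, a) == 0.0

    def test_vi_balanced_split_vs_single_cluster(self):
        a = np.repeat([0, 1], 50)
        b = np.zeros(100, dtype=int)
        assert variation_of_information(a, b) == pytest.approx(np.log(2),
                                                               abs=1e-12)

    def test_vi_symmetric(self):
        rng = np.random.default_rng(7)
        a, b = rng.integers(0, 4, 50), rng.integers(0, 3, 50)
        assert variation_of_information(a, b) == pytest.approx(
            variation_of_information(b, a))

    def test_rand_identical_is_one(self):
        a = np.array([0, 1, 0, 1, 2])
        assert corrected_rand(a, a) == 1.0

    def test_rand_is_chance_corrected(self):
        rng = np.random.default_rng(8)
        vals = [corrected_rand(rng.integers(0, 5, 1000),
                               rng.integers(0, 5, 1000))
                for _ in range(100)]
        assert abs(np.mean(vals)) < 0.02


class TestConsensusPartition:
    def test_recovers_perfect_blocks(self):
        labels = np.repeat([0, 1], 10)
        cm = consensus_matrix([labels] * 20)
        part = consensus_partition(cm, 2)
        assert corrected_rand(part, labels) == 1.0

    def test_k_equal_n_is_singletons(self):
        cm = consensus_matrix([np.array([0, 1, 0, 1])] * 3)
        assert len(set(consensus_partition(cm, 4))) == 4

    def test_beats_random_partitions(self):
        rng = np.random.default_rng(9)
        runs = [rng.integers(0, 3, 30) for _ in range(15)]
        cm = consensus_matrix(runs)
        d = 1.0 - cm.frequency

        def cost(lab):
            tot = 0.0
            for k in np.unique(lab):
                members = np.flatnonzero(lab == k)
                within = d[np.ix_(members, members)].sum(axis=1)
                tot += within.min()
            return tot

        ours = cost(consensus_partition(cm, 3))
        rand_costs = [cost(rng.integers(0, 3, 30)) for _ in range(100)]
        assert ours <= min(rand_costs)


class TestSabecRuns:
    def test_k1_is_trivial(self, small_table):
        X = np.zeros((10, 2), dtype=int)
        labels = sabec_single_run(X, 1, small_table, seed=0)
        assert np.array_equal(labels, np.zeros(10))

    def test_consensus_recovers_two_populations(self, clust_table):
        hits = 0
        for s in range(10):
            X, y = two_population_data(s)
            res = sabec_consensus(X, 2, clust_table, n_runs=25, seed=100 * s)
            if corrected_rand(res["partition"], y) >= 0.8:
                hits += 1
        assert hits >= 9

    def test_single_runs_usually_separate(self, clust_table):
        aris = []
        for s in range(10):
            X, y = two_population_data(s)
            aris.append(corrected_rand(
                sabec_single_run(X, 2, clust_table, seed=s), y))
        assert np.median(aris) >= 0.8

    def test_annealing_speeds_convergence(self, clust_table):
        # hotter annealing schedules harden the assignment sooner
        from burstkit.sabec import _cell_cluster_logL  # noqa: F401
        X, y = two_population_data(3)
        iters = {}
        for tau in (2.0, 10.0):
            counts = []
            for s in range(5):
                n_iter = _count_iterations(X, clust_table, tau, seed=s)
                counts.append(n_iter)
            iters[tau] = np.mean(counts)
        assert iters[10.0] <= iters[2.0]


def _count_iterations(X, table, tau, seed, K=2, swap_tol=0.05,
                      max_iter=100):
    """Instrumented copy of the annealed loop that reports iterations."""
    from burstkit.estimation import ml_estimate_many
    from burstkit.sabec import _cell_cluster_logL, _cluster_gene_histograms, \
        _repair_empty

    counts = np.minimum(np.asarray(X, dtype=np.int64), table.grid.x_max)
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=len(counts))
    for t in range(max_iter):
        labels = _repair_empty(counts, labels, K, table)
        hists = _cluster_gene_histograms(counts, labels, K, table.grid.x_max)
        rows = ml_estimate_many(hists, table).reshape(K, counts.shape[1])
        L = _cell_cluster_logL(counts, rows, table)
        z = (tau ** t) * (L - L.max(axis=1, keepdims=True))
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((len(counts), 1))
        new = (p.cumsum(axis=1) < u).sum(axis=1)
        swapped = np.mean(new != labels)
        labels = new
        if swapped < swap_tol:
            return t + 1
    return max_iter


class TestPruneOutliers:
    def test_cohesive_cells_not_pruned(self):
        labels = np.repeat([0, 1], 5)
        cm = consensus_matrix([labels] * 10)
        kept, match = prune_outliers(cm, labels)
        assert kept.all()
        assert np.allclose(match, 1.0)

    def test_detached_cell_is_pruned(self):
        labels = np.repeat([0, 1], 5)
        runs = []
        for r in range(10):
            run = labels.copy()
            run[0] = 2  # cell 0 never co-clusters with its own label
            runs.append(run)
        kept, match = prune_outliers(consensus_matrix(runs), labels)
        assert not kept[0]
        assert kept[1:].all()
        assert match[0] == 0.0

    def test_singleton_class_warns(self):
        labels = np.array([0, 1, 1])
        cm = consensus_matrix([labels] * 5)
        with pytest.warns(UserWarning, match="size 1"):
            kept, match = prune_outliers(cm, labels)
        assert match[0] == 0.0

    def test_planted_mislabeled_cells_fall_below_threshold(self, clust_table):
        # mislabelled cells co-cluster with the wrong reference class
        rng = np.random.default_rng(11)
        X, y = two_population_data(21, n=40)
        facs = y.copy()
        planted = np.r_[rng.choice(40, 4, replace=False),
                        40 + rng.choice(40, 4, replace=False)]
        facs[planted] = 1 - facs[planted]  # wrong reference label
        runs = [sabec_single_run(X, 2, clust_table, seed=s)
                for s in range(25)]
        kept, match = prune_outliers(consensus_matrix(runs), facs)
        assert np.mean(~kept[planted]) >= 0.7
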