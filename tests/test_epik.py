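"""Differential kinetic-parameter calling (BIC, MP, subsampling KS)."""

import math

import numpy as np
import pandas as pd
import pytest

from burstkit.epik import (EpikThresholds, SCENARIOS, bic_select,
                           epik_combine, epik_test_pair,
                           expressed_cell_filter, marginal_probability,
                           subsample_ks)
from burstkit.estimation import counts_histogram, log_likelihood_surface
from burstkit.synthetic import apply_capture, sample_stationary_counts


def brute_force_scenario_likelihood(counts_a, counts_b, table, scenario):
    """Independent maximisation over the constrained grid product."""
    axis = {"k_on": 0, "k_off": 1, "k_t": 2}
    free = [axis[p] for p in scenario]
    La = table.surface_3d(log_likelihood_surface(
        counts_histogram(counts_a, table.grid.x_max), table))
    Lb = table.surface_3d(log_likelihood_surface(
        counts_histogram(counts_b, table.grid.x_max), table))
    best = -np.inf
    shape = table.grid.shape
    for ia in np.ndindex(shape):
        for ib in np.ndindex(shape):
            # shared axes must agree between the two populations
            if any(ia[d] != ib[d] for d in range(3) if d not in free):
                continue
            best = max(best, La[ia] + Lb[ib])
    return best


class TestBicSelect:
    def test_identical_data_selects_no_change(self, small_table):
        c = sample_stationary_counts((1, 1, 50), 60, seed=1)
        best, scores = bic_select(c, c, small_table)
        assert best == frozenset()
        # penalty is the only thing separating nested scenarios here
        assert scores[frozenset()] < scores[frozenset({"k_on"})]

    def test_scores_match_printed_formula_and_brute_force(self, small_table):
        rng = np.random.default_rng(2)
        a = sample_stationary_counts((1.0, 1.0, 50), 25, rng)
        b = sample_stationary_counts((2.0, 1.0, 20), 25, rng)
        _, scores = bic_select(a, b, small_table)
        n_total = 50
        for scen in (frozenset(), frozenset({"k_t"}),
                     frozenset({"k_on", "k_t"}),
                     frozenset({"k_on", "k_off", "k_t"})):
            L = brute_force_scenario_likelihood(a, b, small_table, scen)
            expected = len(scen) * (math.log(n_total)
                                    - math.log(2 * math.pi)) - 2 * L
            assert scores[scen] == pytest.approx(expected, rel=1e-12)

    def test_standard_bic_changes_penalty_only(self, small_table):
        c = sample_stationary_counts((1, 1, 50), 40, seed=3)
        _, verbatim = bic_select(c, c, small_table)
        _, textbook = bic_select(c, c, small_table, standard=True)
        assert verbatim[frozenset()] == textbook[frozenset()]
        gap = textbook[frozenset({"k_on"})] - verbatim[frozenset({"k_on"})]
        assert gap == pytest.approx(math.log(2 * math.pi), rel=1e-9)

    def test_detects_kon_shift_in_majority_of_seeds(self, bench_table):
        hits = 0
        for s in range(8):
            rng = np.random.default_rng(50 + s)
            a = apply_capture(sample_stationary_counts((0.5, 2.0, 80), 124,
                                                       rng), 0.1, rng)
            b = apply_capture(sample_stationary_counts((3.0, 2.0, 80), 124,
                                                       rng), 0.1, rng)
            best, _ = bic_select(a, b, bench_table)
            hits += best == frozenset({"k_on"})
        assert hits >= 5


class TestMarginalProbability:
    def test_identical_concentrated_posterior_scores_near_zero(
            self, bench_table):
        # enough cells that the posterior concentrates on one grid triple
        c = sample_stationary_counts((1.1, 2.0, 50), 3000, seed=4)
        for p in ("k_on", "k_off", "k_t"):
            assert marginal_probability(c, c, bench_table, p) > -0.1

    def test_always_nonpositive(self, small_table):
        rng = np.random.default_rng(5)
        for s in range(5):
            a = rng.poisson(rng.uniform(1, 40), 30)
            b = rng.poisson(rng.uniform(1, 40), 30)
            for p in ("k_on", "k_off", "k_t"):
                assert marginal_probability(a, b, small_table, p) <= 0.0

    def test_disjoint_marginals_score_very_negative(self, bench_table):
        a = sample_stationary_counts((1, 1, 20), 300, seed=6)
        b = sample_stationary_counts((1, 1, 180), 300, seed=7)
        assert marginal_probability(a, b, bench_table, "k_t") < -20

    def test_unknown_parameter_rejected(self, small_table):
        with pytest.raises(ValueError):
            marginal_probability([1], [1], small_table, "k_d")


class TestSubsampleKS:
    def test_null_statistic_is_small(self, bench_table):
        # same cells on both sides: only subsampling noise remains
        ok = 0
        for s in range(5):
            pop = sample_stationary_counts((1.1, 2.0, 50), 124, seed=60 + s)
            ks = subsample_ks(pop, pop, bench_table, seed=s)
            ok += all(v < 0.25 for v in ks.values())
        assert ok >= 4

    def test_separated_kt_saturates_statistic(self, bench_table):
        a = sample_stationary_counts((1, 1, 40), 124, seed=8)
        b = sample_stationary_counts((1, 1, 160), 124, seed=9)
        ks = subsample_ks(a, b, bench_table, seed=10)
        assert ks["k_t"] >= 0.9

    def test_too_small_subsample_rejected(self, small_table):
        with pytest.raises(ValueError, match="frac"):
            subsample_ks(np.ones(20, dtype=int), np.ones(20, dtype=int),
                         small_table, frac=0.25)


class TestExpressedCellFilter:
    def test_ten_cell_rule(self):
        counts = pd.DataFrame({
            "ok": np.r_[np.ones(12, int), np.ones(12, int)],
            "rare_in_a": np.r_[np.ones(9, int), np.zeros(3, int),
                               np.ones(12, int)],
            "silent": np.zeros(24, int),
        })
        labels = np.repeat(["a", "b"], 12)
        mask = expressed_cell_filter(counts, labels)
        assert mask.loc["a", "ok"] and mask.loc["b", "ok"]
        assert not mask.loc["a", "rare_in_a"]
        assert mask.loc["b", "rare_in_a"]
        assert not mask.loc["a", "silent"]


class TestEpikCombine:
    def test_thresholding_and_set_algebra(self):
        th = EpikThresholds()
        call = epik_combine(
            bic_set=frozenset({"k_on"}),
            mp={"k_on": -7.0, "k_off": -1.0, "k_t": -7.5},
            ks={"k_on": 0.80, "k_off": 0.2, "k_t": 0.80},
            thresholds=th, koff_estimate=2.0, mean_diff=3.0)
        assert call.regime == "low"
        assert call.mp_flags == frozenset({"k_on", "k_t"})  # -7 < -6.3
        assert call.ks_flags == frozenset({"k_on"})  # 0.80 > 0.77, not 0.86
        assert call.intersection == frozenset({"k_on"})
        assert call.union_mp_ks == frozenset({"k_on", "k_t"})
        assert call.direction == 1

    def test_high_regime_never_calls_koff(self):
        call = epik_combine(
            bic_set=frozenset({"k_off"}),
            mp={"k_on": -1.0, "k_off": -99.0, "k_t": -1.0},
            ks={"k_on": 0.1, "k_off": 1.0, "k_t": 0.1},
            koff_estimate=8.0)
        assert call.regime == "high"
        assert "k_off" not in call.mp_flags | call.ks_flags | call.bic_flags
        assert call.intersection == frozenset()

    def test_scenario_table_is_complete(self):
        assert len(SCENARIOS) == 8
        sizes = sorted(len(s) for s in SCENARIOS)
        assert sizes == [0, 1, 1, 1, 2, 2, 2, 3]


class TestEpikTestPair:
    def test_low_expression_is_not_testable(self, small_table):
        a = np.r_[np.ones(5, int), np.zeros(119, int)]
        b = np.ones(124, int)
        call = epik_test_pair(a, b, small_table)
        assert not call.testable

    def test_null_pair_yields_no_intersection_call(self, bench_table):
        rng = np.random.default_rng(70)
        a = apply_capture(sample_stationary_counts((1.0, 2.0, 300), 124,
                                                   rng), 0.1, rng)
        b = apply_capture(sample_stationary_counts((1.0, 2.0, 300), 124,
                                                   rng), 0.1, rng)
        call = epik_test_pair(a, b, bench_table, seed=71)
        assert call.testable
        assert call.intersection == frozenset()

    def test_subsample_fraction_barely_moves_ks_ranking(self, bench_table):
        # doubling the subsample size must not change which pairs look
        # separated: AUC of the k_t statistic is stable
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(72)
        truths, ks25, ks50 = [], [], []
        for s in range(30):
            changed = s % 2 == 1
            kt_a = rng.uniform(50, 550)
            kt_b = rng.uniform(50, 550) if changed else kt_a
            kon, koff = rng.uniform(0.3, 5), rng.uniform(0.4, 5)
            a = apply_capture(sample_stationary_counts((kon, koff, kt_a),
                                                       124, rng), 0.1, rng)
            b = apply_capture(sample_stationary_counts((kon, koff, kt_b),
                                                       124, rng), 0.1, rng)
            truths.append(changed)
            ks25.append(subsample_ks(a, b, bench_table, frac=0.25,
                                     seed=200 + s)["k_t"])
            ks50.append(subsample_ks(a, b, bench_table, frac=0.5,
                                     seed=300 + s)["k_t"])
        auc25 = roc_auc_score(truths, ks25)
        auc50 = roc_auc_score(truths, ks50)
        assert abs(auc25 - auc50) < 0.05
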