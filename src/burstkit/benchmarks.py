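"""In-silico benchmark drivers for the three analysis stages.

These reproduce, at configurable scale, the validation layout the package
is built around: parameter recovery under 90% transcript loss (design A),
clustering recovery of a five-population structure (design B), and
calibration of the differential-kinetics calls on paired populations
(design C).  The same drivers back the test suite and the reproduction
script, so reported numbers always come from an end-to-end run of the
package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .epik import PARAMS, EpikThresholds, epik_test_pair
from .estimation import ml_estimate_many
from .model_core import GridSpec, LookupTable, build_lookup_table
from .sabec import (consensus_matrix, corrected_rand, consensus_partition,
                    pac_score, sabec_single_run)
from .synthetic import generate_design_a, generate_design_b, \
    generate_design_c

__all__ = [
    "benchmark_grid",
    "clustering_grid",
    "recovery_benchmark",
    "recovery_stats",
    "sabec_benchmark",
    "design_c_benchmark",
    "design_c_summary",
]


def benchmark_grid(x_max: int = 200) -> GridSpec:
    """Reduced estimation grid for desk-scale benchmarks.

    Half the full density on the switching axes (k_on step 0.2, k_off
    step 0.8), full density on k_t (step 5): 25,000 triples.
    """
    return GridSpec(
        k_on_values=np.round(0.1 + 0.2 * np.arange(25), 10),
        k_off_values=np.round(0.4 + 0.8 * np.arange(25), 10),
        k_t_values=5.0 * np.arange(1, 41),
        x_max=x_max,
    )


def clustering_grid(x_max: int = 200) -> GridSpec:
    """Coarse grid for clustering benchmarks (3,640 triples).

    Cluster separation needs far less parameter resolution than point
    estimation, and the grid size sets the per-iteration cost of every
    SABEC restart.
    """
    return GridSpec(
        k_on_values=np.round(0.25 + 0.4 * np.arange(13), 10),
        k_off_values=np.round(0.5 + 1.5 * np.arange(14), 10),
        k_t_values=10.0 * np.arange(1, 21) - 5.0,
        x_max=x_max,
    )


# ---------------------------------------------------------------------------
# Design A: parameter recovery
# ---------------------------------------------------------------------------

def recovery_benchmark(table: LookupTable, n_sets: int = 200, seed: int = 0,
                       n_cells: int = 124,
                       capture_probability: float = 0.1) -> pd.DataFrame:
    """True vs estimated triples on thinned design-A populations.

    Estimates live on the captured-count scale (thinning rescales k_t by
    the capture probability and leaves k_on and k_off untouched), so
    recovery is judged by correlation, not identity.
    """
    sets = generate_design_a(n_sets=n_sets, seed=seed, n_cells=n_cells,
                             capture_probability=capture_probability)
    x_max = table.grid.x_max
    hists = np.zeros((n_sets, x_max + 1), dtype=np.int64)
    n_expr = np.zeros(n_sets, dtype=np.int64)
    for i, d in enumerate(sets):
        hists[i] = np.bincount(np.minimum(d["counts"], x_max),
                               minlength=x_max + 1)
        n_expr[i] = int(np.sum(d["counts"] > 0))
    rows = ml_estimate_many(hists, table)
    est = table.param_index[rows]
    true = np.array([d["params"].as_tuple() for d in sets])
    return pd.DataFrame({
        "true_k_on": true[:, 0], "true_k_off": true[:, 1],
        "true_k_t": true[:, 2],
        "est_k_on": est[:, 0], "est_k_off": est[:, 1], "est_k_t": est[:, 2],
        "n_expressing": n_expr,
    })


def recovery_stats(df: pd.DataFrame, koff_cut: float = 5.0,
                   min_expressing: int = 10) -> dict:
    """Pearson correlations of the recovery benchmark.

    Populations the estimator itself would refuse (< ``min_expressing``
    expressing cells) are excluded, as they would be on real data.
    ``r_log_ratio`` correlates ln(k_t/k_off): the quantity that stays
    identifiable in the fast-switching regime.  ``r_koff_high`` is the
    k_off correlation restricted to true k_off above ``koff_cut``, where
    k_off and k_t compensate and recovery degrades.
    """
    def r(x, y):
        return float(np.corrcoef(x, y)[0, 1])

    if "n_expressing" in df:
        df = df[df["n_expressing"] >= min_expressing]
    high = df["true_k_off"] > koff_cut
    return dict(
        r_k_on=r(df["true_k_on"], df["est_k_on"]),
        r_k_off=r(df["true_k_off"], df["est_k_off"]),
        r_k_t=r(df["true_k_t"], df["est_k_t"]),
        r_log_ratio=r(np.log(df["true_k_t"] / df["true_k_off"]),
                      np.log(df["est_k_t"] / df["est_k_off"])),
        r_koff_high=r(df.loc[high, "true_k_off"], df.loc[high, "est_k_off"]),
        n_high=int(high.sum()),
        n_kept=len(df),
    )


# ---------------------------------------------------------------------------
# Design B: clustering recovery
# ---------------------------------------------------------------------------

def sabec_benchmark(table: LookupTable, n_datasets: int = 20, seed: int = 0,
                    Ks=(4, 5, 7), true_k: int = 5, n_runs: int = 50,
                    tau: float = 10.0, n_cells: int = 124,
                    n_genes: int = 18) -> pd.DataFrame:
    """Consensus-clustering recovery on design-B datasets.

    For each dataset and each K: 50 annealed runs, consensus matrix, PAC,
    and (at each K) the corrected Rand index of the PAM consensus cut
    against the truth labels.  One row per (dataset, K).
    """
    datasets = generate_design_b(n_datasets=n_datasets, seed=seed,
                                 n_populations=true_k, n_cells=n_cells,
                                 n_genes=n_genes)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, d in enumerate(datasets):
            for K in Ks:
                runs = [
                    sabec_single_run(d["counts"], K, table, tau=tau,
                                     seed=(seed + 1) * 100_000 + idx * 1000
                                     + K * 100 + r)
                    for r in range(n_runs)
                ]
                cm = consensus_matrix(runs)
                part = consensus_partition(cm, K)
                records.append(dict(
                    dataset=idx, K=K, pac=pac_score(cm),
                    rand=corrected_rand(part, d["labels"]),
                ))
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Design C: differential-kinetics calibration
# ---------------------------------------------------------------------------

def design_c_benchmark(table: LookupTable, seed: int = 0,
                       n_null_per_regime: int = 200,
                       n_changed_per_scenario: int = 25,
                       reps: int = 100, frac: float = 0.25,
                       thresholds: EpikThresholds | None = None
                       ) -> pd.DataFrame:
    """Run the three-method test on paired-population datasets.

    Each k_off regime gets ``n_null_per_regime`` no-change datasets plus
    ``n_changed_per_scenario`` datasets for each of the seven change
    scenarios.  One row per (dataset, callable parameter) with truth and
    the per-method flags.
    """
    null = frozenset()
    records = []
    for regime_i, koff_range in enumerate(((0.0, 5.0), (5.0, 10.0))):
        datasets = generate_design_c(
            per_scenario=n_changed_per_scenario,
            seed=seed * 2 + regime_i,
            koff_range=koff_range,
            per_scenario_override={null: n_null_per_regime},
        )
        for j, d in enumerate(datasets):
            call = epik_test_pair(
                d["counts_a"], d["counts_b"], table,
                thresholds=thresholds, frac=frac, reps=reps,
                seed=((seed * 2 + regime_i) * 1_000_003 + j) % 2 ** 31,
            )
            if not call.testable:
                records.append(dict(regime_truth=("low", "high")[regime_i],
                                    scenario="+".join(sorted(d["scenario"])),
                                    param=None, testable=False,
                                    truth_changed=None, bic=None, mp=None,
                                    ks=None, intersection=None))
                continue
            callable_params = PARAMS if call.regime == "low" \
                else ("k_on", "k_t")
            for p in callable_params:
                records.append(dict(
                    regime_truth=("low", "high")[regime_i],
                    scenario="+".join(sorted(d["scenario"])),
                    param=p, testable=True,
                    truth_changed=p in d["scenario"],
                    change_mag=abs(getattr(d["params_b"], p)
                                   - getattr(d["params_a"], p)),
                    mp_value=call.mp[p], ks_value=call.ks[p],
                    bic=p in call.bic_flags,
                    mp=p in call.mp_flags,
                    ks=p in call.ks_flags,
                    intersection=p in call.intersection,
                ))
    return pd.DataFrame(records)


def design_c_summary(df: pd.DataFrame) -> dict:
    """False/true positive rates (%) from a design-C benchmark table."""
    t = df[df["testable"].eq(True)]
    neg = t[~t["truth_changed"].astype(bool)]
    pos = t[t["truth_changed"].astype(bool)]
    nulls = neg[neg["scenario"] == ""]

    def pct(mask):
        return 100.0 * float(np.mean(mask)) if len(mask) else float("nan")

    return dict(
        n_negatives=len(neg),
        n_nulls=len(nulls),
        n_positives=len(pos),
        fpr_intersection_pct=pct(neg["intersection"].astype(bool)),
        fpr_bic_pct=pct(neg["bic"].astype(bool)),
        fpr_mp_pct=pct(neg["mp"].astype(bool)),
        fpr_ks_pct=pct(neg["ks"].astype(bool)),
        null_fpr_mp_pct=pct(nulls["mp"].astype(bool)),
        null_fpr_ks_pct=pct(nulls["ks"].astype(bool)),
        tpr_intersection_pct=pct(pos["intersection"].astype(bool)),
        tpr_union_mp_ks_pct=pct((pos["mp"] | pos["ks"]).astype(bool)),
    )
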