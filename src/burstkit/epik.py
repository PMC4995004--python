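"""EPiK: Estimation of Parameter changes in Kinetics.

Decides, per gene and per pair of cell populations, which of the three
kinetic parameters (k_on, k_off, k_t) changed, by combining three
statistics computed on the shared lookup grid:

* BIC model selection over the eight change scenarios (subsets of the
  three parameters).  For a scenario the joint likelihood is maximised
  with the unchanged parameters shared between populations and the
  changed ones free; the score is N_i (log(2n) - log(2pi)) - 2 L_i with
  N_i the number of free parameters and 2n the total cell count (a
  ``standard=True`` switch gives textbook k ln n - 2 ln L instead).
* A marginal-probability (MP) score per parameter: the log overlap of the
  two populations' marginal posteriors over that parameter's grid axis
  (other axes marginalised by log-sum-exp).  Near 0 means the marginals
  agree; very negative means the parameter moved.
* A subsampling Kolmogorov–Smirnov statistic per parameter: 25% of each
  population is repeatedly resampled without replacement, each subsample
  is ML-fit, and the two resulting estimate distributions are compared by
  the maximum CDF distance.  Only the raw statistic is used — resampling
  invalidates the KS p-value.

MP and KS thresholds are the published values calibrated to a ~2% false
positive rate, with separate sets for the slow- (k_off < 5) and fast-
(k_off > 5) switching regimes; in the fast regime k_off and k_t compensate
for one another, so k_off is never called there.  The regime is chosen
from the pooled-data ML estimate of k_off (overridable).  A parameter is
called changed by the intersection only if all three methods flag it; the
union of MP and KS is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import ks_2samp

from .estimation import counts_histogram, log_likelihood_surface, \
    ml_estimate, ml_estimate_many, MIN_EXPRESSING_CELLS
from .model_core import LookupTable

__all__ = [
    "SCENARIOS",
    "PARAMS",
    "EpikThresholds",
    "EpikCall",
    "bic_select",
    "marginal_probability",
    "subsample_ks",
    "expressed_cell_filter",
    "epik_combine",
    "epik_test_pair",
]

PARAMS = ("k_on", "k_off", "k_t")
_AXIS = {"k_on": 0, "k_off": 1, "k_t": 2}

#: The eight change scenarios in canonical order: increasing number of
#: changed parameters, lexicographic within (this is also the BIC
#: tie-break order).
SCENARIOS: tuple[frozenset, ...] = (
    frozenset(),
    frozenset({"k_on"}), frozenset({"k_off"}), frozenset({"k_t"}),
    frozenset({"k_on", "k_off"}), frozenset({"k_on", "k_t"}),
    frozenset({"k_off", "k_t"}),
    frozenset({"k_on", "k_off", "k_t"}),
)


@dataclass(frozen=True)
class EpikThresholds:
    """Published decision thresholds, calibrated to ~2% false positives.

    ``mp_*`` are upper bounds (flag when MP falls below), ``ks_*`` lower
    bounds (flag when the KS statistic exceeds).  The fast-switching
    regime (k_off above ``koff_regime_cut``) has no k_off thresholds:
    k_off is unidentifiable there.
    """

    mp_low_koff: dict = field(default_factory=lambda: {
        "k_on": -6.3, "k_off": -8.5, "k_t": -6.8})
    mp_high_koff: dict = field(default_factory=lambda: {
        "k_on": -4.9, "k_t": -6.0})
    ks_low_koff: dict = field(default_factory=lambda: {
        "k_on": 0.77, "k_off": 0.91, "k_t": 0.86})
    ks_high_koff: dict = field(default_factory=lambda: {
        "k_on": 0.681, "k_t": 0.870})
    koff_regime_cut: float = 5.0


@dataclass
class EpikCall:
    """Per gene, per population pair: what each method flags, combined."""

    testable: bool
    regime: str | None = None  # "low" or "high"
    bic_set: frozenset = frozenset()
    mp: dict = field(default_factory=dict)
    ks: dict = field(default_factory=dict)
    mp_flags: frozenset = frozenset()
    ks_flags: frozenset = frozenset()
    bic_flags: frozenset = frozenset()
    intersection: frozenset = frozenset()
    union_mp_ks: frozenset = frozenset()
    direction: int = 0
    gene: str | None = None
    pair: tuple | None = None


def _surfaces(counts_a, counts_b, table: LookupTable):
    x_max = table.grid.x_max
    ha = counts_histogram(counts_a, x_max)
    hb = counts_histogram(counts_b, x_max)
    La = table.surface_3d(log_likelihood_surface(ha, table))
    Lb = table.surface_3d(log_likelihood_surface(hb, table))
    return La, Lb, ha.n_cells, hb.n_cells


def bic_select(counts_a, counts_b, table: LookupTable,
               standard: bool = False):
    """Scenario with the lowest BIC; ties go to fewer free parameters.

    For free set F, unchanged axes are shared between populations and the
    axes in F are maximised independently per population:
    L_F = max_shared [ (max_F L_a) + (max_F L_b) ].  The no-change and
    all-change scenarios are the two extreme cases.

    Returns (scenario frozenset, {scenario: BIC score}).
    """
    La, Lb, n_a, n_b = _surfaces(counts_a, counts_b, table)
    n_total = n_a + n_b
    if standard:
        penalty_unit = np.log(n_total)
    else:
        penalty_unit = np.log(n_total) - np.log(2.0 * np.pi)
    scores: dict[frozenset, float] = {}
    for scen in SCENARIOS:
        free = tuple(sorted(_AXIS[p] for p in scen))
        Am = La.max(axis=free) if free else La
        Bm = Lb.max(axis=free) if free else Lb
        L = float((Am + Bm).max())
        scores[scen] = len(scen) * penalty_unit - 2.0 * L
    best = min(SCENARIOS, key=lambda s: scores[s])  # stable: SCENARIOS order
    return best, scores


def marginal_probability(counts_a, counts_b, table: LookupTable,
                         param: str) -> float:
    """Log overlap of the two marginal posteriors over one parameter axis.

    Per population the likelihood surface is normalised by its total
    (log-sum-exp over the whole grid) and marginalised over the other two
    axes; the score is logsumexp_i(A'(i) + B'(i)) <= 0.
    """
    if param not in PARAMS:
        raise ValueError(f"param must be one of {PARAMS}")
    La, Lb, _, _ = _surfaces(counts_a, counts_b, table)
    axis = _AXIS[param]
    others = tuple(a for a in range(3) if a != axis)

    def marginal(L):
        m = logsumexp(L, axis=others)
        return m - logsumexp(m)

    mp = float(logsumexp(marginal(La) + marginal(Lb)))
    return min(mp, 0.0)


def subsample_ks(counts_a, counts_b, table: LookupTable, frac: float = 0.25,
                 reps: int = 100, seed: int = 0) -> dict:
    """Subsampling KS statistic per parameter.

    Each rep draws floor(frac * n) cells without replacement from each
    population and ML-fits the subsample; per parameter, the statistic is
    the maximum distance between the empirical CDFs of the two estimate
    collections.  No p-value is attached.
    """
    rng = np.random.default_rng(seed)
    x_max = table.grid.x_max
    ests = []
    for counts in (counts_a, counts_b):
        c = np.minimum(np.asarray(counts, dtype=np.int64), x_max)
        m = int(frac * c.size)
        if m < 10:
            raise ValueError(
                f"subsample size {m} < 10 cells; increase frac or supply "
                "more cells"
            )
        hists = np.zeros((reps, x_max + 1), dtype=np.int64)
        for r in range(reps):
            sub = rng.choice(c, size=m, replace=False)
            hists[r] = np.bincount(sub, minlength=x_max + 1)
        rows = ml_estimate_many(hists, table)
        ests.append(table.param_index[rows])
    est_a, est_b = ests
    return {
        p: float(ks_2samp(est_a[:, i], est_b[:, i], method="asymp").statistic)
        for i, p in enumerate(PARAMS)
    }


def expressed_cell_filter(counts: pd.DataFrame, labels,
                          min_cells: int = MIN_EXPRESSING_CELLS
                          ) -> pd.DataFrame:
    """Per (population, gene): is the gene expressed in >= min_cells cells?

    A gene is testable for a population pair iff the mask is True for
    both populations.
    """
    labels = np.asarray(labels)
    rows = {}
    for pop in pd.unique(labels):
        sub = counts.loc[labels == pop]
        rows[pop] = (sub > 0).sum(axis=0) >= min_cells
    return pd.DataFrame(rows).T


def epik_combine(bic_set: frozenset, mp: dict, ks: dict,
                 thresholds: EpikThresholds | None = None,
                 koff_estimate: float = 0.0,
                 mean_diff: float = 0.0) -> EpikCall:
    """Threshold the three methods and combine their calls.

    MP flags a parameter when its score is below the regime threshold, KS
    when the statistic is above; BIC flags the members of its selected
    scenario.  In the fast-switching regime k_off is never called by any
    method.  The intersection needs all three; the union of MP and KS is
    also reported.  ``mean_diff`` (mean expression of population b minus
    a) sets the direction sign.
    """
    th = thresholds or EpikThresholds()
    high = koff_estimate >= th.koff_regime_cut
    regime = "high" if high else "low"
    mp_th = th.mp_high_koff if high else th.mp_low_koff
    ks_th = th.ks_high_koff if high else th.ks_low_koff
    callable_params = frozenset(mp_th)  # excludes k_off in the high regime
    mp_flags = frozenset(p for p in callable_params
                         if p in mp and mp[p] < mp_th[p])
    ks_flags = frozenset(p for p in callable_params
                         if p in ks and ks[p] > ks_th[p])
    bic_flags = bic_set & callable_params
    return EpikCall(
        testable=True, regime=regime, bic_set=bic_set, mp=dict(mp),
        ks=dict(ks), mp_flags=mp_flags, ks_flags=ks_flags,
        bic_flags=bic_flags,
        intersection=bic_flags & mp_flags & ks_flags,
        union_mp_ks=mp_flags | ks_flags,
        direction=int(np.sign(mean_diff)),
    )


def epik_test_pair(counts_a, counts_b, table: LookupTable,
                   thresholds: EpikThresholds | None = None,
                   frac: float = 0.25, reps: int = 100, seed: int = 0,
                   min_cells: int = MIN_EXPRESSING_CELLS,
                   koff_estimate: float | None = None,
                   standard_bic: bool = False) -> EpikCall:
    """Run all three methods on one gene / population pair and combine.

    Populations where the gene is expressed in fewer than ``min_cells``
    cells yield a not-testable call.  The regime k_off defaults to the
    pooled-data ML estimate.
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if np.sum(a > 0) < min_cells or np.sum(b > 0) < min_cells:
        return EpikCall(testable=False)
    if koff_estimate is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pooled = ml_estimate(np.concatenate([a, b]), table)
        koff_estimate = pooled.params.k_off
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bic_set, _ = bic_select(a, b, table, standard=standard_bic)
        mp = {p: marginal_probability(a, b, table, p) for p in PARAMS}
        ks = subsample_ks(a, b, table, frac=frac, reps=reps, seed=seed)
    return epik_combine(bic_set, mp, ks, thresholds,
                        koff_estimate=koff_estimate,
                        mean_diff=float(b.mean() - a.mean()))
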