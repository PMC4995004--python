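"""Synthetic single-cell count data under the telegraph model.

Three benchmark designs mirror the validation layout used throughout the
package:

* design A — parameter-recovery benchmark: many populations, one gene
  each, parameters drawn uniformly from k_on in (0,5), k_off in (0,20),
  k_t in (0,600), with binomial transcript loss at 10% capture emulating
  cDNA-library inefficiency.
* design B — clustering benchmark: 5 populations x 124 cells x 18 genes,
  per-(population, gene) parameters picked from a list of plausible
  captured-scale triples (no additional thinning: the triples already live
  on the captured scale).
* design C — paired-population benchmark: two 124-cell, 1-gene
  populations; one of the 8 subsets of {k_on, k_off, k_t} differs between
  them; k_off drawn either in (0,5) or (5,10); 10% capture.

Cells are drawn i.i.d. by inverse-CDF from the analytic stationary PMF; an
exact Gillespie simulator of the four reactions (activation, inactivation,
transcription, degradation) is provided as an independent cross-check of
that law.  Binomial thinning of a telegraph population is again telegraph
with k_t scaled by the capture probability, so captured-scale counts stay
within the lookup-table ceiling for the ranges above.

All generators are pure functions of their design constants and seed.
Amplification noise, cell-size and cell-cycle structure are deliberately
not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .epik import SCENARIOS
from .model_core import KineticParams, _log_pmf_vector

__all__ = [
    "SCENARIOS",
    "sample_stationary_counts",
    "gillespie_two_state",
    "gillespie_endstates",
    "apply_capture",
    "generate_design_a",
    "default_base_param_list",
    "generate_design_b",
    "generate_design_c",
]

#: Minimum separation of a "changed" parameter between the two populations
#: (one default-grid step); a nominally changed parameter that moves less
#: than the grid can resolve would make the benchmark unfalsifiable.
MIN_CHANGE_STEP = {"k_on": 0.1, "k_off": 0.4, "k_t": 5.0}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Sampling from the stationary law
# ---------------------------------------------------------------------------

def sample_stationary_counts(params, n: int, seed,
                             tail_mass: float = 1e-9,
                             x_budget: int = 5000) -> np.ndarray:
    """Draw n i.i.d. counts by inverse-CDF from the stationary PMF.

    The support ceiling is grown until the truncated tail mass is below
    ``tail_mass``; exceeding ``x_budget`` raises.
    """
    p = params if isinstance(params, KineticParams) else KineticParams(*params)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    x_max = int(p.k_t + 12.0 * math.sqrt(p.k_t + 1.0) + 30)
    while True:
        if x_max > x_budget:
            raise ValueError(
                f"support ceiling {x_max} exceeds budget {x_budget}"
            )
        pmf = np.exp(_log_pmf_vector(p.k_on, p.k_off, p.k_t, x_max))
        if pmf.sum() >= 1.0 - tail_mass:
            break
        x_max *= 2
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.searchsorted(cdf, u).astype(np.int64)


# ---------------------------------------------------------------------------
# Gillespie oracle
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gillespie_batch(k_on: float, k_off: float, k_t: float, t_end: float,
                     n: int, seed: int):
    np.random.seed(seed)
    counts = np.empty(n, dtype=np.int64)
    states = np.empty(n, dtype=np.int64)
    for i in range(n):
        t = 0.0
        on = 0
        m = 0
        while True:
            r_switch = k_off if on == 1 else k_on
            r_tx = k_t if on == 1 else 0.0
            r_deg = float(m)
            total = r_switch + r_tx + r_deg
            if total <= 0.0:
                break
            t += np.random.exponential(1.0 / total)
            if t >= t_end:
                break
            u = np.random.random() * total
            if u < r_switch:
                on = 1 - on
            elif u < r_switch + r_tx:
                m += 1
            else:
                m -= 1
        counts[i] = m
        states[i] = on
    return counts, states


def gillespie_endstates(params, t_end: float, n: int, seed: int):
    """End states of n independent exact simulations run to t_end.

    Time is in mRNA lifetimes; the four reactions are promoter activation
    (k_on), inactivation (k_off), transcription while active (k_t) and
    first-order degradation (rate 1 per molecule).  Trajectories start
    inactive with zero transcripts; for t_end >= ~20 lifetimes the end
    state is effectively stationary.

    Returns (counts, promoter_states) as int arrays.
    """
    p = params if isinstance(params, KineticParams) else KineticParams(*params)
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    return _gillespie_batch(p.k_on, p.k_off, p.k_t, float(t_end), int(n),
                            int(seed) & 0x7FFFFFFF)


def gillespie_two_state(params, t_end: float, seed: int):
    """Single exact simulation; returns (final count, final promoter state)."""
    counts, states = gillespie_endstates(params, t_end, 1, seed)
    return int(counts[0]), int(states[0])


# ---------------------------------------------------------------------------
# Capture / dropout
# ---------------------------------------------------------------------------

def apply_capture(counts, p: float, seed) -> np.ndarray:
    """Binomial thinning: each transcript survives independently with prob p."""
    if not (0.0 < p <= 1.0):
        raise ValueError("capture probability must be in (0, 1]")
    c = np.asarray(counts, dtype=np.int64)
    if p == 1.0:
        return c.copy()
    return _rng(seed).binomial(c, p)


# ---------------------------------------------------------------------------
# Benchmark designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationDesign:
    """Constants of one benchmark design."""

    design: str
    n_cells: int = 124
    capture_probability: float = 1.0
    k_on_range: tuple[float, float] = (0.0, 5.0)
    k_off_range: tuple[float, float] = (0.0, 20.0)
    k_t_range: tuple[float, float] = (0.0, 600.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.capture_probability <= 1.0):
            raise ValueError("capture_probability must be in (0, 1]")


def generate_design_a(n_sets: int = 3000, seed: int = 0, n_cells: int = 124,
                      capture_probability: float = 0.1,
                      k_on_range=(0.0, 5.0), k_off_range=(0.0, 20.0),
                      k_t_range=(0.0, 600.0)) -> list[dict]:
    """Parameter-recovery benchmark: uniform triples, thinned populations.

    Returns a list of dicts with keys ``params`` (KineticParams, the true
    pre-capture triple) and ``counts`` (captured counts, length n_cells).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for i in range(n_sets):
        params = KineticParams(
            rng.uniform(*k_on_range), rng.uniform(*k_off_range),
            rng.uniform(*k_t_range),
        )
        raw = sample_stationary_counts(params, n_cells, rng)
        out.append(dict(
            params=params,
            counts=apply_capture(raw, capture_probability, rng),
        ))
    return out


def default_base_param_list(n: int = 100, seed: int = 20160823,
                            jitter=(0.25, 1.0, 10.0)) -> np.ndarray:
    """Default list of plausible captured-scale parameter triples.

    Anchor triples are drawn uniformly from the interior of the default
    lookup grid and perturbed with Gaussian jitter of s.d. 5% of each
    axis range (0.25, 1, 10); results are clipped back to the grid bounds.
    """
    rng = np.random.default_rng(seed)
    anchors = np.column_stack([
        rng.uniform(0.3, 4.7, n),
        rng.uniform(0.5, 12.0, n),
        rng.uniform(15.0, 185.0, n),
    ])
    jittered = anchors + rng.normal(0.0, jitter, size=(n, 3))
    lo = np.array([0.1, 0.4, 5.0])
    hi = np.array([5.0, 20.0, 200.0])
    return np.clip(jittered, lo, hi)


def generate_design_b(n_datasets: int = 100, seed: int = 0,
                      n_populations: int = 5, n_cells: int = 124,
                      n_genes: int = 18,
                      base_params: np.ndarray | None = None) -> list[dict]:
    """Clustering benchmark: labelled multi-population datasets.

    Each dataset has ``n_populations`` balanced populations of ``n_cells``
    cells over ``n_genes`` genes; each (population, gene) triple is drawn
    from ``base_params`` (default: :func:`default_base_param_list`).  No
    thinning is applied — the base triples emulate captured-scale
    estimates.

    Returns dicts with ``counts`` ((n_pop*n_cells) x n_genes int array),
    ``labels`` (population id per cell) and ``params``
    ((n_pop, n_genes, 3) truth array).
    """
    if base_params is None:
        base_params = default_base_param_list()
    base_params = np.asarray(base_params, dtype=float)
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(n_datasets):
        rng = np.random.default_rng(child)
        picks = rng.integers(0, base_params.shape[0],
                             size=(n_populations, n_genes))
        params = base_params[picks]
        counts = np.empty((n_populations * n_cells, n_genes), dtype=np.int64)
        labels = np.repeat(np.arange(n_populations), n_cells)
        for i in range(n_populations):
            for g in range(n_genes):
                counts[i * n_cells:(i + 1) * n_cells, g] = \
                    sample_stationary_counts(tuple(params[i, g]), n_cells, rng)
        out.append(dict(counts=counts, labels=labels, params=params))
    return out


def _draw_changed(rng, value: float, lo: float, hi: float,
                  step: float) -> float:
    """Independent redraw constrained to differ by at least one grid step."""
    while True:
        v = rng.uniform(lo, hi)
        if abs(v - value) >= step:
            return v


def generate_design_c(per_scenario: int = 200, seed: int = 0,
                      n_cells: int = 124, capture_probability: float = 0.1,
                      koff_range: tuple[float, float] = (0.0, 5.0),
                      k_on_range=(0.0, 5.0), k_t_range=(0.0, 600.0),
                      scenarios=SCENARIOS,
                      per_scenario_override: dict | None = None) -> list[dict]:
    """Paired-population benchmark over the eight change scenarios.

    For each scenario, shared parameters are drawn once and used by both
    populations; changed parameters are drawn independently per population
    (forced to differ by at least one default-grid step).  Both
    populations are thinned at ``capture_probability``.

    ``per_scenario_override`` maps a scenario frozenset to a dataset count
    differing from ``per_scenario`` (e.g. extra null datasets for
    calibration).  Returns dicts with ``scenario`` (frozenset of changed
    parameter names), ``params_a``/``params_b`` (true pre-capture
    triples) and ``counts_a``/``counts_b``.
    """
    ranges = {"k_on": k_on_range, "k_off": koff_range, "k_t": k_t_range}
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    out = []
    for scen in scenarios:
        n_sets = per_scenario
        if per_scenario_override and scen in per_scenario_override:
            n_sets = per_scenario_override[scen]
        for _ in range(n_sets):
            a = {k: rng.uniform(*ranges[k]) for k in ("k_on", "k_off", "k_t")}
            b = dict(a)
            for k in ("k_on", "k_off", "k_t"):  # fixed draw order
                if k in scen:
                    b[k] = _draw_changed(rng, a[k], *ranges[k],
                                         MIN_CHANGE_STEP[k])
            pa = KineticParams(a["k_on"], a["k_off"], a["k_t"])
            pb = KineticParams(b["k_on"], b["k_off"], b["k_t"])
            ca = apply_capture(sample_stationary_counts(pa, n_cells, rng),
                               capture_probability, rng)
            cb = apply_capture(sample_stationary_counts(pb, n_cells, rng),
                               capture_probability, rng)
            out.append(dict(scenario=scen, params_a=pa, params_b=pb,
                            counts_a=ca, counts_b=cb))
    return out
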