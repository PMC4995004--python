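"""Maximum-likelihood kinetic-parameter estimation from count histograms.

For a homogeneous population with counts X = {x_1..x_n} the log-likelihood
of a parameter triple is L = sum_i ln P(x_i | k_on, k_off, k_t).  Binning
the counts turns the sum over cells into a dot product of the histogram
with a lookup-table row, so the whole likelihood surface is a single
matrix-vector product and the ML fit is its argmax.

Estimates are interpreted on the captured-count scale: no attempt is made
to invert transcript loss during library preparation, because capture
efficiency rescales the transcription rate and absolute parameter values
are therefore not comparable across experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import KineticParams, LookupTable

__all__ = [
    "CountHistogram",
    "MLFit",
    "counts_histogram",
    "log_likelihood_surface",
    "ml_estimate",
    "fit_populations",
    "MIN_EXPRESSING_CELLS",
]

#: Populations with fewer expressing (non-zero) cells than this are not fit
#: at the dataset level; the estimate would say more about dropout than
#: about kinetics.
MIN_EXPRESSING_CELLS = 10


@dataclass(frozen=True)
class CountHistogram:
    """Counts-per-value histogram over 0..x_max for one population."""

    counts_per_value: np.ndarray
    n_cells: int

    @property
    def x_max(self) -> int:
        return self.counts_per_value.size - 1


@dataclass(frozen=True)
class MLFit:
    params: KineticParams
    log_likelihood: float
    row_index: int


def counts_histogram(counts, x_max: int) -> CountHistogram:
    """Histogram integer counts onto 0..x_max, clipping overflows.

    Counts above ``x_max`` are clipped into the top bin with a warning (the
    lookup table has no support beyond its ceiling).
    """
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("cannot histogram an empty count vector")
    if np.any(c < 0):
        raise ValueError("counts must be >= 0")
    c = c.astype(np.int64)
    n_over = int(np.sum(c > x_max))
    if n_over:
        warnings.warn(
            f"{n_over} count(s) above x_max={x_max} clipped to x_max",
            stacklevel=2,
        )
        c = np.minimum(c, x_max)
    hist = np.bincount(c, minlength=x_max + 1)
    return CountHistogram(counts_per_value=hist, n_cells=int(c.size))


def log_likelihood_surface(hist: CountHistogram,
                           table: LookupTable) -> np.ndarray:
    """Log-likelihood of every table row given the histogram.

    Element r equals sum_x hist[x] * ln P(x | row r), i.e. the per-cell
    log-likelihood sum, computed as one matrix-vector product.
    """
    if hist.x_max != table.grid.x_max:
        raise ValueError(
            f"histogram x_max={hist.x_max} does not match table "
            f"x_max={table.grid.x_max}"
        )
    return table.log_pmf @ hist.counts_per_value.astype(float)


def ml_estimate(counts, table: LookupTable) -> MLFit:
    """Maximum-likelihood triple over the table grid.

    Ties at the maximum are broken by the lowest row index, which in the
    documented row order means the smallest k_on, then k_off, then k_t.
    """
    hist = counts if isinstance(counts, CountHistogram) else \
        counts_histogram(counts, table.grid.x_max)
    surface = log_likelihood_surface(hist, table)
    row = int(np.argmax(surface))  # np.argmax returns the first maximum
    return MLFit(params=table.params_for_row(row),
                 log_likelihood=float(surface[row]), row_index=row)


def ml_estimate_many(hists: np.ndarray, table: LookupTable) -> np.ndarray:
    """Row indices of the ML fit for a stack of histograms.

    ``hists`` is (n_pop, x_max+1); returns (n_pop,) argmax rows.  Batched
    so that repeated estimation (clustering iterations, subsampling) is a
    single matrix product.
    """
    surfaces = hists.astype(float) @ table.log_pmf.T
    return np.argmax(surfaces, axis=1)


def fit_populations(counts: pd.DataFrame, labels, table: LookupTable,
                    min_expressing: int = MIN_EXPRESSING_CELLS
                    ) -> pd.DataFrame:
    """Fit every (population, gene) combination of a counts matrix.

    Parameters
    ----------
    counts : DataFrame
        cells x genes integer counts, cell IDs in the index.
    labels : sequence
        Population label per cell, aligned with ``counts``.
    min_expressing : int
        Genes with fewer expressing cells than this in a population get a
        NaN fit there (``testable`` False).

    Returns
    -------
    DataFrame with columns gene, population, k_on, k_off, k_t, logL,
    n_cells, n_expressing, testable.
    """
    labels = np.asarray(labels)
    if labels.size != counts.shape[0]:
        raise ValueError("labels must align with the rows of counts")
    rows = []
    for pop in pd.unique(labels):
        sub = counts.loc[labels == pop]
        for gene in counts.columns:
            c = sub[gene].to_numpy()
            n_expr = int(np.sum(c > 0))
            if n_expr < min_expressing:
                rows.append(dict(gene=gene, population=pop, k_on=np.nan,
                                 k_off=np.nan, k_t=np.nan, logL=np.nan,
                                 n_cells=len(c), n_expressing=n_expr,
                                 testable=False))
                continue
            fit = ml_estimate(c, table)
            rows.append(dict(gene=gene, population=pop,
                             k_on=fit.params.k_on, k_off=fit.params.k_off,
                             k_t=fit.params.k_t, logL=fit.log_likelihood,
                             n_cells=len(c), n_expressing=n_expr,
                             testable=True))
    return pd.DataFrame(rows)
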