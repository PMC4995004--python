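"""Scaling of normalised qPCR Ct values to bounded integer count surrogates.

A (housekeeping-normalised) Ct value relates to transcript abundance as
x = int(b * 2**(a - Ct)) for platform constants a, b.  Choosing, per gene,
b so that the most abundant cell maps exactly to the table ceiling x_max
eliminates both constants:

    x = int(x_max * 2**(min(Ct_gene) - Ct))

The per-gene minimum is taken jointly over *all* cells of *all*
populations, so the scale is shared and estimates remain comparable across
populations.  The choice of scale affects absolute parameter values but
not cross-population comparisons.  Housekeeping normalisation is assumed
already applied upstream.

Wells with no detectable expression are often recorded as a sentinel Ct
(e.g. 15, or the platform's limit of detection); those map to count 0 and
are excluded from the per-gene minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtMatrix", "ct_to_counts"]


@dataclass
class CtMatrix:
    """cells x genes matrix of normalised Ct values (lower = more mRNA)."""

    values: pd.DataFrame
    cell_labels: np.ndarray | None = None
    nonexpressed_sentinel: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("Ct values must be finite")


def ct_to_counts(ct: CtMatrix | pd.DataFrame, x_max: int = 200,
                 sentinel: float | None = None) -> pd.DataFrame:
    """Convert a Ct matrix to integer counts in [0, x_max].

    count = floor(x_max * 2**(min(Ct_gene) - Ct)); the floor is toward zero
    (all scaled values are non-negative).  Sentinel-valued wells become 0
    and do not participate in the per-gene minimum.

    Raises if a gene has no expressing (non-sentinel) cell, since its scale
    would be undefined.
    """
    if isinstance(ct, CtMatrix):
        if sentinel is None:
            sentinel = ct.nonexpressed_sentinel
        ct = ct.values
    vals = ct.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Ct values must be finite")
    expressed = np.ones_like(vals, dtype=bool)
    if sentinel is not None:
        expressed = vals != sentinel
    dead = ~expressed.any(axis=0)
    if dead.any():
        genes = list(ct.columns[dead])
        raise ValueError(f"gene(s) with no expressing cell: {genes}")
    masked = np.where(expressed, vals, np.inf)
    gene_min = masked.min(axis=0)
    counts = np.floor(x_max * np.exp2(gene_min[None, :] - vals)).astype(np.int64)
    counts[~expressed] = 0
    return pd.DataFrame(counts, index=ct.index, columns=ct.columns)
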