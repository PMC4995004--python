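"""Stationary distribution of the two-state (telegraph) model of transcription.

A gene promoter switches stochastically between an inactive and an active
state at rates ``k_on`` and ``k_off``; while active it produces mRNA at rate
``k_t``; each transcript decays independently at rate 1 (all rates are
expressed per mRNA lifetime, i.e. normalised to the degradation rate, which
therefore never appears as a free parameter).  At stationarity the mRNA copy
number ``x`` follows the beta-Poisson law of Peccoud & Ycart,

    P(x) = G(k_on + x) G(k_on + k_off) k_t^x
           -------------------------------------- 1F1(k_on + x, k_on + k_off + x, -k_t)
           G(x+1) G(k_on + k_off + x) G(k_on)

with ``G`` the gamma function and ``1F1`` Kummer's confluent hypergeometric
function.  Depending on the rates the law ranges from Poisson-like (fast
switching, mostly on) through negative-binomial-like (brief bursts) to
bimodal (slow switching).

This module evaluates the law in log space and builds the dense lookup
table of ``log P(x | k_on, k_off, k_t)`` over a parameter grid that the
estimation, clustering and differential-kinetics modules all share.

Numerical route: Kummer's transformation ``1F1(a, b, -z) = e^-z 1F1(b-a, b, z)``
turns the alternating series into one with ``b - a = k_off >= 0``, i.e. all
terms positive, so a double-precision sum carries essentially full relative
accuracy with no cancellation.  Arbitrary-precision evaluation (mpmath) is
kept as a fallback for transcription rates beyond the overflow guard.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "KineticParams",
    "GridSpec",
    "LookupTable",
    "LOG_FLOOR",
    "log_pmf",
    "pmf_vector",
    "high_koff_log_pmf",
    "build_lookup_table",
    "load_lookup_table",
]

#: Log-probability floor used inside likelihood sums.  exp(-745) is the edge
#: of the double-precision denormal range; flooring there keeps a single
#: impossible count from erasing a whole population's likelihood surface.
LOG_FLOOR = -745.0

#: Above this transcription rate the positive-term series can overflow a
#: double (e^710 does); scalar evaluation then falls back to mpmath.
_KT_OVERFLOW_GUARD = 700.0


@dataclass(frozen=True)
class KineticParams:
    """Rates of the two-state model, per mRNA lifetime (dimensionless).

    ``k_on``: activation rate; ``k_off``: inactivation rate; ``k_t``:
    transcription rate while active.
    """

    k_on: float
    k_off: float
    k_t: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_t"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k_on, self.k_off, self.k_t)


def _as_params(params) -> KineticParams:
    if isinstance(params, KineticParams):
        return params
    return KineticParams(*params)


# ---------------------------------------------------------------------------
# PMF evaluation
# ---------------------------------------------------------------------------

def _series_log_1f1(k_on: float, k_off: float, k_t: float, x: np.ndarray,
                    max_terms: int | None = None) -> np.ndarray:
    """log 1F1(k_on + x, k_on + k_off + x, -k_t) for a vector of counts.

    Via Kummer's transformation the sum S = 1F1(k_off, k_on+k_off+x, k_t)
    has positive terms t_0 = 1, t_{n+1} = t_n (k_off+n) k_t / ((b+n)(n+1)),
    b = k_on + k_off + x, and log 1F1 = -k_t + log S.
    """
    b = k_on + k_off + x.astype(float)
    term = np.ones_like(b)
    total = np.ones_like(b)
    if max_terms is None:
        max_terms = int(k_t + 20.0 * math.sqrt(k_t + 10.0) + 80)
    for n in range(max_terms):
        term = term * ((k_off + n) * k_t) / ((b + n) * (n + 1.0))
        total += term
        if n >= 1 and np.max(term / total) < 1e-17:
            break
    return -k_t + np.log(total)


def _log_pmf_vector(k_on: float, k_off: float, k_t: float,
                    x_max: int) -> np.ndarray:
    """ln P(x) for x = 0..x_max; may contain -inf where P underflows."""
    x = np.arange(x_max + 1)
    if k_t == 0.0 or k_on == 0.0:
        # never transcribing (or never on): all mass at zero
        out = np.full(x_max + 1, -np.inf)
        out[0] = 0.0
        return out
    if k_t > _KT_OVERFLOW_GUARD:
        return np.array([_log_pmf_mpmath(int(xi), k_on, k_off, k_t) for xi in x])
    log_1f1 = _series_log_1f1(k_on, k_off, k_t, x)
    with np.errstate(divide="ignore"):
        out = (
            gammaln(k_on + x) - gammaln(k_on)
            + gammaln(k_on + k_off) - gammaln(k_on + k_off + x)
            - gammaln(x + 1.0)
            + x * math.log(k_t)
            + log_1f1
        )
    return out


def _log_pmf_mpmath(x: int, k_on: float, k_off: float, k_t: float) -> float:
    import mpmath as mp

    with mp.workdps(50):
        v = (
            mp.loggamma(k_on + x) - mp.loggamma(k_on)
            + mp.loggamma(k_on + k_off) - mp.loggamma(k_on + k_off + x)
            - mp.loggamma(x + 1)
            + x * mp.log(k_t)
            + mp.log(mp.hyp1f1(k_on + x, k_on + k_off + x, -k_t))
        )
        return float(v)


def _log_pmf_block(k_on: float, k_off: float, kt_values: np.ndarray,
                   x_max: int) -> np.ndarray:
    """ln P(x) for one (k_on, k_off) and a whole k_t axis at once.

    Shape (n_kt, x_max+1).  Shares the positive-term Kummer series across
    the k_t axis, which is what makes dense table construction cheap.
    """
    x = np.arange(x_max + 1)
    kt = np.asarray(kt_values, dtype=float)[:, None]
    b = (k_on + k_off + x)[None, :].astype(float)
    term = np.ones((kt.size, x.size))
    total = np.ones_like(term)
    kt_max = float(kt.max())
    max_terms = int(kt_max + 20.0 * math.sqrt(kt_max + 10.0) + 80)
    for n in range(max_terms):
        term *= ((k_off + n) * kt) / ((b + n) * (n + 1.0))
        total += term
        if n % 16 == 15 and np.max(term / total) < 1e-17:
            break
    base = (
        gammaln(k_on + x) - gammaln(k_on)
        + gammaln(k_on + k_off) - gammaln(k_on + k_off + x)
        - gammaln(x + 1.0)
    )[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = base + x[None, :] * np.log(kt) - kt + np.log(total)
    zero_kt = kt[:, 0] == 0.0
    if zero_kt.any():
        out[zero_kt] = -np.inf
        out[zero_kt, 0] = 0.0
    return out


def log_pmf(x: int, params) -> float:
    """ln P(x | k_on, k_off, k_t) under the stationary telegraph model.

    Returns ``-inf`` only when the probability underflows double precision
    entirely; never NaN.

    Parameters
    ----------
    x : int
        mRNA copy number, >= 0.
    params : KineticParams or 3-tuple
    """
    p = _as_params(params)
    if not (isinstance(x, (int, np.integer)) and x >= 0):
        raise ValueError(f"count x must be a non-negative integer, got {x!r}")
    x = int(x)
    if p.k_t == 0.0 or p.k_on == 0.0:
        return 0.0 if x == 0 else -np.inf
    if p.k_t > _KT_OVERFLOW_GUARD:
        return _log_pmf_mpmath(x, p.k_on, p.k_off, p.k_t)
    xv = np.array([x])
    log_1f1 = _series_log_1f1(p.k_on, p.k_off, p.k_t, xv)[0]
    val = (
        float(gammaln(p.k_on + x) - gammaln(p.k_on)
              + gammaln(p.k_on + p.k_off) - gammaln(p.k_on + p.k_off + x)
              - gammaln(x + 1.0))
        + x * math.log(p.k_t)
        + log_1f1
    )
    return val if np.isfinite(val) else -np.inf


def pmf_vector(params, x_max: int) -> np.ndarray:
    """P(x) for x = 0..x_max (inclusive) as a dense probability vector."""
    p = _as_params(params)
    if x_max < 1:
        raise ValueError("x_max must be >= 1")
    return np.exp(_log_pmf_vector(p.k_on, p.k_off, p.k_t, int(x_max)))


def high_koff_log_pmf(x: int, params) -> float:
    """Fast-switching limit of the stationary law (negative-binomial form).

    For large ``k_off`` the telegraph PMF approaches

        P'(x) = (1 + r)^(-k_on) * G(k_on+x)/(G(k_on) x!) * (r/(1+r))^x,

    with ``r = k_t / k_off``: a negative binomial that depends on the two
    rates only through their ratio, which is why ``k_off`` and ``k_t`` become
    unidentifiable separately in that regime.
    """
    p = _as_params(params)
    if p.k_off <= 0:
        raise ValueError("high-k_off limit requires k_off > 0")
    if x < 0:
        raise ValueError("count x must be >= 0")
    x = int(x)
    r = p.k_t / p.k_off
    if r == 0.0:
        return 0.0 if x == 0 else -np.inf
    return (
        -p.k_on * math.log1p(r)
        + float(gammaln(p.k_on + x) - gammaln(p.k_on) - gammaln(x + 1.0))
        + x * (math.log(r) - math.log1p(r))
    )


# ---------------------------------------------------------------------------
# Grid and lookup table
# ---------------------------------------------------------------------------

def _grid_axis(values) -> np.ndarray:
    a = np.asarray(values, dtype=float)
    if a.ndim != 1 or a.size == 0:
        raise ValueError("grid axis must be a non-empty 1-D sequence")
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("grid values must be finite and >= 0")
    if a.size > 1 and np.any(np.diff(a) <= 0):
        raise ValueError("grid axis must be strictly increasing")
    return a


@dataclass(frozen=True)
class GridSpec:
    """Axes of the parameter grid plus the count ceiling ``x_max``.

    The default grid covers activation rates 0.1..5 (step 0.1),
    inactivation rates 0.4..20 (step 0.4) and transcription rates 5..200
    (step 5) — 100,000 triples — with counts 0..200.
    """

    k_on_values: np.ndarray
    k_off_values: np.ndarray
    k_t_values: np.ndarray
    x_max: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_on_values", _grid_axis(self.k_on_values))
        object.__setattr__(self, "k_off_values", _grid_axis(self.k_off_values))
        object.__setattr__(self, "k_t_values", _grid_axis(self.k_t_values))
        if int(self.x_max) < 1:
            raise ValueError("x_max must be >= 1")
        object.__setattr__(self, "x_max", int(self.x_max))

    @classmethod
    def default(cls) -> "GridSpec":
        return cls(
            k_on_values=np.round(np.arange(1, 51) * 0.1, 10),
            k_off_values=np.round(np.arange(1, 51) * 0.4, 10),
            k_t_values=np.arange(1, 41) * 5.0,
            x_max=200,
        )

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.k_on_values.size, self.k_off_values.size,
                self.k_t_values.size)

    @property
    def n_rows(self) -> int:
        n1, n2, n3 = self.shape
        return n1 * n2 * n3


@dataclass
class LookupTable:
    """Dense table of ln P(x | params) over a parameter grid.

    Rows are ordered k_on-major, then k_off, then k_t (row
    ``(i*n_off + j)*n_t + k`` holds the triple ``(k_on[i], k_off[j],
    k_t[k])``); this order is stable across versions.  Stored values are
    floored at ``log_floor`` so likelihood sums stay finite.
    """

    grid: GridSpec
    log_pmf: np.ndarray  # (n_rows, x_max + 1)
    log_floor: float = LOG_FLOOR
    _param_rows: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n1, n2, n3 = self.grid.shape
        if self.log_pmf.shape != (n1 * n2 * n3, self.grid.x_max + 1):
            raise ValueError("log_pmf shape inconsistent with grid")
        on, off, kt = np.meshgrid(
            self.grid.k_on_values, self.grid.k_off_values,
            self.grid.k_t_values, indexing="ij",
        )
        self._param_rows = np.column_stack(
            [on.ravel(), off.ravel(), kt.ravel()]
        )

    # -- row <-> parameter bookkeeping ------------------------------------
    @property
    def n_rows(self) -> int:
        return self.log_pmf.shape[0]

    @property
    def param_index(self) -> np.ndarray:
        """(n_rows, 3) array of (k_on, k_off, k_t) per row."""
        return self._param_rows

    def params_for_row(self, row: int) -> KineticParams:
        k_on, k_off, k_t = self._param_rows[row]
        return KineticParams(k_on, k_off, k_t)

    def row_for_params(self, params) -> int:
        """Row of the grid triple nearest (per axis) to ``params``."""
        p = _as_params(params)
        i = int(np.argmin(np.abs(self.grid.k_on_values - p.k_on)))
        j = int(np.argmin(np.abs(self.grid.k_off_values - p.k_off)))
        k = int(np.argmin(np.abs(self.grid.k_t_values - p.k_t)))
        n2, n3 = self.grid.shape[1:]
        return (i * n2 + j) * n3 + k

    def surface_3d(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a per-row vector to (n_on, n_off, n_t)."""
        return np.asarray(flat).reshape(self.grid.shape)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("log_pmf", data=self.log_pmf)
            f.create_dataset("k_on_values", data=self.grid.k_on_values)
            f.create_dataset("k_off_values", data=self.grid.k_off_values)
            f.create_dataset("k_t_values", data=self.grid.k_t_values)
            f.attrs["x_max"] = self.grid.x_max
            f.attrs["log_floor"] = self.log_floor

    def to_csv_gz(self, path) -> None:
        """Interoperability export: one row per triple, gzip CSV."""
        header = "k_on,k_off,k_t," + ",".join(
            f"logP_{x}" for x in range(self.grid.x_max + 1)
        )
        with gzip.open(path, "wt") as f:
            f.write(header + "\n")
            for r in range(self.n_rows):
                p = self._param_rows[r]
                f.write(
                    f"{p[0]:g},{p[1]:g},{p[2]:g},"
                    + ",".join(f"{v:.10g}" for v in self.log_pmf[r]) + "\n"
                )


def load_lookup_table(path) -> LookupTable:
    import h5py

    with h5py.File(path, "r") as f:
        grid = GridSpec(
            k_on_values=f["k_on_values"][:],
            k_off_values=f["k_off_values"][:],
            k_t_values=f["k_t_values"][:],
            x_max=int(f.attrs["x_max"]),
        )
        return LookupTable(grid=grid, log_pmf=f["log_pmf"][:],
                           log_floor=float(f.attrs.get("log_floor", LOG_FLOOR)))


def build_lookup_table(grid: GridSpec, log_floor: float = LOG_FLOOR,
                       memory_budget_bytes: int = 4 << 30) -> LookupTable:
    """Evaluate ln P(x | params) for every triple in the grid.

    Rows follow the documented k_on-major order.  A grid whose table would
    exceed ``memory_budget_bytes`` is refused outright.
    """
    n_rows = grid.n_rows
    need = n_rows * (grid.x_max + 1) * 8
    if need > memory_budget_bytes:
        raise MemoryError(
            f"grid implies {need / 1e9:.2f} GB (> budget "
            f"{memory_budget_bytes / 1e9:.2f} GB); coarsen the grid or raise "
            "memory_budget_bytes"
        )
    table = np.empty((n_rows, grid.x_max + 1))
    n_t = grid.k_t_values.size
    kt_vectorizable = not np.any(grid.k_t_values > _KT_OVERFLOW_GUARD)
    r = 0
    for k_on in grid.k_on_values:
        for k_off in grid.k_off_values:
            if k_on > 0 and kt_vectorizable:
                table[r:r + n_t] = _log_pmf_block(
                    k_on, k_off, grid.k_t_values, grid.x_max)
            else:
                for i, k_t in enumerate(grid.k_t_values):
                    table[r + i] = _log_pmf_vector(k_on, k_off, k_t,
                                                   grid.x_max)
            r += n_t
    np.maximum(table, log_floor, out=table)
    return LookupTable(grid=grid, log_pmf=table, log_floor=log_floor)
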