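"""SABEC: Simulated Annealing for Bursty Expression Clustering.

Cells are clustered into K populations with homogeneous bursting kinetics.
A single run starts from uniform-random labels and alternates between
(i) maximum-likelihood estimation of each cluster's per-gene kinetic
triple on the lookup grid and (ii) probabilistic reassignment of every
cell, where the assignment distribution is an annealed softmax of the
cluster log-likelihoods: with normalised log-posteriors
L'_i = L_i - logsumexp_j L_j, cell c is assigned to cluster i with
probability proportional to exp(tau^t * L'_i).  The inverse temperature
tau^t grows geometrically with the iteration counter t, so early
iterations move cells freely while later ones lock in the best-fitting
assignment.  A run terminates when fewer than 5% of cells swap clusters,
or after 100 iterations.

Because single runs can land in local optima, the algorithm is repeated
(50 restarts by default) and summarised as a consensus matrix counting how
often each pair of cells co-clusters.  Model order is judged by the
proportion of ambiguously clustered pairs (PAC) and — when reference
labels exist — variation of information and the corrected Rand index; no
single automatic K is forced.  A final partition is cut from the consensus
matrix with partitioning around medoids (PAM), and cells that rarely
co-cluster with others of their own label can be pruned as outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .estimation import ml_estimate_many
from .model_core import LookupTable

__all__ = [
    "ConsensusMatrix",
    "cluster_log_likelihood",
    "assignment_probabilities",
    "sabec_single_run",
    "sabec_consensus",
    "consensus_matrix",
    "pac_score",
    "variation_of_information",
    "corrected_rand",
    "consensus_partition",
    "prune_outliers",
]


@dataclass(frozen=True)
class ConsensusMatrix:
    """Pairwise co-clustering counts over repeated runs."""

    co_count: np.ndarray  # (n_cells, n_cells) int
    n_runs: int

    @property
    def frequency(self) -> np.ndarray:
        return self.co_count / float(self.n_runs)

    @property
    def n_cells(self) -> int:
        return self.co_count.shape[0]


def cluster_log_likelihood(cell_counts, cluster_params, table: LookupTable
                           ) -> float:
    """Log-likelihood of one cell under one cluster's per-gene parameters.

    ``cell_counts`` is the per-gene count vector of the cell;
    ``cluster_params`` the matching per-gene kinetic triples (looked up at
    the nearest grid row).  Additivity over genes is exact.
    """
    counts = np.asarray(cell_counts)
    if len(counts) != len(cluster_params):
        raise ValueError("cell and cluster params must cover the same genes")
    x = np.minimum(counts, table.grid.x_max)
    total = 0.0
    for g, params in enumerate(cluster_params):
        total += table.log_pmf[table.row_for_params(params), x[g]]
    return float(total)


def assignment_probabilities(cell_logL, tau: float, t: int) -> np.ndarray:
    """Annealed soft assignment over K clusters.

    p_i is proportional to exp(beta_t * (L_i - max_j L_j)) with inverse
    temperature beta_t = tau^t; at t = 0 this is an ordinary softmax of
    the log-likelihoods, and the distribution sharpens toward the argmax
    as t grows.
    """
    L = np.asarray(cell_logL, dtype=float)
    if L.size < 2:
        raise ValueError("need K >= 2 clusters")
    if tau <= 1:
        raise ValueError("tau must be > 1")
    if t < 0:
        raise ValueError("t must be >= 0")
    if np.all(np.isneginf(L)):
        warnings.warn("all cluster log-likelihoods are -inf; uniform "
                      "assignment", stacklevel=2)
        return np.full(L.size, 1.0 / L.size)
    beta = tau ** t
    z = beta * (L - L.max())
    p = np.exp(z)
    return p / p.sum()


def _cluster_gene_histograms(counts: np.ndarray, labels: np.ndarray, K: int,
                             x_max: int) -> np.ndarray:
    """Histograms for every (cluster, gene): shape (K * n_genes, x_max+1)."""
    n_genes = counts.shape[1]
    hists = np.zeros((K * n_genes, x_max + 1), dtype=np.int64)
    for i in range(K):
        sub = counts[labels == i]
        for g in range(n_genes):
            hists[i * n_genes + g] = np.bincount(sub[:, g],
                                                 minlength=x_max + 1)
    return hists


def _cell_cluster_logL(counts: np.ndarray, rows: np.ndarray,
                       table: LookupTable) -> np.ndarray:
    """(n_cells, K) log-likelihood of each cell under each cluster."""
    K = rows.shape[0]
    out = np.empty((counts.shape[0], K))
    for i in range(K):
        out[:, i] = table.log_pmf[rows[i][None, :], counts].sum(axis=1)
    return out


def sabec_single_run(counts, K: int, table: LookupTable, tau: float = 10.0,
                     max_iter: int = 100, swap_tol: float = 0.05,
                     seed: int = 0) -> np.ndarray:
    """One annealed clustering run; returns labels in 0..K-1.

    If a cluster empties during reassignment it is re-seeded with the
    single worst-fitting cell (lowest log-likelihood under its current
    cluster).
    """
    counts = np.minimum(np.asarray(counts, dtype=np.int64),
                        table.grid.x_max)
    n_cells, n_genes = counts.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n_cells < K:
        raise ValueError("need at least K cells")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=n_cells)
    if K == 1:
        return np.zeros(n_cells, dtype=np.int64)
    for t in range(max_iter):
        # re-seed any empty cluster with the worst-fitting cell
        labels = _repair_empty(counts, labels, K, table)
        hists = _cluster_gene_histograms(counts, labels, K,
                                         table.grid.x_max)
        rows = ml_estimate_many(hists, table).reshape(K, n_genes)
        L = _cell_cluster_logL(counts, rows, table)
        beta = tau ** t
        z = beta * (L - L.max(axis=1, keepdims=True))
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((n_cells, 1))
        new_labels = (p.cumsum(axis=1) < u).sum(axis=1)
        swapped = np.mean(new_labels != labels)
        labels = new_labels
        if swapped < swap_tol:
            break
    return labels.astype(np.int64)


def _repair_empty(counts, labels, K, table) -> np.ndarray:
    labels = labels.copy()
    for i in range(K):
        if not np.any(labels == i):
            hists = _cluster_gene_histograms(counts, labels, K,
                                             table.grid.x_max)
            rows = ml_estimate_many(hists, table).reshape(
                K, counts.shape[1])
            L = _cell_cluster_logL(counts, rows, table)
            own = L[np.arange(len(labels)), labels]
            worst = int(np.argmin(own))
            warnings.warn(f"cluster {i} emptied; re-seeded with cell "
                          f"{worst}", stacklevel=2)
            labels[worst] = i
    return labels


def sabec_consensus(counts, K: int, table: LookupTable, n_runs: int = 50,
                    tau: float = 10.0, max_iter: int = 100,
                    swap_tol: float = 0.05, seed: int = 0) -> dict:
    """Repeated runs + consensus summary + PAM cut.

    Restart r uses seed ``seed + r``.  Returns a dict with ``runs`` (list
    of label vectors), ``consensus`` (ConsensusMatrix), ``pac`` and
    ``partition`` (PAM cut of the consensus dissimilarity at K).
    """
    runs = [
        sabec_single_run(counts, K, table, tau=tau, max_iter=max_iter,
                         swap_tol=swap_tol, seed=seed + r)
        for r in range(n_runs)
    ]
    cm = consensus_matrix(runs)
    return dict(runs=runs, consensus=cm, pac=pac_score(cm),
                partition=consensus_partition(cm, K))


# ---------------------------------------------------------------------------
# Consensus summaries and partition metrics
# ---------------------------------------------------------------------------

def consensus_matrix(runs) -> ConsensusMatrix:
    """Count, for every cell pair, the runs in which they co-cluster."""
    runs = [np.asarray(r) for r in runs]
    n = runs[0].size
    if any(r.size != n for r in runs):
        raise ValueError("all runs must cover the same cells")
    co = np.zeros((n, n), dtype=np.int64)
    for r in runs:
        co += (r[:, None] == r[None, :])
    return ConsensusMatrix(co_count=co, n_runs=len(runs))


def pac_score(cm: ConsensusMatrix, lower: float = 0.10,
              upper: float = 0.90) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of unordered off-diagonal pairs whose co-clustering
    frequency lies strictly between ``lower`` and ``upper``; lower is more
    stable.
    """
    freq = cm.frequency
    iu = np.triu_indices(cm.n_cells, k=1)
    f = freq[iu]
    return float(np.mean((f > lower) & (f < upper)))


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def variation_of_information(a, b) -> float:
    """VI(a, b) = H(a) + H(b) - 2 I(a; b), natural-log units; 0 iff equal."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("partitions must cover the same cells")
    vi = _entropy(a) + _entropy(b) - 2.0 * mutual_info_score(a, b)
    return float(max(vi, 0.0))


def corrected_rand(a, b) -> float:
    """Hubert–Arabie adjusted (chance-corrected) Rand index."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValueError("partitions must cover the same cells")
    return float(adjusted_rand_score(a, b))


def consensus_partition(cm: ConsensusMatrix, K: int) -> np.ndarray:
    """PAM cut of the consensus dissimilarity d = 1 - co/n_runs.

    Deterministic: a greedy BUILD phase picks initial medoids, then
    alternating assignment / within-cluster medoid updates refine them
    until the medoid set is stable.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    d = 1.0 - cm.frequency
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    if K >= n:
        return np.arange(n, dtype=np.int64)
    # BUILD: start with the most central point, then greedily add the
    # point that most reduces the total distance to the nearest medoid.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < K:
        gain = np.minimum(d, nearest[None, :]).sum(axis=1)
        gain[medoids] = np.inf
        m = int(np.argmin(gain))
        medoids.append(m)
        nearest = np.minimum(nearest, d[m])
    medoids = np.array(medoids)
    # refinement: alternate assignment and per-cluster medoid update
    for _ in range(100):
        labels = np.argmin(d[medoids][:, :], axis=0)
        new_medoids = medoids.copy()
        for k in range(K):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new_medoids[k] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(d[medoids][:, :], axis=0).astype(np.int64)


def prune_outliers(cm: ConsensusMatrix, labels, threshold: float | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mask out cells that rarely co-cluster with their own label.

    The match fraction of a cell is the mean co-clustering frequency with
    the other cells sharing its label.  With ``threshold`` None, the cut
    is placed automatically at the largest single step of the ascending
    sorted match curve within its lower half (the steepest part of the
    curve); cells strictly below the cut are pruned.

    Returns (kept mask, per-cell match fraction).
    """
    labels = np.asarray(labels)
    if labels.size != cm.n_cells:
        raise ValueError("labels must cover all cells of the consensus")
    freq = cm.frequency
    match = np.empty(labels.size)
    for i in range(labels.size):
        same = np.flatnonzero(labels == labels[i])
        same = same[same != i]
        if same.size == 0:
            warnings.warn(f"label class of cell {i} has size 1; match "
                          "fraction set to 0", stacklevel=2)
            match[i] = 0.0
        else:
            match[i] = freq[i, same].mean()
    if threshold is None:
        order = np.sort(match)
        half = max(labels.size // 2, 1)
        steps = np.diff(order[:half + 1])
        if steps.size == 0 or steps.max() <= 0:
            threshold = order[0]  # flat curve: prune nothing
        else:
            threshold = order[int(np.argmax(steps)) + 1]
    kept = match >= threshold
    return kept, match
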