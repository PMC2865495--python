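"""Lloyd-type partitional clustering.

k-means for continuous data (squared Euclidean distance, mean update) and
k-modes for genotype data (allele-sharing distance, per-locus mode update).
Both share one driver: alternate nearest-centroid assignment and centroid
update until the label vector is unchanged, restart from several random
initializations, and return the labeling with the smallest quantization
error.

Parallelism contract
--------------------
Rows are processed in fixed-size blocks (``ROW_BLOCK`` rows). The
``workers`` setting only controls how many blocks are in flight at once on
a thread pool; block boundaries and the order in which block partial
results are reduced never depend on it. Results are therefore bit-identical
for every worker count.

The allele-sharing distance (ASD) between two genotype vectors is the sum
over loci of 2 minus the number of shared alleles, which under 0/1/2 coding
equals the per-locus absolute difference: identical genotypes contribute 0,
heterozygous vs either homozygote 1, opposite homozygotes 2.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .matrix import CONTINUOUS, GENOTYPE, DataMatrix, MatrixError

#: Rows per work unit. Fixed (independent of ``workers``) so that the block
#: decomposition, and hence every floating-point reduction order, is
#: invariant to the degree of parallelism.
ROW_BLOCK = 4096


class DegenerateInputError(ValueError):
    """More clusters requested than the data can support."""


@dataclass(frozen=True)
class ClusterConfig:
    """Settings for one clustering task.

    ``k`` clusters, at most ``max_iter`` assignment/update cycles per
    restart, ``restarts`` random initializations, ``workers`` >= 1 threads,
    and an integer RNG ``seed`` (``None`` draws a fresh one, recorded in the
    result).
    """

    k: int
    max_iter: int = 100
    restarts: int = 10
    workers: int = 1
    seed: int | Sequence[int] | None = None

    def validate(self, n_rows: int) -> None:
        if not 0 < self.k < n_rows:
            raise DegenerateInputError(
                f"k={self.k} must satisfy 0 < k < N={n_rows}"
            )
        if self.max_iter < 1 or self.restarts < 1 or self.workers < 1:
            raise ValueError("max_iter, restarts and workers must be >= 1")


@dataclass(frozen=True)
class ClusteringResult:
    """Outcome of one clustering task (best restart).

    ``sse`` is the quantization error: the sum of squared Euclidean
    distances (continuous) or summed allele-sharing distances (genotype)
    of objects to their assigned centroid; ``mse = sse / N``.
    """

    labels: np.ndarray
    centroids: np.ndarray
    sse: float
    mse: float
    iterations: int
    converged: bool
    seed_used: int | tuple


def _metric(kind: str) -> str:
    return "sqeuclidean" if kind == CONTINUOUS else "cityblock"


def _blocks(n: int) -> list[slice]:
    return [slice(s, min(s + ROW_BLOCK, n)) for s in range(0, n, ROW_BLOCK)]


def _run_blocks(fn: Callable, blocks: list[slice], workers: int) -> list:
    if workers <= 1 or len(blocks) == 1:
        return [fn(b) for b in blocks]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(fn, blocks))


def asd(x, y) -> int:
    """Allele-sharing distance between two genotype vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape:
        raise MatrixError("genotype vectors differ in length")
    for v in (x, y):
        if ((v < 0) | (v > 2)).any():
            raise MatrixError("genotype entries must be in {0,1,2}")
    return int(np.abs(x - y).sum())


def init_centroids(X: DataMatrix, k: int, rng: np.random.Generator) -> np.ndarray:
    """Choose k distinct rows of X uniformly without replacement."""
    distinct = np.unique(X.values, axis=0)
    if not 0 < k <= len(distinct):
        raise DegenerateInputError(
            f"k={k} exceeds the number of distinct rows ({len(distinct)})"
        )
    idx = rng.choice(len(distinct), size=k, replace=False)
    return distinct[idx].copy()


def _assign(values_f: np.ndarray, centroids: np.ndarray, kind: str,
            workers: int) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid labels and the distance to the assigned centroid."""
    metric = _metric(kind)
    cf = np.asarray(centroids, dtype=np.float64)

    def work(sl: slice):
        d = cdist(values_f[sl], cf, metric=metric)
        lab = d.argmin(axis=1)          # ties -> lowest centroid index
        return lab, d[np.arange(lab.shape[0]), lab]

    parts = _run_blocks(work, _blocks(values_f.shape[0]), workers)
    labels = np.concatenate([p[0] for p in parts])
    dists = np.concatenate([p[1] for p in parts])
    return labels, dists


def assign_to_nearest(X: DataMatrix, centroids: np.ndarray,
                      workers: int = 1) -> np.ndarray:
    """Label every object with the index of its nearest centroid.

    Squared Euclidean distance for continuous data, ASD for genotypes;
    ties break to the lowest centroid index. Output is identical for any
    ``workers`` >= 1.
    """
    centroids = np.asarray(centroids)
    if centroids.ndim != 2 or centroids.shape[1] != X.n_cols:
        raise MatrixError(
            f"centroid dimension {centroids.shape} does not match "
            f"{X.n_cols} features"
        )
    values_f = X.values.astype(np.float64, copy=False)
    return _assign(values_f, centroids, X.kind, workers)[0]


def _point_dists(values_f: np.ndarray, centroids: np.ndarray,
                 labels: np.ndarray, kind: str) -> np.ndarray:
    diff = values_f - np.asarray(centroids, dtype=np.float64)[labels]
    if kind == CONTINUOUS:
        return np.einsum("ij,ij->i", diff, diff)
    return np.abs(diff).sum(axis=1)


def _reseat_empty(values: np.ndarray, values_f: np.ndarray,
                  centroids: np.ndarray, labels: np.ndarray,
                  empty: np.ndarray, kind: str) -> np.ndarray:
    """Reseat each empty centroid at the point farthest from its own
    centroid (deterministic: empty slots in index order, distance ties to
    the lowest row index)."""
    dists = _point_dists(values_f, centroids, labels, kind)
    for j in np.sort(empty):
        i = int(dists.argmax())
        centroids[j] = values[i]
        dists[i] = -np.inf
    return centroids


def update_centroids_mean(X: DataMatrix, labels: np.ndarray, k: int,
                          workers: int = 1) -> np.ndarray:
    """Mean-update centroids for continuous data.

    Centroid j is the arithmetic mean of the rows labeled j, computed from
    per-block partial sums reduced in block order (worker-invariant).
    Empty clusters are reseated at the point farthest from its assigned
    centroid.
    """
    if X.kind != CONTINUOUS:
        raise MatrixError("mean update requires continuous data")
    values = X.values
    d = X.n_cols

    def work(sl: slice):
        sums = np.zeros((k, d))
        np.add.at(sums, labels[sl], values[sl])
        counts = np.bincount(labels[sl], minlength=k)
        return sums, counts

    parts = _run_blocks(work, _blocks(values.shape[0]), workers)
    sums = np.zeros((k, d))
    counts = np.zeros(k, dtype=np.int64)
    for s, c in parts:                 # fixed block order
        sums += s
        counts += c
    centroids = np.zeros((k, d))
    nonempty = counts > 0
    centroids[nonempty] = sums[nonempty] / counts[nonempty, None]
    if not nonempty.all():
        centroids = _reseat_empty(values, values, centroids, labels,
                                  np.flatnonzero(~nonempty), CONTINUOUS)
    return centroids


def update_centroids_mode(G: DataMatrix, labels: np.ndarray, k: int,
                          workers: int = 1) -> np.ndarray:
    """Mode-update centroids for genotype data.

    Per cluster and per locus the most frequent genotype wins; frequency
    ties break to the smallest genotype code. Empty clusters are reseated
    as in the mean update (with ASD distances).
    """
    if G.kind != GENOTYPE:
        raise MatrixError("mode update requires genotype data")
    values = G.values
    d = G.n_cols
    cols = np.arange(d)

    def work(sl: slice):
        counts = np.zeros((k, d, 3), dtype=np.int64)
        np.add.at(counts, (labels[sl][:, None], cols[None, :], values[sl]), 1)
        return counts

    parts = _run_blocks(work, _blocks(values.shape[0]), workers)
    counts = np.zeros((k, d, 3), dtype=np.int64)
    for c in parts:
        counts += c
    modes = counts.argmax(axis=2)      # ties -> smallest genotype code
    cluster_sizes = counts[:, 0, :].sum(axis=1)
    empty = np.flatnonzero(cluster_sizes == 0)
    if empty.size:
        values_f = values.astype(np.float64)
        modes = _reseat_empty(values, values_f, modes, labels, empty,
                              GENOTYPE)
    return modes


def quantization_error(X: DataMatrix, labels: np.ndarray,
                       centroids: np.ndarray) -> tuple[float, float]:
    """Sum (sse) and mean (mse) of per-object distances to the assigned
    centroid: squared Euclidean for continuous data, ASD for genotypes."""
    values_f = X.values.astype(np.float64, copy=False)
    dists = _point_dists(values_f, np.asarray(centroids), labels, X.kind)
    sse = float(dists.sum())
    return sse, sse / X.n_rows


def _seed_entropy(seed) -> tuple:
    if seed is None:
        return (int(np.random.SeedSequence().generate_state(1)[0]),)
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


def _restart_rng(entropy: tuple, restart: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy + (restart,)))


def _single_run(X: DataMatrix, k: int, max_iter: int, workers: int,
                rng: np.random.Generator, update_fn: Callable):
    """One Lloyd run from a random initialization.

    Returns the best full-support (no empty cluster) state visited, since
    the mode update need not decrease the allele-sharing objective on
    frequency ties; for k-means the objective is monotone, so the best
    state is simply the converged one.
    """
    values_f = X.values.astype(np.float64, copy=False)
    centroids = init_centroids(X, k, rng).astype(
        np.float64 if X.kind == CONTINUOUS else np.int64, copy=False
    )
    labels, _ = _assign(values_f, centroids, X.kind, workers)
    best = None
    iterations = 0
    converged = False
    for _ in range(max_iter):
        iterations += 1
        centroids = update_fn(X, labels, k, workers)
        obj = float(_point_dists(values_f, centroids, labels, X.kind).sum())
        if np.bincount(labels, minlength=k).min() > 0:
            if best is None or obj < best[2]:
                best = (labels.copy(), centroids.copy(), obj)
        new_labels, _ = _assign(values_f, centroids, X.kind, workers)
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    if best is None:
        # Degenerate path: no visited state used all k clusters. Force full
        # support by moving the farthest points into the missing clusters.
        dists = _point_dists(values_f, centroids, labels, X.kind)
        for j in np.flatnonzero(np.bincount(labels, minlength=k) == 0):
            i = int(dists.argmax())
            labels = labels.copy()
            labels[i] = j
            dists[i] = -np.inf
        centroids = update_fn(X, labels, k, workers)
        obj = float(_point_dists(values_f, centroids, labels, X.kind).sum())
        best = (labels, centroids, obj)
    return best[0], best[1], best[2], iterations, converged


def _cluster(X: DataMatrix, cfg: ClusterConfig,
             update_fn: Callable) -> ClusteringResult:
    cfg.validate(X.n_rows)
    entropy = _seed_entropy(cfg.seed)
    best = None
    for r in range(cfg.restarts):
        rng = _restart_rng(entropy, r)
        labels, centroids, sse, iters, conv = _single_run(
            X, cfg.k, cfg.max_iter, cfg.workers, rng, update_fn
        )
        if best is None or sse < best[2]:
            best = (labels, centroids, sse, iters, conv)
    labels, centroids, sse, iters, conv = best
    seed_used = entropy[0] if len(entropy) == 1 else entropy
    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        sse=sse,
        mse=sse / X.n_rows,
        iterations=iters,
        converged=conv,
        seed_used=seed_used,
    )


def kmeans(X: DataMatrix, cfg: ClusterConfig) -> ClusteringResult:
    """k-means on continuous data; best of ``cfg.restarts`` restarts by
    quantization error. Reproducible given ``cfg.seed``; identical for any
    ``cfg.workers``."""
    if X.kind != CONTINUOUS:
        raise MatrixError("kmeans requires a continuous matrix")
    return _cluster(X, cfg, update_centroids_mean)


def kmodes(G: DataMatrix, cfg: ClusterConfig) -> ClusteringResult:
    """k-modes on genotype data: ASD assignment, per-locus mode update;
    best restart by total ASD. Same determinism contract as :func:`kmeans`."""
    if G.kind != GENOTYPE:
        raise MatrixError("kmodes requires a genotype matrix")
    return _cluster(G, cfg, update_centroids_mode)
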