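"""Resampling-based cluster-number estimation.

For each candidate k, the data is repeatedly subsampled and clustered
(keeping, per subsample, the best of several restarts); all resulting
partitions are compared pairwise with the MCA index on the intersection
of their subsamples. The same is done for baseline partitions drawn under
a null hypothesis (random prototype by default) on independent subsamples
of the same size. The *gap* between the median clustering MCA and the
median baseline MCA measures how much more stable the clustering is than
chance; the best k maximizes the gap (ties to the smallest k). A
one-sided Mann-Whitney U test of clustering-MCA > baseline-MCA at the
best k rates significance; an insignificant gap at level alpha means no
structure was found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from .baselines import (
    BASELINE_KINDS,
    RANDOM_LABEL,
    RANDOM_PARTITION,
    RANDOM_PROTOTYPE,
    random_prototype_partition,
    sample_random_label,
    sample_random_partition,
)
from .cluster import ClusterConfig, ClusteringResult, kmeans, kmodes
from .matrix import CONTINUOUS, DataMatrix
from .partition import Partition, mca


@dataclass(frozen=True)
class ResamplingPlan:
    """Protocol parameters for one cluster-number estimation run.

    ``k_range`` is inclusive: (k_min, k_max) with k_min >= 2.
    ``subsample_size`` = rows retained per draw (default 90% of rows).
    ``reps_per_k`` clusterings (each the best of ``restarts_per_rep``
    restarts) and ``baseline_reps_per_k`` baseline draws per k.
    """

    k_range: tuple[int, int]
    reps_per_k: int = 10
    baseline_reps_per_k: int = 10
    subsample_size: int | None = None
    restarts_per_rep: int = 10
    baseline: str = RANDOM_PROTOTYPE
    max_iter: int = 100
    workers: int = 1
    alpha: float = 0.05
    seed: int | None = None

    @property
    def ks(self) -> list[int]:
        return list(range(self.k_range[0], self.k_range[1] + 1))

    def validate(self, n_rows: int | None = None) -> None:
        kmin, kmax = self.k_range
        if kmin < 2 or kmax < kmin:
            raise ValueError(f"need 2 <= k_min <= k_max, got {self.k_range}")
        if min(self.reps_per_k, self.baseline_reps_per_k,
               self.restarts_per_rep) < 1:
            raise ValueError("repetition counts must be >= 1")
        if self.baseline not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline {self.baseline!r}")
        if n_rows is not None:
            size = self.size_for(n_rows)
            if not 1 <= size <= n_rows:
                raise ValueError(
                    f"subsample_size {size} out of range for N={n_rows}"
                )
            if kmax >= size:
                raise ValueError(
                    f"k_max={kmax} must be below the subsample size {size}"
                )

    def size_for(self, n_rows: int) -> int:
        if self.subsample_size is not None:
            return self.subsample_size
        return max(1, int(round(0.9 * n_rows)))


@dataclass(frozen=True)
class StabilityProfile:
    """Per-k MCA distributions and the resulting model choice.

    ``gap[k] = median_cluster[k] - median_baseline[k]``; ``best_k``
    maximizes the gap; ``p_value`` is the one-sided Mann-Whitney p at
    ``best_k``; ``structure_found`` is False when that test is not
    significant at the plan's alpha.
    """

    ks: list[int]
    cluster_mca: dict[int, np.ndarray]
    baseline_mca: dict[int, np.ndarray]
    median_cluster: dict[int, float]
    median_baseline: dict[int, float]
    gap: dict[int, float]
    best_k: int
    p_value: float
    structure_found: bool
    seed_used: int
    baseline_kind: str = RANDOM_PROTOTYPE


def count_planned_runs(plan: ResamplingPlan) -> int:
    """Total scheduled runs: |k_range| x (clustering + baseline reps)."""
    plan.validate()
    return len(plan.ks) * (plan.reps_per_k + plan.baseline_reps_per_k)


def subsample(X: DataMatrix, size: int,
              rng: np.random.Generator) -> tuple[np.ndarray, DataMatrix]:
    """Uniform draw of ``size`` distinct row indices (returned sorted)
    together with the corresponding submatrix."""
    if not 1 <= size <= X.n_rows:
        raise ValueError(f"size {size} out of range 1..{X.n_rows}")
    idx = np.sort(rng.choice(X.n_rows, size=size, replace=False))
    return idx, X.take_rows(idx)


def rank_test(a, b) -> float:
    """One-sided Mann-Whitney U p-value for "a stochastically greater
    than b". Exact for small tie-free samples, normal approximation with
    tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank test requires two non-empty samples")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.5  # completely tied: no evidence either way
    small = a.size <= 25 and b.size <= 25
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (small and tie_free) else "asymptotic"
    return float(
        mannwhitneyu(a, b, alternative="greater", method=method).pvalue
    )


def select_best_clustering(X: DataMatrix, k_best: int, restarts: int,
                           seed: int | None = None,
                           max_iter: int = 100,
                           workers: int = 1) -> ClusteringResult:
    """Best-of-``restarts`` clustering of the full data at the selected k
    (k-means or k-modes by data kind)."""
    cfg = ClusterConfig(k=k_best, max_iter=max_iter, restarts=restarts,
                        workers=workers, seed=seed)
    return kmeans(X, cfg) if X.kind == CONTINUOUS else kmodes(X, cfg)


def _baseline_partition(kind: str, sub: DataMatrix, k: int,
                        rng: np.random.Generator) -> Partition:
    if kind == RANDOM_PROTOTYPE:
        return random_prototype_partition(sub, k, rng)
    if kind == RANDOM_LABEL:
        return sample_random_label(sub.n_rows, k, rng)
    if kind == RANDOM_PARTITION:
        return sample_random_partition(sub.n_rows, k, rng)
    raise ValueError(kind)


def _pairwise_mca(parts: list[Partition]) -> np.ndarray:
    vals = [
        mca(parts[i], parts[j]).value
        for i in range(len(parts))
        for j in range(i + 1, len(parts))
    ]
    return np.asarray(vals)


def run_stability(X: DataMatrix, plan: ResamplingPlan) -> StabilityProfile:
    """Execute the full cluster-number estimation protocol.

    Per-repetition RNG streams are derived deterministically from
    (seed, k, rep, role), so the profile is reproducible and independent
    of execution order or worker count.
    """
    plan.validate(X.n_rows)
    if plan.reps_per_k < 2 or plan.baseline_reps_per_k < 2:
        raise ValueError(
            "pairwise comparison needs at least 2 repetitions per group"
        )
    size = plan.size_for(X.n_rows)
    seed = (plan.seed if plan.seed is not None
            else int(np.random.SeedSequence().generate_state(1)[0]))

    cluster_mca: dict[int, np.ndarray] = {}
    baseline_mca: dict[int, np.ndarray] = {}
    for k in plan.ks:
        cluster_parts = []
        for rep in range(plan.reps_per_k):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, k, rep, 0))
            )
            idx, sub = subsample(X, size, rng)
            cfg = ClusterConfig(
                k=k, max_iter=plan.max_iter,
                restarts=plan.restarts_per_rep, workers=plan.workers,
                seed=(seed, k, rep, 1),
            )
            res = kmeans(sub, cfg) if X.kind == CONTINUOUS else kmodes(sub, cfg)
            cluster_parts.append(
                Partition(labels=res.labels, k=k, index_set=idx)
            )
        baseline_parts = []
        for rep in range(plan.baseline_reps_per_k):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, k, rep, 2))
            )
            idx, sub = subsample(X, size, rng)
            part = _baseline_partition(plan.baseline, sub, k, rng)
            baseline_parts.append(
                Partition(labels=part.labels, k=k, index_set=idx)
            )
        cluster_mca[k] = _pairwise_mca(cluster_parts)
        baseline_mca[k] = _pairwise_mca(baseline_parts)

    median_cluster = {k: float(np.median(v)) for k, v in cluster_mca.items()}
    median_baseline = {k: float(np.median(v)) for k, v in baseline_mca.items()}
    gap = {k: median_cluster[k] - median_baseline[k] for k in plan.ks}
    best_k = min(plan.ks, key=lambda k: (-gap[k], k))
    if cluster_mca[best_k].size and baseline_mca[best_k].size:
        p_value = rank_test(cluster_mca[best_k], baseline_mca[best_k])
    else:
        p_value = 1.0
    return StabilityProfile(
        ks=plan.ks,
        cluster_mca=cluster_mca,
        baseline_mca=baseline_mca,
        median_cluster=median_cluster,
        median_baseline=median_baseline,
        gap=gap,
        best_k=best_k,
        p_value=p_value,
        structure_found=bool(p_value < plan.alpha),
        seed_used=seed,
        baseline_kind=plan.baseline,
    )
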