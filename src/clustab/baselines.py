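"""Null models for cluster validity: three baseline hypotheses.

A clustering's similarity score only becomes interpretable against the
score expected when there is no structure. Three nulls of increasing
data-dependence are provided:

* **random label** — each object is assigned to one of k clusters
  uniformly, conditioned on no cluster being empty (worst case; lower
  bound of the expected MCA).
* **random partition** — a partition drawn uniformly from all S(n, k) set
  partitions into exactly k non-empty blocks (S = Stirling number of the
  second kind).
* **random prototype** — k prototypes are drawn from the data rows and
  each object joins its nearest prototype; data-driven, hence the
  tightest baseline for centroid-based clustering. Clusters can be empty.

Expected MCA values under a null are estimated by Monte Carlo over pairs
of independent baseline draws, mirroring how real clusterings are
compared pairwise in the stability protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import assign_to_nearest, DegenerateInputError
from .matrix import DataMatrix
from .partition import Partition, mca

RANDOM_LABEL = "random_label"
RANDOM_PARTITION = "random_partition"
RANDOM_PROTOTYPE = "random_prototype"

BASELINE_KINDS = (RANDOM_LABEL, RANDOM_PARTITION, RANDOM_PROTOTYPE)


@dataclass(frozen=True)
class BaselineExpectation:
    """Monte-Carlo estimate of E(MCA) under a baseline hypothesis."""

    n: int
    k: int
    kind: str
    expected: float
    reps: int
    stderr: float


def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k): the number of
    partitions of n objects into exactly k non-empty blocks."""
    if k < 0 or n < 0 or k > n:
        return 0
    return _stirling_table(n, k)[n][k]


def _stirling_table(n: int, k: int) -> list[list[int]]:
    # S(m, j) for all m <= n, j <= k via S(m,j) = j*S(m-1,j) + S(m-1,j-1).
    table = [[0] * (k + 1) for _ in range(n + 1)]
    table[0][0] = 1
    for m in range(1, n + 1):
        for j in range(1, min(m, k) + 1):
            table[m][j] = j * table[m - 1][j] + table[m - 1][j - 1]
    return table


def _check_nk(n: int, k: int) -> None:
    if not 0 < k <= n:
        raise ValueError(f"need 0 < k <= n, got k={k}, n={n}")


def sample_random_label(n: int, k: int,
                        rng: np.random.Generator) -> Partition:
    """Uniform surjective labeling: i.i.d. uniform labels, rejected until
    every cluster is non-empty."""
    _check_nk(n, k)
    while True:
        labels = rng.integers(k, size=n)
        if np.bincount(labels, minlength=k).min() > 0:
            return Partition(labels=labels, k=k)


def sample_random_partition(n: int, k: int,
                            rng: np.random.Generator) -> Partition:
    """Uniform draw from the S(n, k) set partitions into exactly k blocks.

    Sequential construction guided by the Stirling recurrence: the last
    element forms a new block with probability S(n-1, k-1) / S(n, k),
    otherwise it joins one of the k blocks of a uniform partition of the
    remaining elements, chosen uniformly. Blocks are indexed by first
    occurrence, 0..k-1.
    """
    _check_nk(n, k)
    table = _stirling_table(n, k)
    new_block = np.empty(n, dtype=bool)
    m, j = n, k
    while m > 0:
        if j == m:
            new_block[m - 1] = True
            j -= 1
        elif j == 1:
            new_block[m - 1] = m == 1
        else:
            if rng.random() < table[m - 1][j - 1] / table[m][j]:
                new_block[m - 1] = True
                j -= 1
            else:
                new_block[m - 1] = False
        m -= 1
    labels = np.empty(n, dtype=np.int64)
    opened = 0
    for i in range(n):
        if new_block[i]:
            labels[i] = opened
            opened += 1
        else:
            labels[i] = rng.integers(opened)
    return Partition(labels=labels, k=k)


def random_prototype_partition(X: DataMatrix, k: int,
                               rng: np.random.Generator) -> Partition:
    """Draw k prototype rows without replacement and assign every object
    to its nearest prototype (squared Euclidean / ASD by data kind; ties
    to the lowest prototype index). Empty clusters are possible."""
    n = X.n_rows
    if not 0 < k <= n:
        raise DegenerateInputError(f"need 0 < k <= N, got k={k}, N={n}")
    if k > np.unique(X.values, axis=0).shape[0]:
        raise DegenerateInputError(
            f"k={k} exceeds the number of distinct rows"
        )
    idx = rng.choice(n, size=k, replace=False)
    prototypes = X.values[idx]
    labels = assign_to_nearest(X, prototypes)
    return Partition(labels=labels, k=k)


def _draw(kind: str, n: int, k: int, rng: np.random.Generator,
          X: DataMatrix | None) -> Partition:
    if kind == RANDOM_LABEL:
        return sample_random_label(n, k, rng)
    if kind == RANDOM_PARTITION:
        return sample_random_partition(n, k, rng)
    if kind == RANDOM_PROTOTYPE:
        assert X is not None
        return random_prototype_partition(X, k, rng)
    raise ValueError(f"unknown baseline kind {kind!r}")


def expected_mca(n: int, k: int, kind: str, reps: int = 500,
                 rng: np.random.Generator | None = None,
                 X: DataMatrix | None = None) -> BaselineExpectation:
    """Monte-Carlo mean pairwise MCA between independent baseline draws.

    ``X`` is required for (and only used by) the random-prototype
    hypothesis, whose draws are data-driven; then n is taken from X.
    """
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}")
    if kind == RANDOM_PROTOTYPE:
        if X is None:
            raise ValueError("random_prototype baseline requires the data X")
        n = X.n_rows
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    values = np.empty(reps)
    for r in range(reps):
        p = _draw(kind, n, k, rng, X)
        q = _draw(kind, n, k, rng, X)
        values[r] = mca(p, q).value
    stderr = float(values.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return BaselineExpectation(
        n=n, k=k, kind=kind, expected=float(values.mean()),
        reps=reps, stderr=stderr,
    )
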