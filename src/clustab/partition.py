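"""Partition comparison via the maximum cluster assignment (MCA) index.

Two partitions of the same objects are compared by counting, for every
pair of clusters, how many objects they share (the contingency table) and
then finding the bijective cluster matching that maximizes the total
overlap — a linear assignment problem. The MCA index is the matched count
divided by the number of objects: the proportion of objects consistently
co-assigned under the best cluster correspondence. It lies in (0, 1], is
1 exactly when the partitions are identical up to relabeling, and is
linear in the number of objects (unlike pair-counting indices such as
Rand or Jaccard).

Partitions defined on different subsamples are compared on the
intersection of their index sets; unequal cluster counts are handled by
zero-padding the contingency table to square, which cannot change the
optimal matched count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy.optimize import linear_sum_assignment


class PartitionError(ValueError):
    """Raised for malformed partitions or incomparable index sets."""


@dataclass(frozen=True)
class Partition:
    """A labeling of n objects into k clusters (indices 0..k-1).

    ``index_set`` identifies the underlying objects, so partitions of
    different subsamples of one dataset can be intersected. Clusters may
    be empty (e.g. a prototype baseline draw); samplers that guarantee
    non-emptiness document it.
    """

    labels: np.ndarray
    k: int
    index_set: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise PartitionError("labels must be a non-empty 1-D vector")
        if self.k < 1 or labels.min() < 0 or labels.max() >= self.k:
            raise PartitionError(
                f"labels must lie in [0, k={self.k})"
            )
        object.__setattr__(self, "labels", labels)
        idx = (np.arange(labels.size) if self.index_set is None
               else np.asarray(self.index_set))
        if idx.shape != labels.shape:
            raise PartitionError("index_set length must match labels")
        if np.unique(idx).size != idx.size:
            raise PartitionError("index_set contains duplicates")
        object.__setattr__(self, "index_set", idx)

    @property
    def n(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ContingencyTable:
    """k x k matrix of cluster intersection sizes; entries sum to n."""

    counts: np.ndarray
    n: int


@dataclass(frozen=True)
class MCAResult:
    """MCA index ``value`` = ``matched`` / ``n`` with the optimal cluster
    bijection ``mapping`` (cluster i of P corresponds to mapping[i] of Q)."""

    value: float
    mapping: np.ndarray
    matched: int
    n: int


@dataclass(frozen=True)
class CorrectedIndex:
    """Chance-corrected index: (raw - expected) / (max - expected)."""

    raw: float
    expected: float
    max: float
    corrected: float


def contingency(p: Partition, q: Partition) -> ContingencyTable:
    """Cluster intersection counts of two partitions, restricted to the
    common index set and padded to a common square cluster count."""
    common, ia, ib = np.intersect1d(
        p.index_set, q.index_set, return_indices=True
    )
    if common.size == 0:
        raise PartitionError("partitions share no objects")
    k = max(p.k, q.k)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (p.labels[ia], q.labels[ib]), 1)
    return ContingencyTable(counts=counts, n=int(common.size))


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return np.asarray(table, dtype=np.int64)


def solve_assignment(table) -> tuple[np.ndarray, int]:
    """Maximum-weight bijection over a square nonnegative table.

    Returns the optimal mapping (row i -> column mapping[i]) and the
    maximized total overlap. Any optimal bijection may be returned on
    ties; the optimum value is unique.
    """
    counts = _as_counts(table)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise PartitionError(f"assignment table must be square, got {counts.shape}")
    rows, cols = linear_sum_assignment(counts, maximize=True)
    mapping = np.empty(counts.shape[0], dtype=np.int64)
    mapping[rows] = cols
    matched = int(counts[rows, cols].sum())
    return mapping, matched


def mca(p: Partition, q: Partition) -> MCAResult:
    """Maximum cluster assignment index between two partitions."""
    table = contingency(p, q)
    mapping, matched = solve_assignment(table)
    return MCAResult(
        value=matched / table.n, mapping=mapping, matched=matched, n=table.n
    )


def mca_lower_bound(n: int, k: int) -> float:
    """Deterministic floor of the MCA index for partitions into k clusters
    of n objects: ceil(n / k) / n (averaging over all bijections)."""
    return ceil(n / k) / n


def mapping_accuracy(table) -> float:
    """Best-bijection agreement proportion of a contingency table.

    Accepts a :class:`ContingencyTable` or a plain (possibly rectangular)
    count matrix, e.g. clusters vs known population labels; rectangular
    input is zero-padded to square before solving.
    """
    counts = _as_counts(table)
    if counts.ndim != 2:
        raise PartitionError("expected a 2-D count table")
    n = int(counts.sum())
    if n == 0:
        raise PartitionError("empty contingency table")
    r, s = counts.shape
    k = max(r, s)
    if r != s:
        padded = np.zeros((k, k), dtype=counts.dtype)
        padded[:r, :s] = counts
        counts = padded
    _, matched = solve_assignment(counts)
    return matched / n


def corrected_index(raw: float, expected: float,
                    max_value: float = 1.0) -> CorrectedIndex:
    """Correct a validity index for chance agreement under a null model."""
    if expected >= max_value:
        raise ValueError(
            f"expected index {expected} must be below its maximum {max_value}"
        )
    corrected = (raw - expected) / (max_value - expected)
    return CorrectedIndex(
        raw=raw, expected=expected, max=max_value, corrected=corrected
    )
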