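"""Shared brute-force oracles for the test suite.

These are deliberately naive (exhaustive enumeration) and independent of
the library code paths they validate.
"""

from itertools import permutations

import numpy as np
import pytest


def set_partitions(n, k=None):
    """All set partitions of range(n), optionally into exactly k blocks.

    Yields lists of blocks (lists of indices); blocks ordered by first
    element.
    """

    def rec(i, blocks):
        if i == n:
            if k is None or len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        for b in blocks:
            b.append(i)
            yield from rec(i + 1, blocks)
            b.pop()
        if k is None or len(blocks) < k:
            blocks.append([i])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def blocks_to_labels(blocks, n):
    labels = np.empty(n, dtype=np.int64)
    for j, b in enumerate(blocks):
        labels[b] = j
    return labels


def brute_kmeans_objective(values, k):
    """Minimum sum of squared distances to mean centroids over all set
    partitions into exactly k non-empty blocks."""
    values = np.asarray(values, dtype=float)
    best = np.inf
    for blocks in set_partitions(len(values), k):
        sse = 0.0
        for b in blocks:
            pts = values[b]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def mode_smallest_tie(column):
    counts = np.bincount(column, minlength=3)
    return int(counts.argmax())


def brute_kmodes_objective(values, k):
    """Minimum total allele-sharing distance to mode centroids (ties to
    the smallest genotype code) over all k-block set partitions."""
    values = np.asarray(values, dtype=np.int64)
    best = np.inf
    for blocks in set_partitions(len(values), k):
        total = 0
        for b in blocks:
            pts = values[b]
            mode = np.array([mode_smallest_tie(pts[:, j])
                             for j in range(pts.shape[1])])
            total += np.abs(pts - mode).sum()
        best = min(best, total)
    return float(best)


def brute_max_assignment(counts):
    """Exhaustive maximum-weight bijection value of a square table."""
    counts = np.asarray(counts)
    m = counts.shape[0]
    return max(
        sum(counts[i, p[i]] for i in range(m))
        for p in permutations(range(m))
    )


def brute_mca(labels_p, labels_q, k):
    """MCA by direct counting and exhaustive permutation search."""
    labels_p = np.asarray(labels_p)
    labels_q = np.asarray(labels_q)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in zip(labels_p, labels_q):
        counts[a, b] += 1
    return brute_max_assignment(counts) / len(labels_p)


@pytest.fixture
def rng():
    return np.random.default_rng(20241006)
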