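"""Brute-force reference computations for validating the clustering core.

These enumerate every partition of n points into k non-empty blocks and score
each directly from first principles.  They are exponential in n and exist
solely as independent ground truth for small instances (n <= ~12); nothing in
the production path calls them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def partitions_into_k(n: int, k: int):
    """Yield every partition of range(n) into exactly k non-empty blocks.

    Partitions are generated in restricted-growth-string order: element 0 is
    always in block 0, and element i may open at most one new block.
    """
    def rec(i, blocks, n_used):
        if i == n:
            if n_used == k:
                yield [list(b) for b in blocks]
            return
        remaining_after = n - i - 1
        # join an existing block only if enough elements remain to open the
        # k - n_used still-missing blocks
        if remaining_after >= k - n_used:
            for b in range(n_used):
                blocks[b].append(i)
                yield from rec(i + 1, blocks, n_used)
                blocks[b].pop()
        if n_used < k:
            blocks.append([i])
            yield from rec(i + 1, blocks, n_used + 1)
            blocks.pop()

    yield from rec(0, [], 0)


def partition_wcss(X: np.ndarray, blocks) -> float:
    """WCSS of a partition, computed directly: sum of squared deviations
    from each block's mean."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    total = 0.0
    for block in blocks:
        pts = X[list(block)]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def global_minimum_wcss(X, k: int) -> tuple[float, list[list[int]]]:
    """Exhaustively minimal WCSS over all partitions into k non-empty blocks."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    best = (np.inf, None)
    for blocks in partitions_into_k(n, k):
        w = partition_wcss(X, blocks)
        if w < best[0]:
            best = (w, [list(b) for b in blocks])
    return best


def best_two_partition_1d(values) -> tuple[float, tuple, tuple]:
    """Optimal 2-partition of a 1-D point set by direct enumeration of subsets."""
    values = list(values)
    n = len(values)
    idx = range(n)
    best = (np.inf, None, None)
    for size in range(1, n):
        for left in combinations(idx, size):
            right = tuple(i for i in idx if i not in left)
            w = partition_wcss(np.array(values), [list(left), list(right)])
            if w < best[0]:
                best = (w, left, right)
    return best
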