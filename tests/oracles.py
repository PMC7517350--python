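"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (full pairwise
recomputation, explicit enumeration) rather than calling the package's own
code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def naive_agglomerate(vectors=None, linkage: str = "single", base_dist=None):
    """O(N^3) agglomeration recomputing every cluster distance from scratch.

    Cluster distances are evaluated directly over all member-pair node
    distances at every step (no incremental updates); node distances are
    Euclidean over ``vectors`` or taken from ``base_dist``.  Ties break
    toward the smallest (i, j) id pair.  Returns
    [(step, left, right, new, distance), ...] with leaf ids 1..N and new
    ids N+1..2N-1.
    """
    if base_dist is None:
        X = np.asarray(vectors, dtype=float)
        n = len(X)
        node_d = lambda p, q: float(np.linalg.norm(X[p] - X[q]))  # noqa: E731
    else:
        base = np.asarray(base_dist, dtype=float)
        n = len(base)
        node_d = lambda p, q: float(base[p, q])  # noqa: E731
    clusters = {i + 1: [i] for i in range(n)}
    merges = []
    for step in range(1, n):
        best = None
        for a, b in combinations(sorted(clusters), 2):
            dists = [
                node_d(p, q)
                for p in clusters[a] for q in clusters[b]
            ]
            if linkage == "single":
                d = min(dists)
            elif linkage == "complete":
                d = max(dists)
            else:
                d = float(np.mean(dists))
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        new = n + step
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((step, a, b, new, d))
    return merges


def brute_rank_sum_p(a, b) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    U is computed by direct pairwise comparison (wins + half-ties), never
    via ranks.  Returns (U of sample a, two-sided p).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n1 = len(a)
    pooled = a + b

    def u_of(first):
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(first)]
        u = 0.0
        for x in (pooled[i] for i in first):
            for y in rest:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in combinations(range(len(pooled)), n1)]
    lo = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def random_connectivity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random valid connectivity matrix: symmetric, zero diagonal, [0,1]."""
    m = rng.uniform(0.0, 1.0, size=(n, n))
    upper = np.triu(m, k=1)
    return upper + upper.T
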