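"""Independent brute-force graph oracles used to validate the network module.

Everything here works on a plain 0/1 adjacency matrix and deliberately avoids
the package's own graph code paths: degree by row sums, clustering by explicit
neighbour-pair enumeration, closeness via Floyd-Warshall, betweenness via
Floyd-Warshall shortest-path counting.
"""

from __future__ import annotations

import numpy as np

INF = float("inf")


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, k=1)
    return a + a.T


def brute_degree(a: np.ndarray, i: int) -> int:
    return int(a[i].sum())


def brute_clustering(a: np.ndarray, i: int) -> float:
    nbrs = np.nonzero(a[i])[0]
    d = len(nbrs)
    if d <= 1:
        return 0.0
    e = 0
    for x in range(d):
        for y in range(x + 1, d):
            e += a[nbrs[x], nbrs[y]]
    return 2.0 * e / (d * (d - 1))


def floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_closeness(a: np.ndarray, i: int, d: np.ndarray | None = None) -> float:
    if d is None:
        d = floyd_warshall(a)
    reach = np.isfinite(d[i])
    total = d[i][reach].sum()
    if total == 0:
        return 0.0
    return (int(reach.sum()) - 1) / total


def shortest_path_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distances, counts): number of distinct shortest paths per pair."""
    n = a.shape[0]
    d = floyd_warshall(a)
    cnt = np.zeros((n, n))
    np.fill_diagonal(cnt, 1.0)
    cnt[a > 0] = 1.0
    # count paths in order of increasing distance
    finite = sorted({d[i, j] for i in range(n) for j in range(n)
                     if np.isfinite(d[i, j]) and d[i, j] >= 2})
    for dist in finite:
        for i in range(n):
            for j in range(n):
                if d[i, j] == dist:
                    total = 0.0
                    for k in np.nonzero(a[i])[0]:
                        if d[i, k] + d[k, j] == d[i, j]:
                            total += cnt[k, j]
                    cnt[i, j] = total
    return d, cnt


def brute_betweenness(a: np.ndarray, i: int,
                      precomputed: tuple[np.ndarray, np.ndarray] | None = None,
                      ) -> float:
    """Sum over unordered pairs {j,k} (both != i) of the fraction of their
    shortest paths passing through i."""
    n = a.shape[0]
    d, cnt = precomputed if precomputed is not None else shortest_path_counts(a)
    total = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            if j == i or k == i:
                continue
            if not np.isfinite(d[j, k]) or cnt[j, k] == 0:
                continue
            if d[j, i] + d[i, k] == d[j, k]:
                total += cnt[j, i] * cnt[i, k] / cnt[j, k]
    return total
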