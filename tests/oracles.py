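"""Independent brute-force oracles for small graphs.

Everything here enumerates paths exhaustively and is exponential in
graph size; it exists only to cross-check the package's BFS/Brandes
implementations on graphs with at most ~8 nodes.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def all_simple_paths(a: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    n = a.shape[0]
    out: list[tuple[int, ...]] = []

    def walk(path: list[int]):
        v = path[-1]
        if v == t:
            out.append(tuple(path))
            return
        for w in range(n):
            if a[v, w] and w not in path:
                walk(path + [w])

    walk([s])
    return out


def brute_distances(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_simple_paths(a, s, t)
            if paths:
                d[s, t] = min(len(p) - 1 for p in paths)
    return d


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Fractional shortest-path counts through each node, endpoints excluded."""
    n = a.shape[0]
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_simple_paths(a, s, t)
            if not paths:
                continue
            L = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == L]
            for p in shortest:
                for v in p[1:-1]:
                    b[v] += 1.0 / len(shortest)
    return b


def brute_closeness_reciprocal_mean(a: np.ndarray) -> np.ndarray:
    d = brute_distances(a)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        reach = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if reach:
            c[i] = 1.0 / (sum(reach) / len(reach))
    return c


def brute_average_path_length(a: np.ndarray) -> float:
    d = brute_distances(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(i + 1, n) if np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    cc = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(a[u, v] for u in nbrs for v in nbrs if u < v)
        cc[i] = 2.0 * links / (k * (k - 1))
    return cc


def best_modularity_partition(a: np.ndarray) -> float:
    """Exhaustive maximum modularity over all partitions (tiny n only)."""
    from ptnet.graph_metrics import modularity

    n = a.shape[0]

    def partitions(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [subset + [first]] + smaller[i + 1 :]
            yield smaller + [[first]]

    best = -1.0
    for part in partitions(list(range(n))):
        labels = np.zeros(n, int)
        for lab, block in enumerate(part):
            labels[block] = lab
        best = max(best, modularity(a, labels))
    return best
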