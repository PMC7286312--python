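"""Brute-force reference implementations for small networks.

These deliberately share no code with the package: shortest paths are found
by exhaustive enumeration of simple paths, triplet statistics by explicit
three-node loops. Feasible only for a handful of nodes, which is all the
oracle-equivalence tests need.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def _all_simple_paths(adj: np.ndarray, src: int, dst: int):
    """Yield every simple path src -> dst along nonzero edges."""
    n = adj.shape[0]
    stack = [(src, (src,))]
    while stack:
        node, path = stack.pop()
        if node == dst:
            yield path
            continue
        for nxt in range(n):
            if adj[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + (nxt,)))


def shortest_paths_brute(adj: np.ndarray, src: int, dst: int):
    """(min length, list of minimizing paths) under edge length 1/weight."""
    best = np.inf
    best_paths = []
    for path in _all_simple_paths(adj, src, dst):
        length = sum(1.0 / adj[a, b] for a, b in zip(path, path[1:]))
        if length < best - 1e-12:
            best, best_paths = length, [path]
        elif abs(length - best) <= 1e-12:
            best_paths.append(path)
    return best, best_paths


def global_efficiency_brute(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d, _ = shortest_paths_brute(adj, i, j)
            if np.isfinite(d) and d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Raw betweenness: per unordered pair, fraction of shortest paths
    through each interior node."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            d, paths = shortest_paths_brute(adj, h, j)
            if not np.isfinite(d) or not paths:
                continue
            for path in paths:
                for node in path[1:-1]:
                    bc[node] += 1.0 / len(paths)
    return bc


def transitivity_brute(adj: np.ndarray) -> float:
    """Weighted triplet ratio with max-normalized cube-root weights."""
    n = adj.shape[0]
    w_max = adj.max()
    w = adj / w_max if w_max > 0 else adj
    num = 0.0
    denom = 0.0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) < 3:
                    continue
                if adj[i, j] > 0 and adj[i, k] > 0:
                    denom += 1.0
                    if adj[j, k] > 0:
                        num += (w[i, j] * w[i, k] * w[j, k]) ** (1.0 / 3.0)
    return num / denom if denom > 0 else 0.0


def clustering_brute(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    w_max = adj.max()
    w = adj / w_max if w_max > 0 else adj
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        v = len(nbrs)
        if v < 2:
            continue
        s = 0.0
        for j in nbrs:
            for k in nbrs:
                if j != k and adj[j, k] > 0:
                    s += (w[i, j] * w[i, k] * w[j, k]) ** (1.0 / 3.0)
        out[i] = s / (v * (v - 1))
    return out


def spearman_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (textbook Spearman)."""

    def avg_ranks(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def knn_region_brute(coords: np.ndarray, seed: int, k: int) -> set[int]:
    """Seed plus k-1 nearest contacts; ties to lowest index."""
    d = np.linalg.norm(coords - coords[seed], axis=1)
    candidates = sorted(
        (i for i in range(len(coords)) if i != seed),
        key=lambda i: (d[i], i),
    )
    return {seed, *candidates[: k - 1]}
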