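"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — exhaustive path enumeration,
term-by-term sums, truncated series — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_simple_paths(A: np.ndarray, s: int, t: int):
    """All simple paths s -> t in the weighted adjacency A (0 = no edge),
    yielded as (path, length) with length = sum of 1/weight edge lengths."""
    n = A.shape[0]

    def rec(path, length):
        u = path[-1]
        if u == t:
            yield list(path), length
            return
        for v in range(n):
            if A[u, v] > 0 and v not in path:
                path.append(v)
                yield from rec(path, length + 1.0 / A[u, v])
                path.pop()

    yield from rec([s], 0.0)


def brute_force_shortest_paths(A: np.ndarray):
    """For every unordered pair: shortest length and the list of minimal
    paths, by exhaustive simple-path enumeration."""
    n = A.shape[0]
    out = {}
    for s in range(n):
        for t in range(s + 1, n):
            best = math.inf
            paths = []
            for path, length in enumerate_simple_paths(A, s, t):
                if length < best - 1e-12:
                    best = length
                    paths = [path]
                elif abs(length - best) <= 1e-12:
                    paths.append(path)
            out[(s, t)] = (best, paths)
    return out


def brute_force_betweenness(A: np.ndarray):
    """Unnormalised node and edge betweenness from exhaustive enumeration."""
    n = A.shape[0]
    node = np.zeros(n)
    edge = np.zeros((n, n))
    for (s, t), (best, paths) in brute_force_shortest_paths(A).items():
        if not math.isfinite(best) or not paths:
            continue
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                node[v] += 1.0 / sigma
            for u, v in zip(path[:-1], path[1:]):
                edge[u, v] += 1.0 / sigma
                edge[v, u] += 1.0 / sigma
    return node, edge


def brute_force_global_efficiency(A: np.ndarray) -> float:
    """Mean inverse distance via Floyd-Warshall on 1/weight lengths."""
    n = A.shape[0]
    D = np.full((n, n), math.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j] > 0:
                D[i, j] = 1.0 / A[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def brute_force_clustering(A: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by direct triple loops."""
    n = A.shape[0]
    mx = A.max()
    if mx == 0:
        return np.zeros(n)
    W = A / mx
    out = np.zeros(n)
    for u in range(n):
        k = int(np.sum(A[u] > 0))
        if k < 2:
            continue
        acc = 0.0
        for v in range(n):
            for w in range(n):
                if v != u and w != u and v != w:
                    acc += (W[u, v] * W[v, w] * W[w, u]) ** (1.0 / 3.0)
        out[u] = acc / (k * (k - 1))
    return out


def taylor_communicability(A: np.ndarray, terms: int = 50) -> np.ndarray:
    """Row sums of the normalised-adjacency exponential via a truncated
    Taylor series."""
    s = A.sum(axis=1)
    d = np.where(s > 0, s, 1.0)
    inv = 1.0 / np.sqrt(d)
    An = A * inv[:, None] * inv[None, :]
    n = A.shape[0]
    acc = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms + 1):
        term = term @ An / k
        acc = acc + term
    return acc.sum(axis=1)


def random_weighted_graph(n: int, rng: np.random.Generator, density: float = 0.5) -> np.ndarray:
    """Random symmetric weighted adjacency with irrational-ish weights so
    shortest-path ties are non-degenerate."""
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                A[i, j] = A[j, i] = rng.uniform(0.2, 3.0)
    return A


def exhaustive_permutation_pvalue(g1, g2):
    """Exact two-sided permutation p-value over all label assignments,
    with the same add-one correction as the implementation."""
    pooled = list(g1) + list(g2)
    n1 = len(g1)
    obs = abs(np.mean(pooled[:n1]) - np.mean(pooled[n1:]))
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        t = abs(np.mean(a) - np.mean(b))
        total += 1
        if t >= obs - 1e-12:
            count += 1
    return count / total
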