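"""Independent brute-force oracles for graph metrics.

Deliberately naive implementations — explicit enumeration over nodes, pairs
and triples — used only to cross-check the production metric code.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def triangles_and_triples(adj: np.ndarray) -> tuple[int, int]:
    n = adj.shape[0]
    triangles = 0
    triples = 0
    for i, j, k in itertools.combinations(range(n), 3):
        edges = adj[i, j] + adj[i, k] + adj[j, k]
        if edges == 3:
            triangles += 1
        # count connected triples (paths of length 2) centred at each node
    for centre in range(n):
        neigh = [v for v in range(n) if adj[centre, v]]
        triples += len(neigh) * (len(neigh) - 1) // 2
    return triangles, triples


def transitivity_oracle(adj: np.ndarray) -> float:
    triangles, triples = triangles_and_triples(adj)
    if triples == 0:
        return 0.0
    return 3.0 * triangles / triples


def shortest_paths_bfs(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        q = deque([src])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and dist[src, v] == np.inf:
                    dist[src, v] = dist[src, u] + 1
                    q.append(v)
    return dist


def efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_paths_bfs(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def assortativity_oracle(adj: np.ndarray) -> float:
    deg = adj.sum(axis=1)
    xs, ys = [], []
    n = adj.shape[0]
    for i in range(n):
        for j in range(n):
            if adj[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return float("nan")
    xs, ys = np.array(xs, float), np.array(ys, float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


def max_degree_oracle(adj: np.ndarray) -> int:
    if adj.shape[0] == 0:
        return 0
    return int(adj.sum(axis=1).max())


def rich_club_oracle(adj: np.ndarray, k: int) -> float:
    deg = adj.sum(axis=1)
    rich = [i for i in range(adj.shape[0]) if deg[i] > k]
    if len(rich) < 2:
        return float("nan")
    links = sum(
        adj[i, j] for a, i in enumerate(rich) for j in rich[a + 1 :]
    )
    m = len(rich)
    return 2.0 * links / (m * (m - 1))


def nestedness_oracle(adj: np.ndarray) -> float:
    """Pairwise overlap with the mutual link excluded, set arithmetic."""
    n = adj.shape[0]
    if adj.sum() == 0:
        return float("nan")
    scores = []
    for i, j in itertools.combinations(range(n), 2):
        ni = {v for v in range(n) if adj[i, v]} - {j}
        nj = {v for v in range(n) if adj[j, v]} - {i}
        small, big = sorted((ni, nj), key=len)
        if not small:
            continue
        scores.append(100.0 * len(small & big) / len(small))
    return float(np.mean(scores)) if scores else float("nan")


def modularity_oracle(adj: np.ndarray, communities: list[set[int]]) -> float:
    """Direct Q formula: sum_c (e_c - a_c^2) over edge fractions."""
    two_m = adj.sum()
    if two_m == 0:
        return float("nan")
    deg = adj.sum(axis=1)
    q = 0.0
    for comm in communities:
        comm = list(comm)
        e_c = adj[np.ix_(comm, comm)].sum() / two_m
        a_c = deg[comm].sum() / two_m
        q += e_c - a_c**2
    return q


def all_graphs(n: int):
    """Yield every labelled simple graph on n nodes as an adjacency matrix."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=int)
        for b, (i, j) in enumerate(pairs):
            if bits >> b & 1:
                adj[i, j] = adj[j, i] = 1
        yield adj


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    adj = np.triu((rng.random((n, n)) < p).astype(int), 1)
    return adj + adj.T
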