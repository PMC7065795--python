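"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or scalar
hand iteration, deliberately sharing no code with the implementation it
checks.
"""

from __future__ import annotations

import heapq
import itertools

import networkx as nx
import numpy as np


def all_spanning_tree_edges(n: int) -> np.ndarray:
    """Edge lists of all n^(n-2) labeled spanning trees on n nodes,
    enumerated by decoding every Pruefer sequence.  Shape (T, n-1, 2)."""
    trees = []
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        heap = [i for i in range(n) if degree[i] == 1]
        heapq.heapify(heap)
        deg = degree[:]
        edges = []
        for v in seq:
            leaf = heapq.heappop(heap)
            edges.append((leaf, v))
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u, w = heapq.heappop(heap), heapq.heappop(heap)
        edges.append((u, w))
        trees.append(edges)
    return np.array(trees)


def min_spanning_total(dist: np.ndarray, trees: np.ndarray) -> float:
    """Minimum total distance over an explicit tree enumeration."""
    return float(dist[trees[:, :, 0], trees[:, :, 1]].sum(axis=1).min())


def scalar_autocm(x, C: float, epochs: int):
    """Hand-iterated Auto-CM updates with plain Python floats (one pattern)."""
    n = len(x)
    v = [1e-5] * n
    W = [[1e-5] * n for _ in range(n)]
    for _ in range(epochs):
        h = [x[j] * (1 - v[j] / C) for j in range(n)]
        dv = [(x[j] - h[j]) * (1 - v[j] / C) for j in range(n)]
        net = [sum(h[j] * (1 - W[i][j] / C) for j in range(n)) for i in range(n)]
        o = [h[i] * (1 - net[i] / C) for i in range(n)]
        dW = [
            [(h[i] - o[i]) * (1 - W[i][j] / C) * h[j] for j in range(n)]
            for i in range(n)
        ]
        v = [v[j] + dv[j] for j in range(n)]
        W = [[W[i][j] + dW[i][j] for j in range(n)] for i in range(n)]
    return v, W


def quadruple_loop_autocm_cost(U: np.ndarray, W: np.ndarray, C: float) -> float:
    """Naive Σ_q Σ_i Σ_j Σ_k u_iq·u_jq·u_kq·A_ij·A_ik with A = 1 − W/C."""
    A = 1.0 - W / C
    M, N = U.shape
    total = 0.0
    for q in range(M):
        for i in range(N):
            for j in range(N):
                for k in range(N):
                    total += U[q, i] * U[q, j] * U[q, k] * A[i, j] * A[i, k]
    return total


def triple_loop_traditional_cost(U: np.ndarray, sigma: np.ndarray) -> float:
    M, N = U.shape
    total = 0.0
    for q in range(M):
        for i in range(N):
            for j in range(N):
                total += U[q, i] * U[q, j] * sigma[i, j]
    return total


def nx_hubness(g: nx.Graph) -> float:
    """Hubness recomputed with networkx's generic simple-cycle enumerator."""
    n = g.number_of_nodes()
    cycles = sum(1 for c in nx.simple_cycles(g, length_bound=4) if len(c) >= 3)
    return cycles / (1.0 + g.number_of_edges() - (n - 1))


def mrg_prefix_max_hubness(dist: np.ndarray, mst: nx.Graph, max_extra: int) -> float:
    """Exhaustive prefix search for the best achievable hubness."""
    names = list(mst.nodes)
    index = {v: i for i, v in enumerate(names)}
    cands = sorted(
        (
            (dist[index[a], index[b]], a, b)
            for a, b in itertools.combinations(names, 2)
            if not mst.has_edge(a, b)
        ),
        key=lambda t: (t[0], str(t[1]), str(t[2])),
    )[:max_extra]
    g = mst.copy()
    best = nx_hubness(g)
    for _, a, b in cands:
        g.add_edge(a, b)
        best = max(best, nx_hubness(g))
    return best
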