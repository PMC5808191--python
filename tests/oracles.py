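"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (explicit formulas,
exhaustive enumeration, Floyd-Warshall) and deliberately shares no code
with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_formula(x, y) -> float:
    """Direct sum-form Pearson correlation Σ(x-x̄)(y-ȳ)/(σx σy n)."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (sx * sy)


def degrees_by_edge_count(adj) -> list[int]:
    """Degree of each node by explicit edge-list enumeration."""
    n = len(adj)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if adj[i][j]]
    deg = [0] * n
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    return deg


def floyd_warshall(adj, sentinel: int | None = None) -> np.ndarray:
    """All-pairs hop distances by the classic triple loop."""
    n = len(adj)
    if sentinel is None:
        sentinel = n
    inf = float("inf")
    d = [[0 if i == j else (1 if adj[i][j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    out = np.array([[sentinel if v == inf else int(v) for v in row] for row in d])
    return out


def clustering_by_triples(adj) -> np.ndarray:
    """C_i by enumerating all closed triples over node triples."""
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if adj[nbrs[a]][nbrs[b]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def local_efficiency_by_enumeration(adj) -> np.ndarray:
    """E_loc,i by brute force over neighbour pairs of each node.

    Distances are taken on the subgraph induced by the neighbours of i
    (node i removed); unreachable pairs contribute zero.
    """
    n = len(adj)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        d = floyd_warshall(sub, sentinel=10**9)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and d[a][b] < 10**9:
                    total += 1.0 / d[a][b]
        out[i] = total / (k * (k - 1))
    return out


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """A random symmetric binary adjacency with zero diagonal."""
    u = rng.random((n, n))
    upper = np.triu(u < p, 1).astype(int)
    return upper + upper.T
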