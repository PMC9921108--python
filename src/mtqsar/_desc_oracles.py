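"""Brute-force oracle implementations of the descriptor registry.

Deliberately naive and algorithmically independent of the fast path: shortest
paths by Floyd–Warshall over an explicit adjacency list, path counts by
exhaustive depth-first enumeration of simple paths.  Used by
:func:`mtqsar.descriptors.oracle_check` and the test suite; performance is a
non-goal (graphs here are molecule-sized).
"""

from __future__ import annotations

import math

INF = float("inf")


def _edges(G) -> list[tuple[int, int]]:
    return [(int(u), int(v)) for u, v in G.edges()]


def _adj(G) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {int(n): [] for n in G.nodes()}
    for u, v in _edges(G):
        adj[u].append(v)
        adj[v].append(u)
    return adj


def _floyd_warshall(G) -> dict[tuple[int, int], float]:
    nodes = sorted(int(n) for n in G.nodes())
    D = {(i, j): (0.0 if i == j else INF) for i in nodes for j in nodes}
    for u, v in _edges(G):
        D[(u, v)] = D[(v, u)] = 1.0
    for k in nodes:
        for i in nodes:
            for j in nodes:
                via = D[(i, k)] + D[(k, j)]
                if via < D[(i, j)]:
                    D[(i, j)] = via
    return D


def _simple_paths(G, length: int) -> list[tuple[int, ...]]:
    """All simple paths with `length` edges, one orientation each."""
    adj = _adj(G)
    found: set[tuple[int, ...]] = set()

    def extend(path: tuple[int, ...]):
        if len(path) == length + 1:
            found.add(min(path, path[::-1]))
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + (nxt,))

    for start in adj:
        extend((start,))
    return sorted(found)


def _degree(G) -> dict[int, int]:
    return {n: len(nbrs) for n, nbrs in _adj(G).items()}


def heavy_atom_count(G) -> float:
    return float(len(list(G.nodes())))


def bond_count(G) -> float:
    return float(len(_edges(G)))


def ring_count(G) -> float:
    return float(len(_edges(G)) - len(list(G.nodes())) + 1)


def wiener(G) -> float:
    D = _floyd_warshall(G)
    nodes = sorted(int(n) for n in G.nodes())
    total = 0.0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            total += D[(nodes[a], nodes[b])]
    return total


def zagreb_m1(G) -> float:
    return float(sum(d * d for d in _degree(G).values()))


def zagreb_m2(G) -> float:
    deg = _degree(G)
    return float(sum(deg[u] * deg[v] for u, v in _edges(G)))


def randic(G) -> float:
    deg = _degree(G)
    return sum(1.0 / math.sqrt(deg[u] * deg[v]) for u, v in _edges(G))


def chi0(G) -> float:
    return sum(1.0 / math.sqrt(d) for d in _degree(G).values() if d > 0)


def chi2(G) -> float:
    deg = _degree(G)
    return sum(
        1.0 / math.sqrt(deg[p[0]] * deg[p[1]] * deg[p[2]])
        for p in _simple_paths(G, 2)
    )


def kappa1(G) -> float:
    n = len(list(G.nodes()))
    p1 = len(_simple_paths(G, 1))
    return n * (n - 1) ** 2 / p1**2


def kappa2(G) -> float:
    n = len(list(G.nodes()))
    p2 = len(_simple_paths(G, 2))
    return (n - 1) * (n - 2) ** 2 / p2**2


def kappa3(G) -> float:
    n = len(list(G.nodes()))
    p3 = len(_simple_paths(G, 3))
    if n % 2:
        return (n - 1) * (n - 3) ** 2 / p3**2
    return (n - 3) * (n - 2) ** 2 / p3**2


def balaban_j(G) -> float:
    D = _floyd_warshall(G)
    nodes = sorted(int(n) for n in G.nodes())
    S = {i: sum(D[(i, j)] for j in nodes) for i in nodes}
    m = len(_edges(G))
    mu = m - len(nodes) + 1
    return m / (mu + 1) * sum(1.0 / math.sqrt(S[u] * S[v]) for u, v in _edges(G))


def _ecc(G) -> dict[int, float]:
    D = _floyd_warshall(G)
    nodes = sorted(int(n) for n in G.nodes())
    return {i: max(D[(i, j)] for j in nodes) for i in nodes}


def eccentric_connectivity(G) -> float:
    ecc = _ecc(G)
    deg = _degree(G)
    return float(sum(deg[i] * ecc[i] for i in ecc))


def diameter(G) -> float:
    return max(_ecc(G).values())


def radius(G) -> float:
    return min(_ecc(G).values())


def petitjean(G) -> float:
    e = _ecc(G)
    return (max(e.values()) - min(e.values())) / min(e.values())
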