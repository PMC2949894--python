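"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: explicit shortest-path enumeration,
exhaustive subset/partition enumeration, and exact rational arithmetic.
Nothing imports the algorithms under test.
"""

from __future__ import annotations

import itertools
from collections import deque
from fractions import Fraction
from math import comb


def adjacency(edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def _bfs_dist(adj: dict[str, set[str]], s: str) -> dict[str, int]:
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for u in adj.get(v, ()):
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def all_shortest_paths(adj: dict[str, set[str]], s: str, t: str) -> list[list[str]]:
    """Every shortest s-t path, by backward walk over the BFS distance field."""
    dist = _bfs_dist(adj, s)
    if t not in dist:
        return []
    paths: list[list[str]] = []

    def back(v: str, acc: list[str]) -> None:
        if v == s:
            paths.append([s] + acc)
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                back(u, [v] + acc)

    back(t, [])
    return paths


def brute_node_betweenness(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, float]:
    """Unnormalized betweenness: fractional shortest-path counts through each
    node, endpoints excluded, each unordered pair counted once."""
    adj = adjacency(edges)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += w
    return bc


def brute_edge_betweenness(nodes: list[str], edges: set[tuple[str, str]]) -> dict[tuple[str, str], float]:
    """Unnormalized edge betweenness over unordered node pairs."""
    adj = adjacency(edges)
    bc = {e: 0.0 for e in edges}
    for s, t in itertools.combinations(sorted(nodes), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for p in paths:
            for a, b in zip(p, p[1:]):
                bc[(a, b) if a <= b else (b, a)] += w
    return bc


def brute_eccentricity(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, int]:
    """Eccentricity within each node's connected component."""
    adj = adjacency(edges)
    out = {}
    for v in nodes:
        dist = _bfs_dist(adj, v) if v in adj else {v: 0}
        out[v] = max(dist.values())
    return out


def brute_clustering(nodes: list[str], edges: set[tuple[str, str]]) -> dict[str, float]:
    adj = adjacency(edges)
    out = {}
    for v in nodes:
        nbrs = sorted(adj.get(v, ()))
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_kclique_communities(
    nodes: list[str], edges: set[tuple[str, str]], k: int
) -> set[frozenset[str]]:
    """k-clique percolation from first principles: enumerate every k-clique,
    chain cliques sharing k-1 nodes, return node unions of the chains."""
    adj = adjacency(edges)
    cliques = [
        frozenset(c)
        for c in itertools.combinations(sorted(n for n in nodes if n in adj), k)
        if all(b in adj[a] for a, b in itertools.combinations(c, 2))
    ]
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) >= k - 1:
            parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return {frozenset(g) for g in groups.values()}


def brute_modularity(
    edges: set[tuple[str, str]], partition: list[set[str]]
) -> float:
    adj = adjacency(edges)
    L = len(edges)
    m = 0.0
    for part in partition:
        ls = sum(1 for a, b in edges if a in part and b in part)
        ks = sum(len(adj.get(v, ())) for v in part)
        m += ls / L - (ks / (2 * L)) ** 2
    return m


def set_partitions(seq: list[str]):
    """Every partition of ``seq`` into non-empty blocks."""
    if not seq:
        yield []
        return
    first, rest = seq[0], seq[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_max_modularity(nodes: list[str], edges: set[tuple[str, str]]) -> float:
    """Exhaustive-partition modularity maximum (use only for <= 8 nodes)."""
    return max(
        brute_modularity(edges, [set(b) for b in part])
        for part in set_partitions(sorted(nodes))
    )


def brute_fisher_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact one-sided over-representation p-value P(X >= k),
    X ~ Hypergeometric(N, K, n), in exact rational arithmetic."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(min(acc, Fraction(1)))


def brute_chi2_stat(observed: list[float], expected: list[float]) -> float:
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def brute_mannwhitney_u(x: list[float], y: list[float]) -> float:
    """U statistic of x: #{(i,j): x_i > y_j} + 0.5 * ties."""
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def brute_welch(x: list[float], y: list[float]) -> tuple[float, float]:
    """Welch's t and its Welch-Satterthwaite degrees of freedom from the
    textbook formulas (p-value left to the t distribution function)."""
    nx_, ny = len(x), len(y)
    mx = sum(x) / nx_
    my = sum(y) / ny
    vx = sum((a - mx) ** 2 for a in x) / (nx_ - 1)
    vy = sum((b - my) ** 2 for b in y) / (ny - 1)
    se2 = vx / nx_ + vy / ny
    t = (mx - my) / se2**0.5
    df = se2**2 / ((vx / nx_) ** 2 / (nx_ - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
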