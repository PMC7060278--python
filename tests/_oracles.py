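"""Independent brute-force oracles used to cross-check the package.

Nothing here imports from emtnetctrl: these are deliberately naive
re-implementations (exhaustive path enumeration, Floyd-Warshall, explicit
hypergeometric sums, hand BH step-up, closed-form simple regression) that
the fast production code is compared against.
"""

from __future__ import annotations

import math
from collections import deque


# ---------------------------------------------------------------------------
# graphs: edges given as a list of (u, v) directed pairs over hashable nodes
# ---------------------------------------------------------------------------

def _adjacency(nodes, edges):
    adj = {n: [] for n in nodes}
    for u, v in edges:
        if v not in adj[u]:
            adj[u].append(v)
    return adj


def _bfs_dist(adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s->t paths, by backward enumeration over the BFS DAG."""
    if t not in dist:
        return []
    preds = {n: [] for n in dist}
    for u in adj:
        if u in dist:
            for v in adj[u]:
                if v in dist and dist[v] == dist[u] + 1:
                    preds[v].append(u)
    paths = []

    def walk(node, tail):
        if node == s:
            paths.append([s] + tail)
            return
        for p in preds[node]:
            walk(p, [node] + tail)

    walk(t, [])
    return paths


def brute_betweenness(nodes, edges):
    """Unnormalized betweenness by literal enumeration of all shortest paths."""
    adj = _adjacency(nodes, edges)
    score = {n: 0.0 for n in nodes}
    for s in nodes:
        dist = _bfs_dist(adj, s)
        for t in nodes:
            if t == s or t not in dist or dist[t] == 0:
                continue
            paths = enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            for path in paths:
                for interior in path[1:-1]:
                    score[interior] += 1.0 / len(paths)
    return score


def floyd_warshall_summary(nodes, edges):
    """(diameter, n reachable ordered pairs, characteristic path length)."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    inf = math.inf
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        if u != v:
            d[idx[u]][idx[v]] = 1
    for k in range(n):
        dk = d[k]
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            row = d[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < row[j]:
                    row[j] = alt
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] < inf]
    diameter = max(finite) if finite else 0
    cpl = sum(finite) / len(finite) if finite else math.nan
    return diameter, len(finite), cpl


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def hypergeom_tail_by_sum(k, K, n, N):
    """P(X >= k) as an explicit sum of combinatorial fractions."""
    total = 0
    denom = math.comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_by_hand(p_values):
    """q_i = min over j with p_j >= p_i of p_j * m / rank_j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p_values[i] * m / (pos + 1))
        q[i] = running_min
    return q


def regression_by_formula(xs, ys):
    """(slope, pearson r) via the closed-form simple-regression formulas."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    r = sxy / math.sqrt(sxx * syy)
    return slope, r
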