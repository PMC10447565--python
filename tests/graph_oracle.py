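"""Brute-force reference implementations of the seven topological parameters.

Independent of networkx: BFS all-pairs shortest paths with path counting,
explicit triangle enumeration, and direct Freeman centralization formulas.
Intended for small graphs (n <= ~12) as an oracle for the fast pipeline.
"""

from collections import deque
from itertools import combinations

import math


def bfs_shortest_paths(adj, s):
    """(dist, npaths) from s; dist -1 when unreachable."""
    n = len(adj)
    dist = [-1] * n
    npaths = [0] * n
    dist[s] = 0
    npaths[s] = 1
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if dist[v] == -1:
                dist[v] = dist[u] + 1
                q.append(v)
            if dist[v] == dist[u] + 1:
                npaths[v] += npaths[u]
    return dist, npaths


def brute_metrics(nodes, edges):
    """The seven metrics (n, avg_k, cb, cc, cd, den, avg_l) by enumeration."""
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[idx[u]].add(idx[v])
        adj[idx[v]].add(idx[u])
    e = sum(len(a) for a in adj) // 2
    if n < 2:
        return dict(n=n, avg_k=math.nan, cb=math.nan, cc=math.nan, cd=math.nan,
                    den=math.nan, avg_l=math.nan)
    avg_k = 2 * e / n
    den = 2 * e / (n * (n - 1))

    triangles = sum(
        1 for a, b, c in combinations(range(n), 3)
        if b in adj[a] and c in adj[a] and c in adj[b]
    )
    triples = sum(len(a) * (len(a) - 1) // 2 for a in adj)
    cc = 3 * triangles / triples if triples else 0.0

    degrees = [len(a) for a in adj]
    cd = sum(max(degrees) - d for d in degrees) / ((n - 1) * (n - 2)) if n >= 3 else 0.0

    # betweenness by explicit shortest-path counting over all (s, t) pairs
    bet = [0.0] * n
    dists = []
    for s in range(n):
        d, np_ = bfs_shortest_paths(adj, s)
        dists.append(d)
    for s, t in combinations(range(n), 2):
        if dists[s][t] == -1:
            continue
        d_s, np_s = bfs_shortest_paths(adj, s)
        d_t, np_t = bfs_shortest_paths(adj, t)
        sigma_st = np_s[t]
        for v in range(n):
            if v in (s, t):
                continue
            if d_s[v] != -1 and d_t[v] != -1 and d_s[v] + d_t[v] == d_s[t]:
                bet[v] += np_s[v] * np_t[v] / sigma_st
    norm = (n - 1) * (n - 2) / 2
    bet = [b / norm if norm else 0.0 for b in bet]
    cb = sum(max(bet) - b for b in bet) / (n - 1) if n >= 3 else 0.0

    total, pairs = 0.0, 0
    for s in range(n):
        for t in range(n):
            if s != t and dists[s][t] > 0:
                total += dists[s][t]
                pairs += 1
    avg_l = total / pairs if pairs else math.nan
    return dict(n=n, avg_k=avg_k, cb=cb, cc=cc, cd=cd, den=den, avg_l=avg_l)
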