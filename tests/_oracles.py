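"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own graph code paths: shortest paths
are found by exhaustive enumeration of simple paths, so they are only usable
for small graphs (p <= 8 or so).
"""

import numpy as np


def _all_simple_paths(adj_len, s, t):
    """Yield (length, path) for every simple s→t path; adj_len[i][j] is the
    edge length or None."""
    p = len(adj_len)
    stack = [(s, (s,), 0.0)]
    while stack:
        node, path, length = stack.pop()
        if node == t:
            yield length, path
            continue
        for nxt in range(p):
            if adj_len[node][nxt] is None or nxt in path:
                continue
            stack.append((nxt, path + (nxt,), length + adj_len[node][nxt]))


def brute_force_path_centralities(weights: np.ndarray):
    """Closeness and betweenness by exhaustive path enumeration.

    Edge length = 1/|w|; closeness_i = (r_i−1)/(p−1) / Σ_j d(i,j) over
    reachable j; betweenness_i = Σ_{s<t} (shortest s–t paths through i) /
    (number of shortest s–t paths).
    """
    p = weights.shape[0]
    adj = [[(1.0 / abs(weights[i, j]) if weights[i, j] != 0 else None)
            for j in range(p)] for i in range(p)]
    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    shortest_paths: dict[tuple[int, int], list[tuple]] = {}
    for s in range(p):
        for t in range(s + 1, p):
            found = list(_all_simple_paths(adj, s, t))
            if not found:
                continue
            best = min(length for length, _ in found)
            dist[s, t] = dist[t, s] = best
            shortest_paths[(s, t)] = [path for length, path in found
                                      if length < best + 1e-9]
    closeness = np.zeros(p)
    for i in range(p):
        reach = np.isfinite(dist[i]) & (np.arange(p) != i)
        total = dist[i][reach].sum()
        if reach.sum() > 0 and total > 0:
            closeness[i] = reach.sum() / (p - 1) / total
    betweenness = np.zeros(p)
    for (s, t), paths in shortest_paths.items():
        sigma = len(paths)
        for i in range(p):
            if i in (s, t):
                continue
            through = sum(1 for path in paths if i in path)
            betweenness[i] += through / sigma
    return closeness, betweenness
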