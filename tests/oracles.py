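"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: plain BFS, explicit shortest-path
enumeration, direct triangle counting, literal step-up scans.  None of it
shares code with the package.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    """Single-source shortest-path lengths by textbook BFS."""
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and np.isinf(dist[v]):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_pairs_distances(adj: np.ndarray) -> np.ndarray:
    return np.array([bfs_distances(adj, s) for s in range(adj.shape[0])])


def clustering_by_triangle_count(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering via explicit neighbour-pair enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def path_length_by_bfs(adj: np.ndarray) -> float:
    """Mean distance over reachable ordered pairs."""
    d = all_pairs_distances(adj)
    n = adj.shape[0]
    vals = [
        d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    ]
    return float(np.mean(vals))


def global_efficiency_by_bfs(adj: np.ndarray) -> float:
    d = all_pairs_distances(adj)
    n = adj.shape[0]
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def local_efficiency_by_bfs(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency_by_bfs(sub))
    return float(np.mean(vals))


def nodal_efficiency_by_bfs(adj: np.ndarray) -> np.ndarray:
    d = all_pairs_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
        ) / (n - 1)
    return out


def _count_shortest_paths_through(
    adj: np.ndarray, dist: np.ndarray, s: int, t: int
) -> tuple[int, np.ndarray]:
    """Enumerate every shortest s-t path; returns (count, per-node pass counts)."""
    n = adj.shape[0]
    through = np.zeros(n)
    total = 0
    stack = [(s, [s])]
    target_len = dist[s, t]
    while stack:
        u, path = stack.pop()
        if u == t:
            total += 1
            for v in path[1:-1]:
                through[v] += 1
            continue
        for v in range(n):
            if adj[u, v] and dist[s, v] == len(path) and dist[v, t] == target_len - len(path):
                stack.append((v, path + [v]))
    return total, through


def betweenness_by_enumeration(adj: np.ndarray) -> np.ndarray:
    """Betweenness as fractional shortest-path counts over unordered pairs."""
    n = adj.shape[0]
    dist = all_pairs_distances(adj)
    out = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not np.isfinite(dist[s, t]):
            continue
        total, through = _count_shortest_paths_through(adj, dist, s, t)
        if total:
            out += through / total
    return out


def trapezoid_reference(y: np.ndarray, dx: float) -> float:
    """Independent trapezoidal integration via numpy."""
    x = np.arange(len(y)) * dx
    return float(np.trapezoid(y, x))


def bh_reject_bruteforce(p: np.ndarray, q: float) -> np.ndarray:
    """Literal step-up rule: largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def exhaustive_permutation_p(values: np.ndarray, mask: np.ndarray) -> float:
    """Two-tailed p over every distinct group assignment (identity included)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    n_a = int(mask.sum())
    observed = values[mask].mean() - values[~mask].mean()
    count = 0
    total = 0
    for combo in combinations(range(n), n_a):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        diff = values[sel].mean() - values[~sel].mean()
        total += 1
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    return count / total


def pearson_by_formula(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the definitional sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdos-Renyi adjacency with at least one edge."""
    while True:
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1).astype(np.uint8)
        adj |= adj.T
        if adj.sum() > 0:
            return adj
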