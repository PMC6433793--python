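"""Degree-preserving edge-swap kernel (Maslov-Sneppen rewiring).

The hot loop is JIT-compiled with numba when available; a pure-Python
fallback with identical logic is used otherwise.  Both paths draw from
the Mersenne-Twister stream seeded inside the kernel, so results are
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _swap_kernel(
    edges: np.ndarray, adj: np.ndarray, n_target: int, max_attempts: int, seed: int
) -> int:
    """Attempt double-edge swaps in place; returns the number performed.

    ``edges`` is an (E, 2) int array; ``adj`` the matching 0/1 matrix.
    A swap replaces edges (a, b), (c, d) with (a, d), (c, b) when that
    creates neither self-loops nor duplicate edges.
    """
    np.random.seed(seed)
    m = edges.shape[0]
    performed = 0
    attempts = 0
    while performed < n_target and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        performed += 1
    return performed


def rewire_adjacency(
    adjacency: np.ndarray,
    n_swaps_per_edge: int,
    seed: int,
    attempt_factor: int = 100,
) -> tuple[np.ndarray, int]:
    """Return a degree-preserving randomization of ``adjacency``.

    Targets ``n_swaps_per_edge * E`` successful swaps within an attempt
    budget of ``attempt_factor`` times that.  Returns the rewired matrix
    and the number of swaps actually performed (0 for rigid graphs such
    as complete graphs, where no legal swap exists).
    """
    adj = np.ascontiguousarray(adjacency, dtype=np.uint8).copy()
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([iu, ju]).astype(np.int64)
    n_edges = edges.shape[0]
    if n_edges < 2:
        return adj, 0
    n_target = n_swaps_per_edge * n_edges
    performed = _swap_kernel(
        edges, adj, n_target, attempt_factor * n_target, int(seed) & 0x7FFFFFFF
    )
    return adj, int(performed)
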