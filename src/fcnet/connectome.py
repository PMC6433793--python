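"""Functional connectome construction: correlation matrices and
sparsity-thresholded binary networks.

Edges are defined by the Pearson correlation between ROI time series.
Binarization keeps, at sparsity ``s``, the ``round(s * N(N-1)/2)`` edge
slots with the largest absolute correlation; ties are broken by
lexicographic node-pair order so results are platform-independent.
Networks at increasing sparsity are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .aal import default_labels
from .prep import RoiTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "SparsityGrid",
    "correlation_matrix",
    "edge_count_at_sparsity",
    "binarize_at_sparsity",
    "binarize_grid",
    "select_sparsity_range",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """N x N symmetric matrix of pairwise Pearson correlations."""

    weights: np.ndarray
    roi_labels: tuple[str, ...] = field(default=())
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.nanmax(np.abs(w)) > 1 + 1e-8:
            raise ValueError("correlation weights must lie in [-1, 1]")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 1.0)
        object.__setattr__(self, "weights", w)
        labels = self.roi_labels or default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValueError("roi_labels length does not match matrix size")
        object.__setattr__(self, "roi_labels", tuple(labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Symmetric 0/1 adjacency at a given sparsity, zero diagonal."""

    adjacency: np.ndarray
    sparsity: float
    roi_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError("sparsity must lie in (0, 1)")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))
        labels = self.roi_labels or default_labels(a.shape[0])
        object.__setattr__(self, "roi_labels", tuple(labels))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class SparsityGrid:
    """Uniform grid of sparsity levels, endpoints inclusive.

    The default (0.10, 0.34, 0.01) gives 25 levels.
    """

    s_min: float = 0.10
    s_max: float = 0.34
    delta_s: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.s_min < self.s_max < 1.0:
            raise ValueError("need 0 < s_min < s_max < 1")
        if self.delta_s <= 0:
            raise ValueError("delta_s must be positive")
        n_steps = (self.s_max - self.s_min) / self.delta_s
        if abs(n_steps - round(n_steps)) > 1e-6:
            raise ValueError(
                "s_max must be reachable from s_min in whole delta_s steps"
            )

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.delta_s)) + 1
        return np.round(self.s_min + np.arange(n) * self.delta_s, 10)

    def __len__(self) -> int:
        return int(round((self.s_max - self.s_min) / self.delta_s)) + 1


def correlation_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between all pairs of ROI time series."""
    if ts.n_timepoints < 3:
        raise ValueError("correlation needs at least 3 timepoints")
    sd = ts.data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = ", ".join(ts.roi_labels[i] for i in constant[:5])
        raise ValueError(f"constant time series for ROI(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, ts.roi_labels, ts.subject_id)


def edge_count_at_sparsity(n_nodes: int, s: float) -> int:
    """Number of retained edges: round-half-up of ``s * N(N-1)/2``."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(s * m + 0.5))


def _ranked_edges(cm: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges ranked by (|weight| desc, then (i, j) asc)."""
    iu, ju = np.triu_indices(cm.n_nodes, 1)
    absw = np.abs(cm.weights[iu, ju])
    order = np.lexsort((ju, iu, -absw))
    return iu[order], ju[order], absw[order]


def binarize_at_sparsity(cm: ConnectivityMatrix, s: float) -> BinaryNetwork:
    """Binary network keeping the top ``round(s * N(N-1)/2)`` edges by |r|."""
    if not 0.0 < s < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    k = edge_count_at_sparsity(cm.n_nodes, s)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges for N={cm.n_nodes}")
    ii, jj, _ = _ranked_edges(cm)
    adj = np.zeros((cm.n_nodes, cm.n_nodes), dtype=np.uint8)
    adj[ii[:k], jj[:k]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, s, cm.roi_labels)


def binarize_grid(
    cm: ConnectivityMatrix, grid: SparsityGrid
) -> Iterator[BinaryNetwork]:
    """Yield nested binary networks for every grid sparsity (ascending).

    Edges are ranked once, so networks at higher sparsity are supersets of
    those at lower sparsity.
    """
    ii, jj, _ = _ranked_edges(cm)
    adj = np.zeros((cm.n_nodes, cm.n_nodes), dtype=np.uint8)
    added = 0
    for s in grid.values:
        k = edge_count_at_sparsity(cm.n_nodes, float(s))
        if k == 0:
            raise ValueError(f"sparsity {s} keeps zero edges for N={cm.n_nodes}")
        while added < k:
            adj[ii[added], jj[added]] = 1
            adj[jj[added], ii[added]] = 1
            added += 1
        yield BinaryNetwork(adj.copy(), float(s), cm.roi_labels)


def select_sparsity_range(
    cohort_cms: Sequence[ConnectivityMatrix],
    delta_s: float = 0.01,
    sigma_threshold: float = 1.1,
    candidates: tuple[float, float] = (0.01, 0.50),
    log_base: float = np.e,
    n_null: int = 10,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> tuple[SparsityGrid, dict]:
    """Select the sparsity grid from the two standard criteria.

    ``s_min`` is the smallest candidate level at which every thresholded
    network has mean degree >= 2*log(N); ``s_max`` is the largest level at
    which every subject's small-worldness sigma exceeds
    ``sigma_threshold``.  The logarithm base is configurable (natural log
    by default, the small-world-literature convention).

    Returns the grid plus a diagnostics dict with the per-criterion
    bounds and the per-subject sigma values at the selected ``s_max``.
    """
    from .metrics import small_world_params  # local import avoids cycle

    if not cohort_cms:
        raise ValueError("cohort must be non-empty")
    n = cohort_cms[0].n_nodes
    lo, hi = candidates
    n_levels = int(round((hi - lo) / delta_s)) + 1
    levels = np.round(lo + np.arange(n_levels) * delta_s, 10)

    degree_bound = 2.0 * np.log(n) / np.log(log_base)
    mean_degree = np.array(
        [2.0 * edge_count_at_sparsity(n, float(s)) / n for s in levels]
    )
    ok_degree = mean_degree >= degree_bound
    if not ok_degree.any():
        raise ValueError(
            f"no candidate sparsity reaches mean degree {degree_bound:.2f}"
        )
    s_min = float(levels[np.argmax(ok_degree)])

    # walk down from the top; stop at the first level where every subject
    # is small-world enough
    s_max = None
    sigma_at_smax: list[float] = []
    for s in levels[::-1]:
        if s < s_min:
            break
        sigmas = []
        for i, cm in enumerate(cohort_cms):
            net = binarize_at_sparsity(cm, float(s))
            _, _, sig = small_world_params(
                net, n_null=n_null, n_swaps_per_edge=n_swaps_per_edge,
                seed=seed + i,
            )
            sigmas.append(sig)
            if sig <= sigma_threshold:
                break
        if all(sig > sigma_threshold for sig in sigmas):
            s_max = float(s)
            sigma_at_smax = sigmas
            break
    if s_max is None or s_max < s_min:
        raise ValueError(
            f"empty feasible sparsity range: degree criterion needs "
            f"s >= {s_min}, sigma > {sigma_threshold} never holds above it"
        )
    diagnostics = {
        "degree_bound": float(degree_bound),
        "s_min": s_min,
        "s_max": s_max,
        "sigma_threshold": sigma_threshold,
        "sigma_at_s_max": sigma_at_smax,
    }
    return SparsityGrid(s_min, s_max, delta_s), diagnostics
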