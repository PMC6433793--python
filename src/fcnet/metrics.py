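"""Global and nodal topology metrics of binary brain networks.

All metrics operate on undirected, unweighted adjacency matrices.
Shortest-path distances come from breadth-first search
(:func:`scipy.sparse.csgraph.shortest_path`); betweenness uses a
level-synchronous, matrix-form variant of Brandes' accumulation so that
whole distance/path-count tables are handled with dense linear algebra.

Conventions (thresholded networks can fragment or contain low-degree
nodes, and the metrics must stay defined):

* nodes with degree < 2 have clustering coefficient 0;
* nodes with < 2 neighbours contribute 0 to local efficiency;
* characteristic path length averages over *reachable* ordered pairs and
  emits a warning when the graph is disconnected;
* unreachable pairs contribute 0 to efficiency;
* betweenness is reported in unnormalized pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rewire import rewire_adjacency
from .connectome import BinaryNetwork

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "nodal_metrics",
    "betweenness_centrality",
    "random_reference",
    "small_world_params",
    "global_metrics",
    "distance_matrix",
]

GLOBAL_METRIC_NAMES = ("cp", "lp", "gamma", "lam", "sigma", "e_glob", "e_loc")
NODAL_METRIC_NAMES = ("degree", "efficiency", "betweenness")


@dataclass(frozen=True)
class GlobalMetrics:
    """Scalar topology summary of one binary network at one sparsity."""

    cp: float
    lp: float
    gamma: float
    lam: float
    sigma: float
    e_glob: float
    e_loc: float
    sparsity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cp <= 1.0:
            raise ValueError("cp out of [0, 1]")
        if not 0.0 <= self.e_glob <= 1.0 or not 0.0 <= self.e_loc <= 1.0:
            raise ValueError("efficiency out of [0, 1]")
        if np.isfinite(self.gamma) and np.isfinite(self.lam):
            if abs(self.sigma - self.gamma / self.lam) > 1e-12 * max(
                1.0, abs(self.sigma)
            ):
                raise ValueError("sigma must equal gamma / lam")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES}


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node degree, efficiency and betweenness vectors."""

    degree: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        n = len(self.degree)
        if len(self.efficiency) != n or len(self.betweenness) != n:
            raise ValueError("nodal metric vectors must share length")
        if np.any(self.betweenness < -1e-9):
            raise ValueError("betweenness must be non-negative")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree,
            "efficiency": self.efficiency,
            "betweenness": self.betweenness,
        }


def _as_adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net, dtype=np.uint8)


def _sparsity_of(net: BinaryNetwork | np.ndarray) -> float:
    if isinstance(net, BinaryNetwork):
        return net.sparsity
    a = _as_adj(net)
    n = a.shape[0]
    return float(a.sum() / (n * (n - 1)))


def distance_matrix(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths (BFS); ``inf`` for unreachable pairs."""
    adj = _as_adj(net)
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def clustering_coefficient(
    net: BinaryNetwork | np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean and per-node clustering coefficient.

    ``C_i = 2 * triangles_i / (k_i (k_i - 1))``; nodes with degree < 2
    contribute 0.
    """
    adj = _as_adj(net).astype(np.float64)
    if adj.shape[0] < 3:
        raise ValueError("clustering needs at least 3 nodes")
    k = adj.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(c.mean()), c


def characteristic_path_length(net: BinaryNetwork | np.ndarray) -> float:
    """Mean shortest-path length over reachable ordered pairs.

    Disconnected pairs are excluded with a warning (low-sparsity networks
    can fragment); a graph with no edges at all is an error.
    """
    adj = _as_adj(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    if adj.sum() == 0:
        raise ValueError("graph has no edges; path length undefined")
    d = distance_matrix(adj)
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(d) & off
    n_unreachable = int(off.sum() - reachable.sum())
    if n_unreachable:
        warnings.warn(
            f"graph is disconnected: {n_unreachable} unreachable ordered "
            "pairs excluded from Lp",
            stacklevel=2,
        )
    return float(d[reachable].mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    adj = _as_adj(net)
    if adj.shape[0] < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    return _efficiency_from_distances(distance_matrix(adj))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each neighbour subgraph."""
    adj = _as_adj(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("local efficiency needs at least 2 nodes")
    vals = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals[i] = _efficiency_from_distances(distance_matrix(sub))
    return float(vals.mean())


def betweenness_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: shortest-path pair counts through each node.

    Level-synchronous Brandes accumulation carried out for all sources at
    once with dense matrix products.
    """
    adj = _as_adj(net).astype(np.float64)
    n = adj.shape[0]
    d = distance_matrix(adj)
    finite = np.isfinite(d)
    max_d = int(d[finite].max()) if finite.any() else 0

    # sigma[s, v]: number of shortest s->v paths, built level by level
    sigma = np.eye(n)
    for lev in range(1, max_d + 1):
        prev = d == lev - 1
        cur = d == lev
        contrib = (sigma * prev) @ adj
        sigma = np.where(cur, contrib, sigma)

    # delta[s, v]: dependency of source s on v, accumulated deepest-first
    delta = np.zeros((n, n))
    for lev in range(max_d, 0, -1):
        cur = d == lev
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(cur & (sigma > 0), (1.0 + delta) / sigma, 0.0)
        upd = (w @ adj) * sigma
        prev = d == lev - 1
        delta = np.where(prev, delta + upd, delta)

    bc = delta.sum(axis=0) - np.diag(delta)
    return bc / 2.0  # each unordered pair counted from both endpoints


def nodal_metrics(net: BinaryNetwork | np.ndarray) -> NodalMetrics:
    """Degree, nodal efficiency, and betweenness for every node."""
    adj = _as_adj(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("nodal metrics need at least 2 nodes")
    d = distance_matrix(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return NodalMetrics(
        degree=adj.sum(axis=1).astype(np.int64),
        efficiency=inv.sum(axis=1) / (n - 1),
        betweenness=betweenness_centrality(adj),
        sparsity=_sparsity_of(net),
    )


def random_reference(
    net: BinaryNetwork | np.ndarray,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Degree-preserving rewiring null of the input adjacency.

    Returns the rewired adjacency; if no legal swap exists within the
    attempt budget (e.g. complete graphs) the input is returned unchanged
    with a warning.  Connectivity is not enforced.
    """
    adj = _as_adj(net)
    if adj.sum() < 4:
        raise ValueError("rewiring needs at least 2 edges")
    out, performed = rewire_adjacency(adj, n_swaps_per_edge, seed)
    if performed == 0:
        warnings.warn(
            "no legal edge swap found; returning the input network",
            stacklevel=2,
        )
    return out


def small_world_params(
    net: BinaryNetwork | np.ndarray,
    n_null: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Normalized clustering (gamma), path length (lambda) and sigma.

    ``gamma = Cp / mean(Cp_null)``, ``lam = Lp / mean(Lp_null)`` over
    ``n_null`` independent degree-preserving rewirings; ``sigma`` is their
    ratio.  A null realization with zero clustering is resampled once and
    then dropped with a warning (it would make gamma undefined).
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    adj = _as_adj(net)
    cp, _ = clustering_coefficient(adj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lp = characteristic_path_length(adj)
    cps, lps = [], []
    for i in range(n_null):
        null, _ = rewire_adjacency(adj, n_swaps_per_edge, seed + 7919 * i)
        c_null, _ = clustering_coefficient(null)
        if c_null == 0.0:
            null, _ = rewire_adjacency(adj, n_swaps_per_edge, seed + 7919 * i + 104729)
            c_null, _ = clustering_coefficient(null)
            if c_null == 0.0:
                warnings.warn(
                    "null network with zero clustering excluded", stacklevel=2
                )
                continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lps.append(characteristic_path_length(null))
        cps.append(c_null)
    if not cps:
        raise ValueError("all null networks had zero clustering")
    gamma = cp / float(np.mean(cps))
    lam = lp / float(np.mean(lps))
    return gamma, lam, gamma / lam


def global_metrics(
    net: BinaryNetwork | np.ndarray,
    n_null: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """All global metrics of one network (set ``n_null=0`` to skip nulls)."""
    adj = _as_adj(net)
    cp, _ = clustering_coefficient(adj)
    lp = characteristic_path_length(adj)
    if n_null > 0:
        gamma, lam, sigma = small_world_params(adj, n_null, n_swaps_per_edge, seed)
    else:
        gamma = lam = sigma = float("nan")
    return GlobalMetrics(
        cp=cp,
        lp=lp,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        e_glob=global_efficiency(adj),
        e_loc=local_efficiency(adj),
        sparsity=_sparsity_of(net),
    )
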