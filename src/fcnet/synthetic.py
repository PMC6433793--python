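"""Synthetic two-group BOLD cohort generator.

Ground truth is a small-world graph; subject signals are drawn from a
zero-mean Gaussian whose covariance is the matrix exponential of the
weighted coupling matrix, then band-limited to the resting-state
frequency band.  Group effects are injected as additional coupling on
the edges incident to designated nodes, and clinical variables are
generated with a calibrated correlation to the injected per-subject
coupling.

Why ``expm``: a covariance of the form ``inv(I + c A)`` is *not*
positive definite for the default graphs at the default coupling (the
adjacency spectrum dips below ``-1/c``), whereas ``expm(c A)`` is
positive definite for every symmetric coupling matrix and keeps the
closed analytic form needed by the test oracles.  Adjacent nodes get
correlation ~``c`` to first order, non-adjacent nodes much less.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import expm

from .aal import default_labels
from .prep import RoiTimeSeries, bandpass

__all__ = [
    "GroundTruthNetwork",
    "SimulationSpec",
    "make_small_world_graph",
    "coupling_matrix",
    "analytic_covariance",
    "simulate_bold",
    "make_cohort",
]

PATIENT, CONTROL = "patient", "control"

#: group-wise (mean, sd) used for the clinical table; patient-only
#: variables get clinically normal control values.
CLINICAL_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "bmi": {PATIENT: (25.37, 2.85), CONTROL: (25.20, 2.80)},
    "hba1c": {PATIENT: (8.15, 1.78), CONTROL: (5.40, 0.40)},
    "glu": {PATIENT: (9.59, 3.04), CONTROL: (5.20, 0.60)},
    "chol": {PATIENT: (4.42, 1.10), CONTROL: (4.81, 0.87)},
    "tg": {PATIENT: (2.05, 2.41), CONTROL: (1.55, 0.82)},
    "hdl": {PATIENT: (0.98, 0.24), CONTROL: (1.21, 0.33)},
    "ldl": {PATIENT: (2.51, 0.90), CONTROL: (2.77, 0.64)},
    "moca": {PATIENT: (25.36, 1.74), CONTROL: (27.79, 1.90)},
    "duration": {PATIENT: (8.87, 6.42), CONTROL: (0.0, 0.0)},
}

AGE_MEAN, AGE_SD, AGE_RANGE = 53.3, 8.5, (40.0, 75.0)
MALE_FRACTION = {PATIENT: 35 / 55, CONTROL: 21 / 47}


@dataclass(frozen=True)
class GroundTruthNetwork:
    """True binary connectivity underlying the simulated signals."""

    n_nodes: int
    adjacency: np.ndarray
    rewiring_prob: float = 0.0
    module_labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("adjacency shape does not match n_nodes")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not 0.0 <= self.rewiring_prob <= 1.0:
            raise ValueError("rewiring_prob must lie in [0, 1]")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study: 55 patients / 47 controls,
    200 retained timepoints at TR = 2 s, band 0.01-0.08 Hz.
    ``effect_nodes`` default to left insula, right putamen and right
    inferior temporal gyrus in the 90-node atlas ordering.
    """

    n_per_group: tuple[int, int] = (55, 47)
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    coupling_strength: float = 0.25
    noise_sd: float = 1.0
    effect_nodes: tuple[int, ...] = (28, 73, 89)
    effect_size: float = 0.15
    clinical_assoc: tuple[str, str, float] = ("bmi", "efficiency", 0.31)
    subject_coupling_sd: float = 0.05
    band: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("group sizes must be positive")
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.tr_seconds <= 0 or self.noise_sd <= 0:
            raise ValueError("tr_seconds and noise_sd must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be non-negative")
        if abs(self.clinical_assoc[2]) >= 1:
            raise ValueError("|target correlation| must be < 1")

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group)


def make_small_world_graph(
    n_nodes: int,
    lattice_degree: int,
    rewiring_prob: float,
    seed: int,
    tries: int = 200,
) -> GroundTruthNetwork:
    """Connected Watts-Strogatz graph as ground-truth connectivity.

    Rewiring preserves the edge count, so the result always has exactly
    ``n_nodes * lattice_degree / 2`` edges.
    """
    if lattice_degree % 2 != 0:
        raise ValueError("lattice_degree must be even")
    if not 2 <= lattice_degree < n_nodes:
        raise ValueError("need 2 <= lattice_degree < n_nodes")
    if not 0.0 <= rewiring_prob <= 1.0:
        raise ValueError("rewiring_prob must lie in [0, 1]")
    try:
        g = nx.connected_watts_strogatz_graph(
            n_nodes, lattice_degree, rewiring_prob, tries=tries, seed=seed
        )
    except nx.NetworkXError as exc:
        raise RuntimeError(
            f"could not draw a connected rewired lattice in {tries} tries "
            f"(n={n_nodes}, k={lattice_degree}, p={rewiring_prob})"
        ) from exc
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=np.uint8)
    assert adj.sum() // 2 == n_nodes * lattice_degree // 2
    return GroundTruthNetwork(n_nodes, adj, rewiring_prob)


def coupling_matrix(
    gt: GroundTruthNetwork,
    spec: SimulationSpec,
    group: str,
    extra_edge_coupling: float = 0.0,
) -> np.ndarray:
    """Symmetric edge-coupling weights for one subject.

    Every true edge carries ``coupling_strength``; edges incident to
    ``effect_nodes`` additionally carry ``effect_size`` for the patient
    group plus any per-subject increment.  Weights are floored at zero.
    """
    if group not in (PATIENT, CONTROL):
        raise ValueError(f"group must be '{PATIENT}' or '{CONTROL}'")
    adj = gt.adjacency.astype(float)
    w = spec.coupling_strength * adj
    if spec.effect_nodes:
        mask = np.zeros_like(adj)
        idx = np.asarray(spec.effect_nodes, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= gt.n_nodes):
            raise ValueError("effect_nodes out of range")
        mask[idx, :] = adj[idx, :]
        mask[:, idx] = np.maximum(mask[:, idx], adj[:, idx])
        bump = extra_edge_coupling + (spec.effect_size if group == PATIENT else 0.0)
        w = w + bump * mask
    return np.maximum(w, 0.0)


def analytic_covariance(w: np.ndarray, noise_sd: float = 1.0) -> np.ndarray:
    """Model covariance ``noise_sd^2 * expm(W)``; positive definite for
    any symmetric coupling matrix ``W``."""
    return noise_sd**2 * expm(np.asarray(w, dtype=float))


def simulate_bold(
    gt: GroundTruthNetwork,
    spec: SimulationSpec,
    group: str,
    seed: int,
    extra_edge_coupling: float = 0.0,
    subject_id: str | None = None,
    apply_bandpass: bool = True,
) -> RoiTimeSeries:
    """Band-limited Gaussian ROI signals with network-encoded covariance."""
    w = coupling_matrix(gt, spec, group, extra_edge_coupling)
    cov = analytic_covariance(w, spec.noise_sd)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur
        raise AssertionError("model covariance not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((gt.n_nodes, spec.n_timepoints))
    data = (chol @ z).T
    ts = RoiTimeSeries(
        data=data,
        tr_seconds=spec.tr_seconds,
        subject_id=subject_id or f"sim-{group}-{seed}",
        roi_labels=default_labels(gt.n_nodes),
    )
    if apply_bandpass:
        ts = bandpass(ts, *spec.band)
    return ts


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def make_cohort(
    spec: SimulationSpec,
    gt: GroundTruthNetwork | None = None,
) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Returns one time series per subject plus the cohort table with group,
    demographics, clinical variables, and the per-subject injected
    coupling increment (``coupling_jitter``) used to calibrate the
    clinical association.
    """
    rng = np.random.default_rng(spec.seed)
    if gt is None:
        gt = make_small_world_graph(
            90, 8, 0.1, seed=int(rng.integers(2**31 - 1))
        )

    groups = [PATIENT] * spec.n_per_group[0] + [CONTROL] * spec.n_per_group[1]
    n = len(groups)
    jitter = rng.normal(0.0, spec.subject_coupling_sd, size=n)

    series: list[RoiTimeSeries] = []
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        ts = simulate_bold(
            gt,
            spec,
            group,
            seed=int(rng.integers(2**31 - 1)),
            extra_edge_coupling=float(jitter[i]),
            subject_id=sid,
        )
        series.append(ts)

    table: dict[str, object] = {
        "subject_id": [ts.subject_id for ts in series],
        "group": groups,
        "age": _truncated_normal(rng, AGE_MEAN, AGE_SD, *AGE_RANGE, size=n),
        "sex": [
            int(rng.random() < MALE_FRACTION[g]) for g in groups
        ],  # 1 = male
    }
    for var, moments in CLINICAL_MOMENTS.items():
        vals = np.array(
            [rng.normal(*moments[g]) for g in groups]
        )
        if var in ("duration", "tg", "hba1c", "glu"):
            vals = np.maximum(vals, 0.0)
        table[var] = vals

    # rebuild the association variable as r * z(jitter) + sqrt(1-r^2) * noise,
    # rescaled to its clinical units, so its correlation with the injected
    # coupling matches the target
    var, _metric, target_r = spec.clinical_assoc
    if var:
        if var not in CLINICAL_MOMENTS:
            raise ValueError(f"unknown clinical variable '{var}'")
        z = (jitter - jitter.mean()) / (jitter.std() or 1.0)
        mixed = target_r * z + np.sqrt(1 - target_r**2) * rng.standard_normal(n)
        vals = np.empty(n)
        for g in (PATIENT, CONTROL):
            sel = np.array([grp == g for grp in groups])
            mean, sd = CLINICAL_MOMENTS[var][g]
            vals[sel] = mean + sd * mixed[sel]
        table[var] = vals

    cohort = pd.DataFrame(table)
    cohort["coupling_jitter"] = jitter
    return series, cohort
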