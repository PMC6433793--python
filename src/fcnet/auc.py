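"""Integration of metric curves over the sparsity grid.

Summarizing each topology metric by the area under its curve across all
sparsity levels removes the dependence on any single threshold; the AUC
is the composite trapezoidal rule on the uniform grid,

    AUC = (dS / 2) * sum_k [ Y(S_k) + Y(S_{k+1}) ].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import SparsityGrid

__all__ = ["MetricCurves", "auc_over_sparsity"]


def auc_over_sparsity(values: np.ndarray, delta_s: float) -> float | np.ndarray:
    """Trapezoidal area under a metric curve sampled on a uniform grid.

    ``values`` may be 1-D (one curve) or 2-D with curves along axis 0
    (e.g. grid x nodes), in which case one AUC per column is returned.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if delta_s <= 0:
        raise ValueError("delta_s must be positive")
    auc = 0.5 * delta_s * (values[:-1] + values[1:]).sum(axis=0)
    return float(auc) if np.ndim(auc) == 0 else auc


@dataclass(frozen=True)
class MetricCurves:
    """Per-subject metric values over the sparsity grid, plus their AUCs.

    ``global_curves`` maps metric name -> vector over grid points;
    ``nodal_curves`` maps metric name -> (n_grid x n_nodes) array.  AUCs
    are computed on construction with the trapezoidal rule.
    """

    subject_id: str
    grid: SparsityGrid
    global_curves: dict[str, np.ndarray]
    nodal_curves: dict[str, np.ndarray]
    global_aucs: dict[str, float] = field(default_factory=dict)
    nodal_aucs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_grid = len(self.grid)
        for name, curve in self.global_curves.items():
            if len(curve) != n_grid:
                raise ValueError(
                    f"curve '{name}' has {len(curve)} values for "
                    f"{n_grid} grid points"
                )
        for name, curve in self.nodal_curves.items():
            if curve.shape[0] != n_grid:
                raise ValueError(
                    f"nodal curve '{name}' has {curve.shape[0]} rows for "
                    f"{n_grid} grid points"
                )
        if not self.global_aucs:
            object.__setattr__(
                self,
                "global_aucs",
                {
                    name: float(auc_over_sparsity(curve, self.grid.delta_s))
                    for name, curve in self.global_curves.items()
                    if np.all(np.isfinite(curve))
                },
            )
        if not self.nodal_aucs:
            object.__setattr__(
                self,
                "nodal_aucs",
                {
                    name: np.asarray(auc_over_sparsity(curve, self.grid.delta_s))
                    for name, curve in self.nodal_curves.items()
                },
            )
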