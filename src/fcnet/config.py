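"""Run configuration: one YAML-serializable object drives the pipeline.

All randomness in a run flows from ``seed`` through named substreams
(simulation, permutations, null networks), so a config fully determines
every output byte.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .connectome import SparsityGrid

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved parameters of one end-to-end run."""

    # sparsity grid
    s_min: float = 0.10
    s_max: float = 0.34
    delta_s: float = 0.01
    # preprocessing
    low_hz: float = 0.01
    high_hz: float = 0.08
    n_discard: int = 0
    # inference
    n_perm: int = 10_000
    n_null: int = 100
    n_swaps_per_edge: int = 10
    fdr_q: float = 0.05
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    clinical_vars: list[str] = field(
        default_factory=lambda: [
            "bmi", "duration", "hba1c", "glu", "chol", "tg", "hdl", "ldl", "moca",
        ]
    )
    # simulation (used by the `simulate` stage)
    n_patients: int = 55
    n_controls: int = 47
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    coupling_strength: float = 0.25
    effect_size: float = 0.15
    effect_nodes: list[int] = field(default_factory=lambda: [28, 73, 89])
    gt_nodes: int = 90
    gt_degree: int = 8
    gt_rewiring: float = 0.1
    seed: int = 0
    # file locations, relative to the run directory unless absolute
    paths: dict[str, str] = field(default_factory=dict)

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.delta_s)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})
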