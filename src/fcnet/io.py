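"""Plain-text readers and writers for every pipeline artifact.

Formats are deliberately simple: TSV for matrices and time series (ROI
labels in the header, ``#`` metadata lines for sampling interval and
subject id), CSV for the cohort table, long-format TSV for metrics and
AUCs.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .prep import RoiTimeSeries

__all__ = [
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_table_tsv",
    "read_table_tsv",
]

_FLOAT_FMT = "%.10g"


def write_timeseries_tsv(ts: RoiTimeSeries, path: str | Path) -> Path:
    """Write a T x N time series with metadata comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# subject_id={ts.subject_id}\n")
        fh.write(f"# tr_seconds={ts.tr_seconds!r}\n")
        fh.write("\t".join(ts.roi_labels) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt=_FLOAT_FMT)
    return path


def read_timeseries_tsv(path: str | Path) -> RoiTimeSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = line.split("\t")
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                    f"expected {len(header)})"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell") from exc
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows")
    return RoiTimeSeries(
        data=np.array(rows),
        tr_seconds=float(meta.get("tr_seconds", "1.0")),
        subject_id=meta.get("subject_id", path.stem),
        roi_labels=tuple(header),
    )


def write_matrix_tsv(
    matrix: np.ndarray | ConnectivityMatrix,
    path: str | Path,
    labels: tuple[str, ...] | None = None,
) -> Path:
    """Write a square labelled matrix (connectivity or adjacency)."""
    if isinstance(matrix, ConnectivityMatrix):
        labels = matrix.roi_labels
        matrix = matrix.weights
    matrix = np.asarray(matrix, dtype=float)
    path = Path(path)
    with path.open("w") as fh:
        if labels:
            fh.write("\t".join(labels) + "\n")
        np.savetxt(fh, matrix, delimiter="\t", fmt=_FLOAT_FMT)
    return path


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        labels = tuple(first.split("\t"))
        try:  # headerless matrix: first line is numeric
            [float(c) for c in labels]
        except ValueError:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        else:
            fh.seek(0)
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
            labels = tuple(f"ROI_{i + 1:03d}" for i in range(data.shape[1]))
    if data.shape[0] != data.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {data.shape}")
    return data, labels


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    return pd.read_csv(path)


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> Path:
    """Long-format results table (metrics, AUCs, comparisons, ...)."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "node" in df.columns:
        df["node"] = df["node"].fillna("").astype(str)
    return df
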