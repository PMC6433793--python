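"""Conditioning of ROI time series before connectivity estimation.

The pipeline mirrors standard resting-state preprocessing at the
extracted-signal level: discard initial volumes, remove linear drift,
band-pass to the low-frequency regime, and regress out nuisance
covariates.  All operations are pure (they return new objects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .aal import default_labels

__all__ = [
    "RoiTimeSeries",
    "discard_initial",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
]

#: minimum length accepted by the band-pass filter (zero-phase filtering
#: needs enough samples for its edge padding)
MIN_FILTER_LENGTH = 30


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's T x N matrix of ROI signals with sampling interval.

    Parameters
    ----------
    data:
        Array of shape ``(n_timepoints, n_rois)``; must be finite.
    tr_seconds:
        Repetition time (sampling interval) in seconds.
    subject_id:
        Free-form subject label.
    roi_labels:
        One label per ROI column; defaults to atlas names for 90 columns.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = "subject"
    roi_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (T x N), got shape {data.shape}")
        if data.shape[0] < 2:
            raise ValueError("time series needs at least 2 timepoints")
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contains NaN or infinite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        object.__setattr__(self, "data", data)
        labels = self.roi_labels or default_labels(data.shape[1])
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"roi_labels has {len(labels)} entries for {data.shape[1]} columns"
            )
        object.__setattr__(self, "roi_labels", tuple(labels))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def discard_initial(ts: RoiTimeSeries, n_discard: int) -> RoiTimeSeries:
    """Drop the first ``n_discard`` timepoints (scanner-equilibration volumes)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_timepoints:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_timepoints} timepoints"
        )
    if n_discard == 0:
        return ts
    return replace(ts, data=ts.data[n_discard:].copy())


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the least-squares line (drift + mean) from every column."""
    if ts.n_timepoints < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    out = _signal.detrend(ts.data, axis=0, type="linear")
    return replace(ts, data=out)


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass of every ROI signal.

    The realization is contractual rather than prescriptive: any filter
    transmitting >= 0.9 of mid-band amplitude and <= 0.1 at 2.5x the upper
    edge conforms.  A zero-phase (forward-backward) Butterworth is used to
    avoid introducing inter-column lag.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not 0.0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    if ts.n_timepoints < MIN_FILTER_LENGTH:
        raise ValueError(
            f"band-pass needs at least {MIN_FILTER_LENGTH} timepoints, "
            f"got {ts.n_timepoints}"
        )
    sos = _signal.butter(
        order, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr_seconds, output="sos"
    )
    out = _signal.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=np.ascontiguousarray(out))


def regress_nuisance(ts: RoiTimeSeries, nuisance: np.ndarray) -> RoiTimeSeries:
    """Project nuisance regressors out of every ROI signal.

    Output columns are orthogonal to every nuisance column.  Rank-deficient
    designs fall back to the pseudo-inverse with a warning.
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != ts.n_timepoints:
        if nuisance.shape[1] == ts.n_timepoints:  # accept K x T for convenience
            nuisance = nuisance.T
        else:
            raise ValueError(
                f"nuisance has {nuisance.shape[0]} rows for "
                f"{ts.n_timepoints} timepoints"
            )
    if not np.all(np.isfinite(nuisance)):
        raise ValueError("nuisance regressors contain non-finite values")
    k = nuisance.shape[1]
    if k >= ts.n_timepoints:
        raise ValueError("more nuisance regressors than timepoints")
    rank = np.linalg.matrix_rank(nuisance)
    if rank < k:
        warnings.warn(
            f"nuisance design is rank deficient (rank {rank} < {k}); "
            "using pseudo-inverse",
            stacklevel=2,
        )
    beta = np.linalg.pinv(nuisance) @ ts.data
    return replace(ts, data=ts.data - nuisance @ beta)
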