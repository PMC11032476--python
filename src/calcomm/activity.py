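"""Detrending and binarization of normalized Ca2+ traces.

Each normalized trace is smoothed with a short running median, a slow
running-median baseline is subtracted, negatives are clipped and the
residual is rescaled by its maximum.  Frames whose rescaled residual
reaches ``bin_thr`` are active; a candidate run is kept only if its peak
reaches ``peak_thr``.  The resulting binary matrix and the spike onsets
(first frame of each maximal active run) feed event detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, median_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .traces import AnalysisParameters, NormalizedTraces

__all__ = [
    "ActivityMatrix",
    "SpikeBinarizer",
    "detrend",
    "binarize",
    "build_activity",
    "runs_of",
    "activation_rate",
    "local_density",
    "spike_magnitude_zscore",
]


@dataclass
class ActivityMatrix:
    """Binary active/inactive state per cell and frame, with onsets.

    ``onsets[i]`` lists the first frames of the maximal runs of
    ``active[i]``; a constant-trace cell has an all-zero row.
    """

    active: np.ndarray  # bool (n_cells, n_frames)
    detrended: np.ndarray  # float (n_cells, n_frames) in [0, 1]
    onsets: list  # list of int arrays, one per cell

    @property
    def n_cells(self) -> int:
        return self.active.shape[0]

    @property
    def n_frames(self) -> int:
        return self.active.shape[1]

    def onset_counts(self) -> np.ndarray:
        return np.array([len(o) for o in self.onsets])


def _odd_window(k: int, n: int, name: str) -> int:
    """Clamp a running-median window to an odd value <= trace length."""
    if k < 1:
        raise ValueError(f"{name} must be >= 1")
    if k % 2 == 0:
        warnings.warn(f"{name}={k} is even; using {k + 1}", stacklevel=3)
        k += 1
    if k > n:
        k = n if n % 2 == 1 else n - 1
        warnings.warn(f"{name} longer than trace; truncated to {k}", stacklevel=3)
    return max(k, 1)


def detrend(trace: np.ndarray, smooth_k: int = 3, bias_k: int = 25) -> np.ndarray:
    """Median-smooth, subtract a running-median baseline, clip and rescale.

    The short window (``smooth_k``) suppresses single-frame noise; the
    long window (``bias_k``) tracks slow baseline drift.  The clipped
    residual is rescaled to [0, 1] by its own maximum (all-zero residual
    rows stay zero).
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    n = trace.shape[-1]
    sk = _odd_window(smooth_k, n, "smooth_k")
    bk = _odd_window(bias_k, n, "bias_k")
    smoothed = median_filter(trace, size=sk, mode="nearest", axes=(-1,))
    baseline = median_filter(smoothed, size=bk, mode="nearest", axes=(-1,))
    resid = np.clip(smoothed - baseline, 0.0, None)
    peak = resid.max(axis=-1, keepdims=True)
    return np.divide(resid, peak, out=np.zeros_like(resid), where=peak > 0)


def runs_of(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as (start, end) inclusive."""
    row = np.asarray(row, dtype=bool)
    if not row.any():
        return []
    d = np.diff(row.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if row[0]:
        starts = np.r_[0, starts]
    if row[-1]:
        ends = np.r_[ends, row.size - 1]
    return list(zip(starts.tolist(), ends.tolist()))


def binarize(detrended: np.ndarray, peak_thr: float = 0.3, bin_thr: float = 0.4) -> np.ndarray:
    """Threshold a rescaled detrended trace into an active/inactive row.

    Frames >= ``bin_thr`` are candidate-active; a maximal candidate run
    survives only if its maximum reaches ``peak_thr``.  With the default
    thresholds (0.4 >= 0.3) the peak filter keeps every run; it bites when
    a user sets ``peak_thr`` above ``bin_thr``.
    """
    detrended = np.atleast_2d(np.asarray(detrended, dtype=float))
    active = detrended >= bin_thr
    if peak_thr > bin_thr:
        for i in range(active.shape[0]):
            for s, e in runs_of(active[i]):
                if detrended[i, s : e + 1].max() < peak_thr:
                    active[i, s : e + 1] = False
    return active if active.shape[0] > 1 else active[0]


class SpikeBinarizer(BaseEstimator, TransformerMixin):
    """Detrend + binarize normalized traces into spike runs.

    Rows are cells, columns frames.  ``fit`` computes and stores the
    detrended matrix, the binary activity and per-cell onsets;
    ``transform`` returns the binary activity for the fitted data (the
    operation is per-row and stateless across cells).

    Parameters mirror the detrending/binarization knobs of
    :class:`~calcomm.traces.AnalysisParameters`.
    """

    def __init__(self, smooth_k: int = 3, bias_k: int = 25, peak_thr: float = 0.3, bin_thr: float = 0.4):
        self.smooth_k = smooth_k
        self.bias_k = bias_k
        self.peak_thr = peak_thr
        self.bin_thr = bin_thr

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_cells, n_frames)")
        self.detrended_ = detrend(X, self.smooth_k, self.bias_k)
        self.active_ = np.atleast_2d(binarize(self.detrended_, self.peak_thr, self.bin_thr))
        self.onsets_ = [np.array([s for s, _ in runs_of(r)], dtype=int) for r in self.active_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X=None):
        return self.active_


def build_activity(
    normalized: NormalizedTraces | np.ndarray, params: AnalysisParameters | None = None
) -> ActivityMatrix:
    """Run detrending + binarization on a normalized trace matrix."""
    params = params or AnalysisParameters()
    values = normalized.values if isinstance(normalized, NormalizedTraces) else np.asarray(normalized)
    sb = SpikeBinarizer(params.smooth_k, params.bias_k, params.peak_thr, params.bin_thr).fit(values)
    return ActivityMatrix(active=sb.active_, detrended=sb.detrended_, onsets=sb.onsets_)


def activation_rate(activity: ActivityMatrix, frame_interval: float) -> tuple[np.ndarray, float]:
    """Per-cell and mean activation rate in activations per minute.

    An activation is one spike onset; the rate divides the onset count by
    the recording duration in minutes.
    """
    if frame_interval <= 0 or activity.n_frames == 0:
        raise ValueError("recording must have positive duration")
    minutes = activity.n_frames * frame_interval / 60.0
    per_cell = activity.onset_counts() / minutes
    return per_cell, float(per_cell.mean())


def local_density(positions: np.ndarray, window: float = 14.0) -> tuple[np.ndarray, float]:
    """Number of other cells in an axis-aligned window x window um square
    centred on each cell (self excluded), and the mean over cells."""
    if window <= 0:
        raise ValueError("window must be > 0")
    pos = np.asarray(positions, dtype=float)
    half = window / 2.0
    dx = np.abs(pos[:, 0][:, None] - pos[:, 0][None, :])
    dy = np.abs(pos[:, 1][:, None] - pos[:, 1][None, :])
    inside = (dx <= half) & (dy <= half)
    np.fill_diagonal(inside, False)
    per_cell = inside.sum(axis=1)
    return per_cell, float(per_cell.mean())


def spike_magnitude_zscore(
    normalized: np.ndarray, activity: ActivityMatrix, guard: int = 3
) -> np.ndarray:
    """Relative spike magnitude per cell: mean z-score of spike peaks
    against the cell's background.

    Background frames are those farther than ``guard`` frames from every
    active frame.  A spike's magnitude is the z-score of its peak
    normalized value against the background mean and SD; the cell value is
    the mean over its spikes.  Cells with no spikes, fewer than 2
    background frames, or zero background SD are returned as NaN.
    """
    values = np.atleast_2d(np.asarray(normalized, dtype=float))
    out = np.full(values.shape[0], np.nan)
    structure = np.ones(2 * guard + 1, dtype=bool)
    for i in range(values.shape[0]):
        row_active = activity.active[i]
        spike_runs = runs_of(row_active)
        if not spike_runs:
            continue
        background = ~binary_dilation(row_active, structure=structure)
        if background.sum() < 2:
            continue
        mu = values[i, background].mean()
        sd = values[i, background].std(ddof=1)
        if sd == 0:
            continue
        zs = [(values[i, s : e + 1].max() - mu) / sd for s, e in spike_runs]
        out[i] = float(np.mean(zs))
    return out
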