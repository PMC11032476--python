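"""Data model and I/O for single-cell Ca2+ imaging recordings.

A recording is a set of cells with static 2-D centroid coordinates (in
micrometres) and one raw fluorescence trace per cell, sampled at a fixed
frame interval.  Traces are brought to a common scale by per-cell min-max
normalization, F'_t = (F_t - F_min) / (F_max - F_min), so that every cell's
trace spans [0, 1] regardless of expression level or imaging gain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "AnalysisParameters",
    "Recording",
    "NormalizedTraces",
    "TraceNormalizer",
    "read_recording",
    "write_recording",
    "normalize",
]


@dataclass(frozen=True)
class AnalysisParameters:
    """Tunable parameters of the community-detection pipeline.

    Distances are in micrometres, times in seconds, and the smoothing /
    baseline windows in frames.  ``max_lag`` (seconds) is converted to
    frames with ``lag_frames``; window parameters stay frame-based because
    running medians operate on samples.

    Attributes
    ----------
    eps : float
        Distance threshold (um) for two cells to count as neighbors, both
        for within-frame clustering and for frame-to-frame event linking.
    min_total_event_size : int
        Minimum number of distinct cells an event must accumulate over its
        lifetime to be reported.
    min_cluster_size : int
        Minimum number of co-active cells a within-frame cluster needs to
        enter the linking stage (1 allows single-cell growth steps).
    max_lag : float
        Maximum time (s) between activations that still links them into
        the same event.
    min_duration : int
        Minimum event lifetime in frames.
    smooth_k, bias_k : int
        Short running-median smoothing window and long running-median
        baseline window (frames) for detrending.
    peak_thr, bin_thr : float
        Peak- and binarization thresholds on the rescaled detrended trace.
    close_far_cutoff : float
        Distance (um) splitting cell pairs into close/far groups.
    density_window : float
        Side (um) of the axis-aligned square used for local cell density.
    n_permutations : int
        Number of spatial permutations for the shuffle test.
    alpha : float
        Significance level used throughout.
    """

    eps: float = 14.0
    min_total_event_size: int = 3
    min_cluster_size: int = 1
    max_lag: float = 15.0
    min_duration: int = 1
    smooth_k: int = 3
    bias_k: int = 25
    peak_thr: float = 0.3
    bin_thr: float = 0.4
    close_far_cutoff: float = 14.0
    density_window: float = 14.0
    n_permutations: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.max_lag <= 0:
            raise ValueError("max_lag must be > 0")
        if self.min_total_event_size < 1 or self.min_cluster_size < 1:
            raise ValueError("event/cluster size floors must be >= 1")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")

    def lag_frames(self, frame_interval: float) -> int:
        """Maximum linking lag in frames: ceil(max_lag / frame_interval)."""
        if frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        return max(1, math.ceil(self.max_lag / frame_interval))

    def replace(self, **kwargs) -> "AnalysisParameters":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


@dataclass
class Recording:
    """One imaging recording: cells, coordinates and raw traces.

    Parameters
    ----------
    cell_ids : sequence of str
        Unique cell identifiers, ordered as the rows of ``raw``.
    positions : (n_cells, 2) float array
        Static cell-centroid coordinates in micrometres.
    raw : (n_cells, n_frames) float array
        Raw fluorescence intensities (arbitrary units).
    frame_interval : float
        Seconds per frame (> 0).
    metadata : dict
        Free-form metadata; conventional keys: ``condition``, ``stage``,
        ``recording_id``.
    """

    cell_ids: list
    positions: np.ndarray
    raw: np.ndarray
    frame_interval: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.positions = np.asarray(self.positions, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique within a recording")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must have shape (n_cells, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("cell coordinates must be finite")
        if self.raw.ndim != 2 or self.raw.shape[0] != n:
            raise ValueError("raw must have one row per cell")
        if self.raw.shape[1] < 2:
            raise ValueError("raw must contain at least 2 frames")
        if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
            raise ValueError("frame_interval must be a positive number")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


@dataclass
class NormalizedTraces:
    """Per-cell min-max normalized traces with the scaling retained."""

    values: np.ndarray  # (n_cells, n_frames) in [0, 1]
    f_min: np.ndarray
    f_max: np.ndarray
    constant_cells: list  # row indices of flat traces, mapped to all-zero

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


class TraceNormalizer(BaseEstimator, TransformerMixin):
    """Min-max normalization of fluorescence traces, one scale per cell.

    Rows of the input are cells (samples), columns are frames.  Unlike
    column-wise feature scalers, the scaling here is per *row*: each cell's
    trace is mapped by (F - F_min) / (F_max - F_min) so its minimum frame
    maps to 0 and its maximum frame to 1.  Constant rows are mapped to
    all-zero and reported in ``constant_cells_`` rather than dropped, so
    the cell roster (and hence geometry) is preserved downstream.

    Attributes
    ----------
    f_min_, f_max_ : (n_cells,) arrays
        Per-row extrema seen at fit time.
    constant_cells_ : list of int
        Row indices with F_max == F_min.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (n_cells, n_frames) with >= 2 frames")
        if not np.all(np.isfinite(X)):
            raise ValueError("traces must be finite")
        self.f_min_ = X.min(axis=1)
        self.f_max_ = X.max(axis=1)
        self.constant_cells_ = np.flatnonzero(self.f_max_ == self.f_min_).tolist()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        span = self.f_max_ - self.f_min_
        safe = np.where(span > 0, span, 1.0)
        out = (X - self.f_min_[:, None]) / safe[:, None]
        if self.constant_cells_:
            out[self.constant_cells_, :] = 0.0
            warnings.warn(
                f"{len(self.constant_cells_)} constant trace(s) normalized to "
                f"zero (rows {self.constant_cells_})",
                stacklevel=2,
            )
        return out


def normalize(recording: Recording | np.ndarray) -> NormalizedTraces:
    """Min-max normalize each cell's raw trace to [0, 1].

    Accepts a :class:`Recording` or a bare (n_cells, n_frames) matrix.
    Constant traces map to all-zero and are listed in ``constant_cells``.
    """
    raw = recording.raw if isinstance(recording, Recording) else np.asarray(recording, float)
    tn = TraceNormalizer().fit(raw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = tn.transform(raw)
    if tn.constant_cells_:
        warnings.warn(
            f"constant trace(s) at rows {tn.constant_cells_}: normalized to zero "
            "and excluded from spike calling",
            stacklevel=2,
        )
    return NormalizedTraces(
        values=values, f_min=tn.f_min_, f_max=tn.f_max_, constant_cells=tn.constant_cells_
    )


_WIDE_META = ("cell_id", "x", "y")


def read_recording(
    path,
    layout: str = "wide",
    frame_interval: float = 1.0,
    metadata: dict | None = None,
) -> Recording:
    """Read a recording from CSV.

    Two layouts are accepted, matching common ROI-intensity exports:

    ``wide``
        One row per cell with columns ``cell_id, x, y`` followed by one
        column per frame (any names; file order defines frame order).
    ``long``
        Columns ``cell_id, frame, intensity, x, y`` with one row per
        (cell, frame); ``x``/``y`` must be constant within a cell.

    Cells are ordered by first appearance.  Missing coordinates or an
    incomplete (ragged) trace raise a ``ValueError`` naming the cell.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "wide":
        missing = [c for c in _WIDE_META if c not in df.columns]
        if missing:
            raise ValueError(f"wide layout requires columns {missing}")
        frame_cols = [c for c in df.columns if c not in _WIDE_META]
        if len(frame_cols) < 2:
            raise ValueError("wide layout needs at least 2 frame columns")
        cell_ids = df["cell_id"].astype(str).tolist()
        for cid, row in zip(cell_ids, df.itertuples(index=False)):
            if not (np.isfinite(row.x) and np.isfinite(row.y)):
                raise ValueError(f"cell {cid!r}: missing or non-finite coordinates")
        raw = df[frame_cols].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.all(np.isfinite(raw), axis=1))
        if bad.size:
            raise ValueError(f"cell {cell_ids[bad[0]]!r}: incomplete or non-numeric trace")
        positions = df[["x", "y"]].to_numpy(dtype=float)
    else:
        required = ["cell_id", "frame", "intensity", "x", "y"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"long layout requires columns {missing}")
        df = df.copy()
        df["cell_id"] = df["cell_id"].astype(str)
        cell_ids = list(dict.fromkeys(df["cell_id"]))  # order of first appearance
        frames = np.sort(df["frame"].unique())
        if len(frames) < 2:
            raise ValueError("long layout needs at least 2 frames")
        expected = set(frames.tolist())
        raw = np.empty((len(cell_ids), len(frames)))
        positions = np.empty((len(cell_ids), 2))
        frame_pos = {f: i for i, f in enumerate(frames)}
        for i, cid in enumerate(cell_ids):
            sub = df[df["cell_id"] == cid]
            got = set(sub["frame"].tolist())
            if got != expected:
                lost = sorted(expected - got)
                raise ValueError(f"cell {cid!r}: missing frame(s) {lost[:5]}")
            xs, ys = sub["x"].unique(), sub["y"].unique()
            if len(xs) != 1 or len(ys) != 1:
                raise ValueError(f"cell {cid!r}: inconsistent coordinates across frames")
            if not (np.isfinite(xs[0]) and np.isfinite(ys[0])):
                raise ValueError(f"cell {cid!r}: missing or non-finite coordinates")
            positions[i] = (xs[0], ys[0])
            idx = sub["frame"].map(frame_pos).to_numpy()
            vals = sub["intensity"].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"cell {cid!r}: incomplete or non-numeric trace")
            raw[i, idx] = vals
    return Recording(
        cell_ids=cell_ids,
        positions=positions,
        raw=raw,
        frame_interval=frame_interval,
        metadata=dict(metadata or {}),
    )


def write_recording(recording: Recording, path, layout: str = "wide") -> None:
    """Write a recording to CSV in the ``wide`` or ``long`` layout."""
    if layout == "wide":
        data = {
            "cell_id": recording.cell_ids,
            "x": recording.positions[:, 0],
            "y": recording.positions[:, 1],
        }
        for t in range(recording.n_frames):
            data[f"f{t:05d}"] = recording.raw[:, t]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        n, T = recording.n_cells, recording.n_frames
        pd.DataFrame(
            {
                "cell_id": np.repeat(recording.cell_ids, T),
                "frame": np.tile(np.arange(T), n),
                "intensity": recording.raw.ravel(),
                "x": np.repeat(recording.positions[:, 0], T),
                "y": np.repeat(recording.positions[:, 1], T),
            }
        ).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")
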