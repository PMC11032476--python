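"""Detection of transient multicellular signaling communities.

Active cells are grouped into collective events by spatiotemporal
linking: within each frame, co-active cells closer than ``eps`` are
clustered by single linkage; a cluster joins an existing event when any
of its cells lies within ``eps`` of a cell that was active in that event
during the preceding lag window (``max_lag`` seconds, converted to
frames).  Clusters that link several events merge them; unlinked
clusters seed new events; an event closes after a full lag window of
silence.  Events smaller than ``min_total_event_size`` distinct cells or
shorter than ``min_duration`` frames are discarded.

``brute_force_events`` is an independent oracle for small instances: it
builds the graph whose nodes are (cell, active-run) pairs, connects runs
within ``eps`` whose temporal gap is at most the lag window, and reads
events off the connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .activity import ActivityMatrix, runs_of
from .traces import AnalysisParameters

__all__ = [
    "CollectiveEvent",
    "EventSummary",
    "CollectiveEventDetector",
    "adjacency_matrix",
    "detect_events",
    "brute_force_events",
    "summarize_event",
    "propagation_speed",
    "pooled_speeds",
]


@dataclass(frozen=True)
class CollectiveEvent:
    """One transient community.

    ``members_by_frame`` maps each active frame of the event to the set of
    cell indices assigned to it in that frame; ``participants`` is their
    union over the event lifetime.
    """

    event_id: int
    members_by_frame: dict  # {frame: frozenset(cell indices)}
    participants: frozenset
    start_frame: int
    end_frame: int

    @property
    def frames(self) -> list[int]:
        return sorted(self.members_by_frame)

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def first_activation(self) -> dict:
        """First frame at which each participant is active within the event."""
        first: dict = {}
        for t in self.frames:
            for c in self.members_by_frame[t]:
                first.setdefault(c, t)
        return first

    def cell_frame_set(self) -> frozenset:
        return frozenset(
            (c, t) for t, cells in self.members_by_frame.items() for c in cells
        )


@dataclass(frozen=True)
class EventSummary:
    size: int
    max_concurrent: int
    duration_frames: int
    duration_s: float


def adjacency_matrix(positions: np.ndarray, eps: float) -> np.ndarray:
    """Boolean neighbor matrix: Euclidean distance <= eps (diagonal True)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    pos = np.asarray(positions, dtype=float)
    adj = squareform(pdist(pos) <= eps).astype(bool)
    np.fill_diagonal(adj, True)
    return adj


def neighbor_sets(adjacency: np.ndarray) -> list[set]:
    """Per-cell neighbor sets (cell included) from a boolean adjacency."""
    return [set(np.flatnonzero(row).tolist()) for row in np.asarray(adjacency, bool)]


def _as_neighbor_sets(adjacency, positions, eps: float) -> list[set]:
    if adjacency is None:
        return neighbor_sets(adjacency_matrix(positions, eps))
    if isinstance(adjacency, np.ndarray):
        return neighbor_sets(adjacency)
    return adjacency  # already a list of sets


def _frame_clusters(act: list[int], neighbors: list[set]) -> list[list[int]]:
    """Single-linkage components of the co-active cells at one frame."""
    if len(act) == 1:
        return [act]
    parent = {c: c for c in act}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    act_set = set(act)
    for c in act:
        for nb in neighbors[c] & act_set:
            if nb <= c:
                continue
            ra, rb = find(c), find(nb)
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for c in act:
        groups.setdefault(find(c), []).append(c)
    return list(groups.values())


def detect_events(
    activity: ActivityMatrix | np.ndarray,
    positions: np.ndarray,
    params: AnalysisParameters | None = None,
    frame_interval: float = 1.0,
    adjacency: np.ndarray | None = None,
) -> list[CollectiveEvent]:
    """Detect collective events by incremental spatiotemporal linking.

    ``activity`` may be an :class:`ActivityMatrix` or a bare boolean
    matrix.  ``adjacency`` can be supplied to reuse a precomputed
    neighbor matrix (positions then only define the roster size).
    """
    params = params or AnalysisParameters()
    active = activity.active if isinstance(activity, ActivityMatrix) else np.asarray(activity, bool)
    positions = np.asarray(positions, dtype=float)
    if active.shape[0] != positions.shape[0]:
        raise ValueError("activity and positions must share the cell roster")
    neighbors = _as_neighbor_sets(adjacency, positions, params.eps)
    lag = params.lag_frames(frame_interval)
    n, T = active.shape

    live: list[dict] = []
    closed: list[dict] = []
    frames_nz, cells_nz = np.nonzero(active.T)
    splits = np.searchsorted(frames_nz, np.arange(1, T))
    active_cols = [a.tolist() for a in np.split(cells_nz, splits)]
    for t in range(T):
        act = active_cols[t]
        if live:
            still = []
            for ev in live:
                (closed if ev["last"] < t - lag else still).append(ev)
            live = still
        if not act:
            continue
        clusters = _frame_clusters(act, neighbors)
        if params.min_cluster_size > 1:
            clusters = [c for c in clusters if len(c) >= params.min_cluster_size]
        lo = t - lag
        for cl in clusters:
            targets = []
            for ev in live:
                cells = ev["cells"]
                linked = False
                for c in cl:
                    for nb in neighbors[c]:
                        lf = cells.get(nb)
                        if lf is not None and lo <= lf <= t - 1:
                            linked = True
                            break
                    if linked:
                        break
                if linked:
                    targets.append(ev)
            if not targets:
                ev = {"cells": {}, "frames": {}, "last": t}
                live.append(ev)
            else:
                ev = targets[0]
                for other in targets[1:]:
                    for c, lf in other["cells"].items():
                        ev["cells"][c] = max(lf, ev["cells"].get(c, -1))
                    for f, cells in other["frames"].items():
                        ev["frames"].setdefault(f, set()).update(cells)
                    ev["last"] = max(ev["last"], other["last"])
                    live.remove(other)
            for c in cl:
                ev["cells"][c] = t
            ev["frames"].setdefault(t, set()).update(cl)
            ev["last"] = t
    closed.extend(live)

    out: list[CollectiveEvent] = []
    for ev in closed:
        participants = frozenset(ev["cells"])
        frames = sorted(ev["frames"])
        duration = frames[-1] - frames[0] + 1
        if len(participants) < params.min_total_event_size or duration < params.min_duration:
            continue
        out.append((frames[0], ev))
    out.sort(key=lambda pair: (pair[0], min(pair[1]["cells"])))
    return [
        CollectiveEvent(
            event_id=i,
            members_by_frame={f: frozenset(cells) for f, cells in ev["frames"].items()},
            participants=frozenset(ev["cells"]),
            start_frame=min(ev["frames"]),
            end_frame=max(ev["frames"]),
        )
        for i, (_, ev) in enumerate(out)
    ]


def brute_force_events(
    activity: ActivityMatrix | np.ndarray,
    positions: np.ndarray,
    params: AnalysisParameters | None = None,
    frame_interval: float = 1.0,
) -> list[CollectiveEvent]:
    """Exhaustive run-graph oracle for event detection (test-sized inputs).

    Refuses instances with more than 12 cells or 40 frames; requires
    ``min_cluster_size == 1`` (the configuration under which the linking
    semantics and the run graph coincide).
    """
    import networkx as nx

    params = params or AnalysisParameters()
    active = activity.active if isinstance(activity, ActivityMatrix) else np.asarray(activity, bool)
    n, T = active.shape
    if n > 12 or T > 40:
        raise ValueError("brute_force_events is an oracle for <= 12 cells, <= 40 frames")
    if params.min_cluster_size != 1:
        raise ValueError("oracle defined for min_cluster_size == 1")
    positions = np.asarray(positions, dtype=float)
    adj = adjacency_matrix(positions, params.eps)
    lag = params.lag_frames(frame_interval)

    nodes = []
    for c in range(n):
        for s, e in runs_of(active[c]):
            nodes.append((c, s, e))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, (c1, s1, e1) in enumerate(nodes):
        for c2, s2, e2 in nodes[i + 1 :]:
            if adj[c1, c2] and s2 <= e1 + lag and s1 <= e2 + lag:
                g.add_edge((c1, s1, e1), (c2, s2, e2))

    events = []
    for comp in nx.connected_components(g):
        participants = frozenset(c for c, _, _ in comp)
        frames: dict[int, set] = {}
        for c, s, e in comp:
            for f in range(s, e + 1):
                frames.setdefault(f, set()).add(c)
        start, end = min(frames), max(frames)
        if len(participants) < params.min_total_event_size:
            continue
        if end - start + 1 < params.min_duration:
            continue
        events.append((start, frames, participants))
    events.sort(key=lambda tup: (tup[0], min(p for cells in tup[1].values() for p in cells)))
    return [
        CollectiveEvent(
            event_id=i,
            members_by_frame={f: frozenset(cells) for f, cells in frames.items()},
            participants=participants,
            start_frame=min(frames),
            end_frame=max(frames),
        )
        for i, (_, frames, participants) in enumerate(events)
    ]


def summarize_event(event: CollectiveEvent, frame_interval: float = 1.0) -> EventSummary:
    """Participant count, maximum concurrency and duration of one event."""
    max_concurrent = max(len(cells) for cells in event.members_by_frame.values())
    return EventSummary(
        size=len(event.participants),
        max_concurrent=max_concurrent,
        duration_frames=event.duration_frames,
        duration_s=event.duration_frames * frame_interval,
    )


def propagation_speed(
    event: CollectiveEvent,
    positions: np.ndarray,
    frame_interval: float,
    eps: float = 14.0,
) -> float:
    """Mean intercellular signaling propagation speed of one event (um/s).

    Over all participant pairs within ``eps`` whose first activations in
    the event fall on distinct frames, the pair speed is distance divided
    by the absolute activation-time difference; the event speed is the
    mean over such pairs.  An event with no sequential adjacent pair
    (fully simultaneous activation) has speed 0.
    """
    positions = np.asarray(positions, dtype=float)
    first = event.first_activation()
    cells = sorted(first)
    speeds = []
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            d = float(np.linalg.norm(positions[a] - positions[b]))
            if d > eps:
                continue
            dt = abs(first[a] - first[b]) * frame_interval
            if dt > 0:
                speeds.append(d / dt)
    return float(np.mean(speeds)) if speeds else 0.0


def pooled_speeds(
    events: list[CollectiveEvent],
    positions: np.ndarray,
    frame_interval: float,
    eps: float = 14.0,
) -> list[float]:
    """Per-event propagation speeds (one value per community)."""
    return [propagation_speed(e, positions, frame_interval, eps) for e in events]


class CollectiveEventDetector(BaseEstimator):
    """Estimator facade over :func:`detect_events`.

    Parameters mirror :class:`~calcomm.traces.AnalysisParameters`;
    ``fit`` takes the binary activity matrix as ``X`` plus the cell
    positions and frame interval, and exposes the detected events and
    per-cell participation counts as fitted attributes.
    """

    def __init__(
        self,
        eps: float = 14.0,
        min_total_event_size: int = 3,
        min_cluster_size: int = 1,
        max_lag: float = 15.0,
        min_duration: int = 1,
    ):
        self.eps = eps
        self.min_total_event_size = min_total_event_size
        self.min_cluster_size = min_cluster_size
        self.max_lag = max_lag
        self.min_duration = min_duration

    def _params(self) -> AnalysisParameters:
        return AnalysisParameters(
            eps=self.eps,
            min_total_event_size=self.min_total_event_size,
            min_cluster_size=self.min_cluster_size,
            max_lag=self.max_lag,
            min_duration=self.min_duration,
        )

    def fit(self, X, y=None, *, positions, frame_interval: float = 1.0):
        active = X.active if isinstance(X, ActivityMatrix) else np.asarray(X, bool)
        self.events_ = detect_events(active, positions, self._params(), frame_interval)
        self.n_events_ = len(self.events_)
        counts = np.zeros(active.shape[0], dtype=int)
        for ev in self.events_:
            for c in ev.participants:
                counts[c] += 1
        self.participation_counts_ = counts
        return self
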