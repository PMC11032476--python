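"""Recurrent-community hotspots: detection, bootstrap validation and
hotspot-environment interaction statistics.

A hotspot is a connected group (in the <= eps neighbor graph) of at
least three cells whose participation counts in collective events reach
the recording-specific threshold max(5, max_count / 2).  Validation
swaps the traces of hotspot cells with activity-matched non-hotspot
cells (each match must have at least as many activations) and asks how
often the hotspot-cell MEC of such activity-preserving permutations
reaches the observed one; recurrence that is a mere consequence of high
per-cell activity survives the swap and is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError
from sklearn.base import BaseEstimator

from .activity import ActivityMatrix
from .events import CollectiveEvent, adjacency_matrix, detect_events, neighbor_sets
from .traces import AnalysisParameters

__all__ = [
    "Hotspot",
    "HotspotValidation",
    "InteractionProfile",
    "HotspotDetector",
    "participation_counts",
    "detect_hotspots",
    "validate_hotspot",
    "hotspot_mec",
    "interaction_probability",
    "initiation_fraction",
    "transmission_probability",
    "expected_initiator_probability",
    "interaction_profile",
]


@dataclass(frozen=True)
class Hotspot:
    """A candidate hotspot: connected above-threshold cells + hull."""

    hotspot_id: int
    members: frozenset  # cell indices
    hull_vertices: np.ndarray | None  # (k, 2) polygon vertices, or None if degenerate
    hull_area: float
    threshold: float  # participation threshold used (max(5, lg_max / 2))
    lg_max: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HotspotValidation:
    """Outcome of the activity-matched trace-swap bootstrap."""

    observed_mec: float  # MEC over hotspot member cells
    permuted_mecs: np.ndarray
    n_valid_permutations: int
    n_tries: int
    p_value: float  # NaN when insufficient data
    status: str  # validated | not_significant | insufficient_data
    seed: int | None = None
    duplicate_matchings: int = 0


@dataclass(frozen=True)
class InteractionProfile:
    """How a hotspot exchanges signaling with its surroundings."""

    hotspot_size: int
    n_hotspot_communities: int
    p_interact: float  # P(hotspot community involves a non-hotspot cell)
    init_fraction: float  # fraction of mixed communities initiated inside
    transmission_prob: float  # P(hotspot cell fires first in adjacent mixed pairs)
    expected_initiator_prob: float  # mean hotspot-cell proportion in hotspot communities


def participation_counts(events: list[CollectiveEvent], n_cells: int) -> np.ndarray:
    """Number of distinct collective events each cell participates in."""
    counts = np.zeros(n_cells, dtype=int)
    for ev in events:
        for c in ev.participants:
            counts[c] += 1
    return counts


def detect_hotspots(
    counts: np.ndarray,
    positions: np.ndarray,
    eps: float = 14.0,
    min_size: int = 3,
) -> list[Hotspot]:
    """Hotspot candidates from participation counts.

    The threshold is max(5, lg_max / 2) where lg_max is the highest
    per-cell count (kept as a real number; cells qualify when count >=
    threshold).  Connected components of qualifying cells in the <= eps
    neighbor graph with at least ``min_size`` members become candidates,
    each with its convex hull (hull is None for degenerate geometry).
    """
    counts = np.asarray(counts)
    positions = np.asarray(positions, dtype=float)
    lg_max = int(counts.max()) if counts.size else 0
    threshold = max(5.0, lg_max / 2.0)
    marked = np.flatnonzero(counts >= threshold)
    if marked.size == 0:
        return []
    adj = adjacency_matrix(positions[marked], eps)
    n_comp, labels = connected_components(adj, directed=False)
    hotspots = []
    hid = 0
    for k in range(n_comp):
        members = marked[labels == k]
        if members.size < min_size:
            continue
        pts = positions[members]
        try:
            hull = ConvexHull(pts)
            vertices = pts[hull.vertices]
            area = float(hull.volume)  # 2-D: volume is the polygon area
        except QhullError:
            vertices, area = None, 0.0
        hotspots.append(
            Hotspot(
                hotspot_id=hid,
                members=frozenset(int(c) for c in members),
                hull_vertices=vertices,
                hull_area=area,
                threshold=threshold,
                lg_max=lg_max,
            )
        )
        hid += 1
    return hotspots


def hotspot_mec(events: list[CollectiveEvent], members) -> float:
    """Mean number of distinct events per hotspot member cell."""
    members = set(members)
    total = sum(len(members & ev.participants) for ev in events)
    return total / len(members)


def validate_hotspot(
    hotspot: Hotspot,
    activity: ActivityMatrix,
    positions: np.ndarray,
    params: AnalysisParameters | None = None,
    frame_interval: float = 1.0,
    max_tries: int = 1000,
    seed: int | None = None,
    min_valid: int = 100,
) -> HotspotValidation:
    """Activity-matched trace-swap bootstrap for one hotspot candidate.

    Per permutation, each hotspot cell is matched uniformly at random
    (without replacement) to a distinct non-hotspot cell with at least as
    many activations; the permutation is valid when at least half the
    hotspot cells are matched.  Matched pairs swap traces, events are
    re-detected and the MEC over the hotspot member positions recorded.
    The p-value is the fraction of valid permutations whose hotspot MEC
    is >= the observed one.  A candidate needs >= ``min_valid`` valid
    permutations to be testable; p <= alpha then validates it.
    """
    params = params or AnalysisParameters()
    positions = np.asarray(positions, dtype=float)
    n = activity.n_cells
    members = sorted(hotspot.members)
    others = np.array([c for c in range(n) if c not in hotspot.members])
    act_counts = activity.onset_counts()
    nbrs = neighbor_sets(adjacency_matrix(positions, params.eps))
    observed_events = detect_events(activity.active, positions, params, frame_interval, adjacency=nbrs)
    observed = hotspot_mec(observed_events, members)
    need = int(np.ceil(len(members) / 2.0))

    rng = np.random.default_rng(seed)
    permuted = []
    seen: dict = {}
    duplicates = 0
    for _ in range(int(max_tries)):
        order = rng.permutation(len(members))
        used = np.zeros(others.size, dtype=bool)
        matching = {}
        for mi in order:
            m = members[mi]
            cand = np.flatnonzero(~used & (act_counts[others] >= act_counts[m]))
            if cand.size == 0:
                continue
            pick = cand[rng.integers(cand.size)]
            used[pick] = True
            matching[m] = int(others[pick])
        if len(matching) < need:
            continue
        key = tuple(sorted(matching.items()))
        if key in seen:
            duplicates += 1
        else:
            seen[key] = True
        idx = np.arange(n)
        for m, c in matching.items():
            idx[m], idx[c] = c, m
        ev = detect_events(activity.active[idx], positions, params, frame_interval, adjacency=nbrs)
        permuted.append(hotspot_mec(ev, members))
    permuted = np.asarray(permuted)
    n_valid = permuted.size
    if duplicates:
        warnings.warn(f"{duplicates} duplicate matching map(s) among valid permutations", stacklevel=2)
    if n_valid == 0:
        return HotspotValidation(
            observed_mec=observed,
            permuted_mecs=permuted,
            n_valid_permutations=0,
            n_tries=int(max_tries),
            p_value=float("nan"),
            status="insufficient_data",
            seed=seed,
        )
    p = float((permuted >= observed).mean())
    if n_valid < min_valid:
        status = "insufficient_data"
    elif p <= params.alpha:
        status = "validated"
    else:
        status = "not_significant"
    return HotspotValidation(
        observed_mec=observed,
        permuted_mecs=permuted,
        n_valid_permutations=int(n_valid),
        n_tries=int(max_tries),
        p_value=p,
        status=status,
        seed=seed,
        duplicate_matchings=duplicates,
    )


def _hotspot_communities(hotspot: Hotspot, events: list[CollectiveEvent]) -> list[CollectiveEvent]:
    return [ev for ev in events if ev.participants & hotspot.members]


def interaction_probability(hotspot: Hotspot, events: list[CollectiveEvent]) -> float:
    """Fraction of hotspot communities that involve >= 1 non-hotspot cell.

    A hotspot community is any collective event containing at least one
    hotspot cell.  NaN (with a warning) when there are none.
    """
    hc = _hotspot_communities(hotspot, events)
    if not hc:
        warnings.warn("no hotspot communities; interaction probability undefined", stacklevel=2)
        return float("nan")
    mixed = sum(1 for ev in hc if ev.participants - hotspot.members)
    return mixed / len(hc)


def initiation_fraction(hotspot: Hotspot, events: list[CollectiveEvent]) -> float:
    """Fraction of mixed hotspot communities initiated by hotspot cells.

    Initiators are the cells active in a community's first frame.  Mixed
    communities whose first frame contains both hotspot and non-hotspot
    cells are excluded as ambiguous.  NaN when every community is
    excluded or there are no mixed communities.
    """
    mixed = [
        ev for ev in _hotspot_communities(hotspot, events) if ev.participants - hotspot.members
    ]
    inside = 0
    retained = 0
    for ev in mixed:
        initiators = ev.members_by_frame[ev.start_frame]
        has_in = bool(initiators & hotspot.members)
        has_out = bool(initiators - hotspot.members)
        if has_in and has_out:
            continue
        retained += 1
        if has_in:
            inside += 1
    if retained == 0:
        warnings.warn("no unambiguous mixed communities; initiation fraction undefined", stacklevel=2)
        return float("nan")
    return inside / retained


def transmission_probability(
    hotspot: Hotspot,
    events: list[CollectiveEvent],
    positions: np.ndarray,
    eps: float = 14.0,
) -> float:
    """P(hotspot cell activates first) over adjacent mixed sequential pairs.

    Pairs are (hotspot cell, non-hotspot cell) within one community at
    distance <= eps whose first activations fall on distinct frames;
    same-frame pairs are excluded from the denominator.  NaN when no
    qualifying pair exists.
    """
    positions = np.asarray(positions, dtype=float)
    first_earlier = 0
    total = 0
    for ev in _hotspot_communities(hotspot, events):
        outside = ev.participants - hotspot.members
        if not outside:
            continue
        first = ev.first_activation()
        for h in ev.participants & hotspot.members:
            for o in outside:
                if np.linalg.norm(positions[h] - positions[o]) > eps:
                    continue
                if first[h] == first[o]:
                    continue
                total += 1
                if first[h] < first[o]:
                    first_earlier += 1
    if total == 0:
        warnings.warn("no qualifying hotspot/non-hotspot pairs; transmission undefined", stacklevel=2)
        return float("nan")
    return first_earlier / total


def expected_initiator_probability(hotspot: Hotspot, events: list[CollectiveEvent]) -> float:
    """Mean proportion of hotspot cells across hotspot communities.

    Under random activation order within a community, this proportion is
    the expected probability that a hotspot cell initiates it.
    """
    hc = _hotspot_communities(hotspot, events)
    if not hc:
        return float("nan")
    props = [len(ev.participants & hotspot.members) / len(ev.participants) for ev in hc]
    return float(np.mean(props))


def interaction_profile(
    hotspot: Hotspot,
    events: list[CollectiveEvent],
    positions: np.ndarray,
    eps: float = 14.0,
) -> InteractionProfile:
    """All hotspot-environment interaction statistics for one hotspot."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return InteractionProfile(
            hotspot_size=hotspot.size,
            n_hotspot_communities=len(_hotspot_communities(hotspot, events)),
            p_interact=interaction_probability(hotspot, events),
            init_fraction=initiation_fraction(hotspot, events),
            transmission_prob=transmission_probability(hotspot, events, positions, eps),
            expected_initiator_prob=expected_initiator_probability(hotspot, events),
        )


class HotspotDetector(BaseEstimator):
    """Estimator facade over :func:`detect_hotspots`.

    ``fit`` takes per-cell participation counts as ``X`` together with
    cell positions and exposes the candidates in ``hotspots_``.
    """

    def __init__(self, eps: float = 14.0, min_size: int = 3):
        self.eps = eps
        self.min_size = min_size

    def fit(self, X, y=None, *, positions):
        self.hotspots_ = detect_hotspots(np.asarray(X), positions, self.eps, self.min_size)
        self.n_hotspots_ = len(self.hotspots_)
        self.threshold_ = self.hotspots_[0].threshold if self.hotspots_ else max(
            5.0, (np.asarray(X).max() if np.asarray(X).size else 0) / 2.0
        )
        return self
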