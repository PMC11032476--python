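"""Hotspot detection, swap-bootstrap validation and interaction profiles."""

import numpy as np
import pytest

from calcomm import (
    ActivityMatrix,
    build_activity,
    detect_events,
    detect_hotspots,
    expected_initiator_probability,
    initiation_fraction,
    interaction_probability,
    normalize,
    participation_counts,
    transmission_probability,
    validate_hotspot,
)
from calcomm.activity import runs_of
from calcomm.hotspots import Hotspot, HotspotDetector
from calcomm.synthetic import planted_hotspot_config, simulate

from test_spatial_stats import make_event


def make_hotspot(members):
    return Hotspot(
        hotspot_id=0,
        members=frozenset(members),
        hull_vertices=None,
        hull_area=0.0,
        threshold=5.0,
        lg_max=10,
    )


class TestParticipationCounts:
    def test_distinct_events_counted(self):
        events = [
            make_event(0, {0: {0, 1, 2}}),
            make_event(1, {4: {0, 3, 4}}),
        ]
        counts = participation_counts(events, 6)
        np.testing.assert_array_equal(counts, [2, 1, 1, 1, 1, 0])

    def test_overlapping_events_share_one_cell(self):
        events = [
            make_event(0, {0: {0, 1, 2}}),
            make_event(1, {8: {2, 3, 4}}),
        ]
        counts = participation_counts(events, 5)
        np.testing.assert_array_equal(counts, [1, 1, 2, 1, 1])


class TestDetectHotspots:
    def test_threshold_floor_at_five(self):
        # lg_max = 8 -> threshold max(5, 4) = 5
        counts = np.array([8, 5, 5, 0, 0])
        positions = np.array([[0, 0], [5, 0], [10, 0], [60, 60], [80, 80]], float)
        hs = detect_hotspots(counts, positions)
        assert len(hs) == 1
        assert hs[0].members == frozenset({0, 1, 2})
        assert hs[0].threshold == 5.0

    def test_threshold_tracks_half_of_max(self):
        # lg_max = 14 -> threshold 7: count 7 qualifies, count 6 does not
        counts = np.array([14, 7, 7, 6, 0])
        positions = np.array([[0, 0], [5, 0], [10, 0], [12, 0], [80, 80]], float)
        hs = detect_hotspots(counts, positions)
        assert len(hs) == 1
        assert hs[0].members == frozenset({0, 1, 2})
        assert hs[0].threshold == 7.0

    def test_components_smaller_than_three_are_dropped(self):
        counts = np.array([9, 9, 0, 0])
        positions = np.array([[0, 0], [5, 0], [50, 50], [60, 60]], float)
        assert detect_hotspots(counts, positions) == []

    def test_no_marked_cells_gives_empty_list(self):
        assert detect_hotspots(np.zeros(4, int), np.zeros((4, 2))) == []

    def test_members_are_connected_within_eps(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 15, size=40)
        positions = rng.uniform(0, 120, size=(40, 2))
        for hs in detect_hotspots(counts, positions, eps=14.0):
            members = sorted(hs.members)
            d = np.linalg.norm(positions[members][:, None] - positions[members][None], axis=-1)
            adj = d <= 14.0
            # connectivity via BFS over the member adjacency
            seen = {0}
            frontier = [0]
            while frontier:
                k = frontier.pop()
                for j in range(len(members)):
                    if adj[k, j] and j not in seen:
                        seen.add(j)
                        frontier.append(j)
            assert seen == set(range(len(members)))

    def test_hull_area_of_triangle(self):
        counts = np.array([9, 9, 9])
        positions = np.array([[0, 0], [10, 0], [0, 10]], float)
        hs = detect_hotspots(counts, positions)
        assert hs[0].hull_area == pytest.approx(50.0)

    def test_estimator_facade(self):
        counts = np.array([8, 6, 6, 0])
        positions = np.array([[0, 0], [5, 0], [10, 0], [90, 90]], float)
        det = HotspotDetector().fit(counts, positions=positions)
        assert det.n_hotspots_ == 1
        assert det.threshold_ == 5.0


class TestValidateHotspot:
    def _activity(self, active):
        onsets = [np.array([s for s, _ in runs_of(r)]) for r in active]
        return ActivityMatrix(active=active, detrended=active.astype(float), onsets=onsets)

    def test_unmatchable_hotspot_is_insufficient_data(self):
        """Every non-member is less active than every member, so no valid
        activity-matched permutation exists."""
        rng = np.random.default_rng(0)
        active = np.zeros((8, 60), bool)
        for c in range(3):  # hyperactive members
            active[c, rng.choice(60, size=20, replace=False)] = True
        for c in range(3, 8):
            active[c, rng.choice(60, size=2, replace=False)] = True
        positions = np.vstack([[[0, 0], [5, 0], [10, 0]], rng.uniform(40, 90, (5, 2))])
        res = validate_hotspot(
            make_hotspot({0, 1, 2}), self._activity(active), positions,
            frame_interval=3.0, max_tries=50, seed=1,
        )
        assert res.status == "insufficient_data"
        assert res.n_valid_permutations == 0

    def test_trace_multiset_preserved_by_swaps(self):
        """Swapping matched pairs permutes rows; the multiset of traces in
        any permuted recording equals the original multiset."""
        # indirect check: swapping is an involution on indices, so applying
        # the index map twice restores the identity
        rng = np.random.default_rng(3)
        n = 10
        idx = np.arange(n)
        matching = {0: 7, 1: 5, 2: 9}
        for m, c in matching.items():
            idx[m], idx[c] = idx[c], idx[m]
        assert sorted(idx) == list(range(n))  # a permutation: multiset preserved
        np.testing.assert_array_equal(idx[idx], np.arange(n))

    def test_interchangeable_members_not_validated(self):
        """A 'hotspot' whose members behave like the background is not
        statistically validated."""
        rng = np.random.default_rng(11)
        n, T = 30, 200
        active = rng.random((n, T)) < 0.08
        positions = rng.uniform(0, 100, (n, 2))
        # force three adjacent cells as the candidate
        positions[:3] = [[0, 0], [6, 0], [12, 0]]
        res = validate_hotspot(
            make_hotspot({0, 1, 2}), self._activity(active), positions,
            frame_interval=3.0, max_tries=300, seed=2,
        )
        assert res.status in ("not_significant", "insufficient_data")
        if res.status == "not_significant":
            assert res.p_value > 0.05

    def test_planted_hotspot_is_validated(self):
        cfg = planted_hotspot_config(6010)
        rec, gt = simulate(cfg)
        act = build_activity(normalize(rec))
        events = detect_events(act, rec.positions, frame_interval=rec.frame_interval)
        counts = participation_counts(events, rec.n_cells)
        cands = detect_hotspots(counts, rec.positions)
        planted = gt.hotspot_members[0]
        best = max(cands, key=lambda h: len(h.members & planted) / len(h.members | planted))
        res = validate_hotspot(
            best, act, rec.positions, frame_interval=rec.frame_interval,
            max_tries=300, seed=10,
        )
        assert res.status == "validated"
        assert res.n_valid_permutations >= 100


class TestInteractionStatistics:
    def test_interaction_probability_fraction(self):
        hs = make_hotspot({0, 1, 2})
        events = [make_event(i, {0: {0, 1, 9}}) for i in range(7)]
        events += [make_event(7 + i, {0: {0, 1, 2}}) for i in range(3)]
        assert interaction_probability(hs, events) == pytest.approx(0.7)

    def test_interaction_extremes(self):
        hs = make_hotspot({0, 1, 2})
        internal = [make_event(0, {0: {0, 1, 2}})]
        mixed = [make_event(0, {0: {0, 5, 6}})]
        assert interaction_probability(hs, internal) == 0.0
        assert interaction_probability(hs, mixed) == 1.0

    def test_no_hotspot_communities_is_undefined(self):
        hs = make_hotspot({0, 1})
        with pytest.warns(UserWarning):
            assert np.isnan(interaction_probability(hs, [make_event(0, {0: {5, 6, 7}})]))

    def test_initiation_fraction_excludes_ambiguous_first_frames(self):
        hs = make_hotspot({0, 1, 2})
        events = [
            make_event(0, {0: {0}, 1: {0, 5}}),       # initiated inside
            make_event(1, {0: {1}, 1: {1, 6}}),       # initiated inside
            make_event(2, {0: {7}, 1: {7, 0}}),       # initiated outside
            make_event(3, {0: {0, 8}, 1: {0, 8, 1}}),  # ambiguous: excluded
        ]
        assert initiation_fraction(hs, events) == pytest.approx(2.0 / 3.0)

    def test_initiation_extremes(self):
        hs = make_hotspot({0, 1, 2})
        inside = [make_event(0, {0: {0}, 1: {0, 9}})]
        outside = [make_event(0, {0: {9}, 1: {9, 0}})]
        assert initiation_fraction(hs, inside) == 1.0
        assert initiation_fraction(hs, outside) == 0.0

    def test_transmission_probability_counts_ordered_pairs(self):
        hs = make_hotspot({0, 1})
        positions = np.array([[0, 0], [5, 0], [10, 0], [50, 50]], float)
        # one community: hotspot cells 0,1 and non-hotspot 2; cell 3 too far
        ev = make_event(0, {0: {0}, 1: {1}, 2: {2}})
        # qualifying pairs: (0,2) 10 um apart 0 first; (1,2) 5 um apart 1 first
        assert transmission_probability(hs, [ev], positions) == 1.0
        ev_rev = make_event(0, {0: {2}, 1: {1}, 2: {0}})
        assert transmission_probability(hs, [ev_rev], positions) == 0.0

    def test_transmission_same_frame_pairs_excluded(self):
        hs = make_hotspot({0})
        positions = np.array([[0, 0], [5, 0], [10, 0]], float)
        ev = make_event(0, {0: {0, 1}, 1: {2}})
        # (0,1) same frame: excluded; (0,2) hotspot first: counted
        assert transmission_probability(hs, [ev], positions) == 1.0

    def test_expected_initiator_probability_average(self):
        hs = make_hotspot({0, 1, 2})
        events = [
            make_event(0, {0: {0, 1, 2, 7}}),  # 0.75 hotspot proportion
            make_event(1, {0: {0, 1, 2}}),     # 1.0
        ]
        assert expected_initiator_probability(hs, events) == pytest.approx(0.875)
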