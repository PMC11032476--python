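"""Shared fixtures: a hand-built propagation-event recording and helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calcomm import Recording

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_propagation_fixture() -> Recording:
    """A recording reproducing one gradually growing transient community.

    Six cells in a 10-um-spaced chain activate sequentially: a 3-cell
    nucleus grows to five concurrently active cells, then shrinks while a
    sixth cell joins late, so the community accumulates 6 participants
    with a per-frame maximum of 5.  Distractors that must not join or
    form events: a far pair of co-active cells (only 2 cells) and
    constant-trace (silent) cells both near and far.
    """
    n_frames = 40
    chain_x = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0]
    positions = [(x, 0.0) for x in chain_x]
    # active frame windows (inclusive) for the six community cells
    windows = [(20, 25), (21, 26), (22, 26), (23, 26), (23, 25), (26, 27)]
    # far co-active pair (60 um off-axis; 5 um apart -> cluster of 2 only)
    positions += [(0.0, 60.0), (5.0, 60.0)]
    windows += [(22, 24), (22, 24)]
    # silent distractors: one near the chain, one far
    positions += [(25.0, 8.0), (120.0, 60.0)]
    windows += [None, None]

    raw = np.full((len(positions), n_frames), 0.1)
    for i, w in enumerate(windows):
        if w is not None:
            raw[i, w[0] : w[1] + 1] = 1.0
    return Recording(
        cell_ids=[f"cell{i}" for i in range(len(positions))],
        positions=np.asarray(positions, dtype=float),
        raw=raw,
        frame_interval=3.0,
        metadata={"recording_id": "propagation-fixture"},
    )


@pytest.fixture
def propagation_recording() -> Recording:
    return build_propagation_fixture()


@pytest.fixture
def small_recording() -> Recording:
    rng = np.random.default_rng(7)
    n, T = 5, 30
    return Recording(
        cell_ids=[f"c{i}" for i in range(n)],
        positions=rng.uniform(0, 60, size=(n, 2)),
        raw=100 + rng.normal(0, 3, size=(n, T)),
        frame_interval=3.0,
    )


def random_activity_instance(rng, max_cells=12, max_frames=40):
    """A random small (activity, positions) instance for oracle sweeps."""
    n = rng.integers(3, max_cells + 1)
    T = rng.integers(6, max_frames + 1)
    positions = rng.uniform(0, 40, size=(n, 2))
    active = rng.random((n, T)) < rng.uniform(0.05, 0.3)
    return active, positions
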