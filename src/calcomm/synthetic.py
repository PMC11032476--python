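"""Synthetic recordings with planted communities, hotspots and cascades.

The generator emulates GCaMP-like recordings of dozens of cells in a
~100-200 um field at 2.3-6.7 s per frame.  Cells fire source spikes as
independent Poisson processes; each spike propagates to neighbors within
the coupling radius with a per-link transmission probability, after a
delay distance / speed plus jitter, with a no-reactivation guard per
cascade.  Fluorescence is a noisy baseline plus a transient kernel per
spike (instant rise, brief plateau, exponential decay).  Hotspot regions
scale the source rate and transmission probability of the cells inside
them.  Ground truth (spike times, propagation parents, cascade rosters,
hotspot memberships) is exported for every recording.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .traces import Recording

__all__ = [
    "HotspotSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "null_recording",
    "activity_confounded_recording",
    "null_config",
    "chain_speed_config",
    "planted_hotspot_config",
    "confounded_hotspot_config",
    "symmetric_coupling_config",
]


@dataclass(frozen=True)
class HotspotSpec:
    """A planted hotspot region.

    ``n_seeded`` cells are placed inside the region (the rest of the
    roster follows the global placement); cells whose centroid falls in
    the region get their source rate multiplied by ``rate_multiplier``
    and their outgoing transmission probability by ``p_t_multiplier``.

    ``arrangement`` controls both seeding and membership geometry:
    ``disc`` seeds uniformly in the disc of ``radius`` around ``center``
    and counts every cell in the disc as a member; ``line`` seeds evenly
    (with jitter) along the x-axis segment of half-length ``radius``
    through ``center`` and counts cells within ``line_margin`` of the
    segment, giving a chain-like hotspot whose local density matches the
    surrounding tissue.
    """

    center: tuple[float, float]
    radius: float
    rate_multiplier: float = 1.0
    p_t_multiplier: float = 1.0
    n_seeded: int = 0
    arrangement: str = "disc"  # disc | line
    line_margin: float = 7.0

    def __post_init__(self) -> None:
        if self.arrangement not in ("disc", "line"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.  Units: um, s, spikes/min."""

    seed: int
    n_cells: int = 50
    field_size: tuple[float, float] = (150.0, 150.0)
    placement: str = "uniform"  # uniform | clustered | chain
    n_clusters: int = 5  # clustered placement: number of cluster centers
    offspring_sd: float = 15.0  # clustered placement: spread around centers
    chain_spacing: float = 10.0  # chain placement: distance between cells
    frame_interval: float = 3.0
    duration: float = 450.0
    baseline_mean: float = 100.0
    baseline_sd: float = 2.5
    spike_amplitude: float = 20.0
    spike_plateau: float = 5.0  # s of near-peak fluorescence after onset
    decay_tau: float = 4.0  # s, exponential decay after the plateau
    spike_rate: float = 1.0  # source spikes per minute per cell
    rate_sigma: float = 0.0  # lognormal per-cell rate heterogeneity (mean-preserving)
    coupling_radius: float = 14.0
    p_transmit: float = 0.35
    speed: float = 1.6  # um/s propagation speed
    delay_jitter: float = 0.2  # +-fraction of the deterministic hop delay
    hotspots: tuple[HotspotSpec, ...] = ()
    mode: str = "wildtype"  # wildtype | uncoupled
    uncoupled_rate_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("n_cells, duration and frame_interval must be positive")
        if self.placement not in ("uniform", "clustered", "chain"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not (0.0 <= self.p_transmit <= 1.0):
            raise ValueError("p_transmit must be in [0, 1]")
        for name in ("baseline_sd", "spike_amplitude", "spike_plateau", "decay_tau",
                     "spike_rate", "rate_sigma", "coupling_radius", "speed", "delay_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("wildtype", "uncoupled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if sum(h.n_seeded for h in self.hotspots) > self.n_cells:
            raise ValueError("seeded hotspot cells exceed n_cells")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted structure of a simulated recording."""

    spikes: list  # rows: dict(cell, time, cascade, parent) -- parent None for sources
    hotspot_members: list  # list of sets of cell indices, one per HotspotSpec
    cascades: dict = field(default_factory=dict)  # cascade id -> set of cells
    config: SimulationConfig | None = None

    def spike_times(self, n_cells: int) -> list:
        out = [[] for _ in range(n_cells)]
        for s in self.spikes:
            out[s["cell"]].append(s["time"])
        return [np.array(sorted(t)) for t in out]

    def onset_frames(self, n_cells: int, frame_interval: float, n_frames: int | None = None) -> list:
        """Frame index at which each true spike first affects a sample.

        Spikes landing after the last sampled frame are dropped when
        ``n_frames`` is given (they are invisible to the recording).
        """
        out = []
        for t in self.spike_times(n_cells):
            f = np.unique(np.ceil(t / frame_interval).astype(int)) if t.size else np.array([], int)
            if n_frames is not None:
                f = f[f < n_frames]
            out.append(f)
        return out

    def community_rosters(self, min_size: int = 3) -> list:
        return [cells for cells in self.cascades.values() if len(cells) >= min_size]

    def to_json(self, path) -> None:
        data = {
            "spikes": [
                {k: (None if v is None else (int(v) if k in ("cell", "cascade", "parent") else float(v)))
                 for k, v in s.items()}
                for s in self.spikes
            ],
            "hotspot_members": [sorted(int(c) for c in m) for m in self.hotspot_members],
            "cascades": {str(k): sorted(int(c) for c in v) for k, v in self.cascades.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh)


def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, list]:
    w, h = config.field_size
    n = config.n_cells
    pos = np.empty((n, 2))
    i = 0
    for spec in config.hotspots:
        if spec.arrangement == "line" and spec.n_seeded > 0:
            xs = np.linspace(-spec.radius, spec.radius, spec.n_seeded)
            for x in xs:
                pos[i] = (
                    spec.center[0] + x + rng.uniform(-1.5, 1.5),
                    spec.center[1] + rng.uniform(-1.5, 1.5),
                )
                i += 1
        else:
            for _ in range(spec.n_seeded):
                r = spec.radius * math.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * math.pi)
                pos[i] = (spec.center[0] + r * math.cos(theta), spec.center[1] + r * math.sin(theta))
                i += 1
    remaining = n - i
    if config.placement == "uniform":
        pos[i:] = rng.uniform([0, 0], [w, h], size=(remaining, 2))
    elif config.placement == "chain":
        start = i
        for k in range(remaining):
            pos[start + k] = ((k + 0.5) * config.chain_spacing, h / 2.0)
    else:  # clustered (Thomas-like: centers + Gaussian offspring)
        centers = rng.uniform([0, 0], [w, h], size=(config.n_clusters, 2))
        assign = rng.integers(config.n_clusters, size=remaining)
        pos[i:] = np.clip(
            centers[assign] + rng.normal(0, config.offspring_sd, size=(remaining, 2)),
            [0, 0],
            [w, h],
        )
    hotspot_members = []
    for spec in config.hotspots:
        c = np.asarray(spec.center)
        if spec.arrangement == "line":
            dx = np.clip(np.abs(pos[:, 0] - c[0]) - spec.radius, 0, None)
            dy = np.abs(pos[:, 1] - c[1])
            seg_dist = np.sqrt(dx**2 + dy**2)
            inside = np.flatnonzero(seg_dist <= spec.line_margin)
        else:
            inside = np.flatnonzero(np.linalg.norm(pos - c, axis=1) <= spec.radius)
        hotspot_members.append(set(int(k) for k in inside))
    return pos, hotspot_members


def simulate(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth.  Seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    pos, hotspot_members = _place_cells(config, rng)

    rates = np.full(n, config.spike_rate / 60.0)  # per second
    if config.rate_sigma > 0:
        rates *= rng.lognormal(-config.rate_sigma**2 / 2.0, config.rate_sigma, size=n)
    p_out = np.full(n, 0.0 if config.mode == "uncoupled" else config.p_transmit)
    if config.mode == "uncoupled":
        rates *= config.uncoupled_rate_multiplier
    for spec, members in zip(config.hotspots, hotspot_members):
        idx = sorted(members)
        rates[idx] *= spec.rate_multiplier
        p_out[idx] = np.clip(p_out[idx] * spec.p_t_multiplier, 0.0, 1.0)

    # neighbor lists within the coupling radius
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    neighbors = [np.flatnonzero((dist[c] <= config.coupling_radius) & (np.arange(n) != c)) for c in range(n)]

    sources = []
    for c in range(n):
        k = rng.poisson(rates[c] * config.duration)
        for t in np.sort(rng.uniform(0, config.duration, size=k)):
            sources.append((float(t), c))
    sources.sort()

    spikes = []
    cascades: dict[int, set] = {}
    for cid, (t0, c0) in enumerate(sources):
        fired = {c0}
        cascades[cid] = fired
        spikes.append({"cell": c0, "time": t0, "cascade": cid, "parent": None})
        queue = [(t0, c0)]
        while queue:
            t, c = queue.pop(0)
            for nb in neighbors[c]:
                nb = int(nb)
                if nb in fired:
                    continue
                if rng.uniform() >= p_out[c]:
                    continue
                delay = dist[c, nb] / config.speed if config.speed > 0 else 0.0
                if config.delay_jitter > 0:
                    delay *= 1.0 + rng.uniform(-config.delay_jitter, config.delay_jitter)
                t_nb = t + delay
                if t_nb >= config.duration:
                    continue
                fired.add(nb)
                spikes.append({"cell": nb, "time": t_nb, "cascade": cid, "parent": c})
                queue.append((t_nb, nb))

    T = config.n_frames
    frame_times = np.arange(T) * config.frame_interval
    raw = config.baseline_mean + rng.normal(0, config.baseline_sd, size=(n, T))
    # overlapping transients saturate the indicator: kernels combine by max
    signal = np.zeros((n, T))
    for s in spikes:
        dt = frame_times - s["time"]
        mask = dt >= 0
        kern = np.zeros(T)
        on = dt[mask]
        kern[mask] = np.where(
            on <= config.spike_plateau,
            1.0,
            np.exp(-(on - config.spike_plateau) / max(config.decay_tau, 1e-9)),
        )
        np.maximum(signal[s["cell"]], kern, out=signal[s["cell"]])
    raw += config.spike_amplitude * signal

    rec = Recording(
        cell_ids=[f"c{i:03d}" for i in range(n)],
        positions=pos,
        raw=raw,
        frame_interval=config.frame_interval,
        metadata={"condition": config.mode, "recording_id": f"sim{config.seed}"},
    )
    gt = GroundTruth(spikes=spikes, hotspot_members=hotspot_members, cascades=cascades, config=config)
    return rec, gt


def null_recording(config: SimulationConfig) -> Recording:
    """Uncoupled, spatially unstructured recording (p_transmit = 0, no
    hotspot multipliers): homogeneous independent spiking."""
    rec, _ = simulate(config.replace(p_transmit=0.0, hotspots=()))
    return rec


def activity_confounded_recording(config: SimulationConfig) -> tuple[Recording, GroundTruth]:
    """Uncoupled recording where designated subsets spike faster.

    Propagation is off; the configured hotspot regions keep their source
    rate multipliers but lose the coupling boost, so any apparent
    recurrent community is a pure chance/activity artifact.
    """
    specs = tuple(replace(h, p_t_multiplier=1.0) for h in config.hotspots)
    return simulate(config.replace(p_transmit=0.0, hotspots=specs))


# ---------------------------------------------------------------------------
# Named study conditions.  These presets freeze the scenarios used by the
# calibration and recovery suites; see docs/methods.md for the rationale
# behind each parameter choice.

def null_config(seed: int) -> SimulationConfig:
    """~50 cells uniform in 150x150 um, 1 spike/min, 150 frames at 3 s,
    no coupling: the null for shuffle-test calibration."""
    return SimulationConfig(seed=seed, n_cells=50, field_size=(150.0, 150.0),
                            frame_interval=3.0, duration=450.0, spike_rate=1.0,
                            p_transmit=0.0)


def chain_speed_config(seed: int) -> SimulationConfig:
    """Dense chain with certain transmission at 1.6 um/s, for propagation-
    speed recovery.  Adjacent cells are 10 um apart (within the coupling
    radius); second neighbors are beyond it."""
    return SimulationConfig(seed=seed, n_cells=12, field_size=(120.0, 40.0),
                            placement="chain", chain_spacing=10.0,
                            frame_interval=2.5, duration=300.0,
                            spike_rate=0.12, p_transmit=1.0, speed=1.6)


def planted_hotspot_config(seed: int) -> SimulationConfig:
    """One coupling-driven hotspot of 6 seeded cells among 50.

    Inside the disc the transmission probability is boosted to ~0.9 while
    the source rate is reduced, so members recur in communities through
    coupling yet keep activation counts comparable to the background --
    the regime in which the swap bootstrap is informative (matching
    requires non-hotspot cells at least as active as the members)."""
    return SimulationConfig(
        seed=seed, n_cells=50, field_size=(150.0, 150.0), frame_interval=3.0,
        duration=1800.0, spike_rate=0.3, rate_sigma=0.5, p_transmit=0.05,
        hotspots=(HotspotSpec(center=(75.0, 75.0), radius=27.0,
                              rate_multiplier=0.17, p_t_multiplier=18.0, n_seeded=6,
                              arrangement="line"),),
    )


def confounded_hotspot_config(seed: int) -> SimulationConfig:
    """Uncoupled recording with a hyperactive adjacent subset: recurrence
    candidates arise purely from elevated per-cell firing.  Background
    rate heterogeneity supplies activity-matched swap partners."""
    return SimulationConfig(
        seed=seed, n_cells=50, field_size=(150.0, 150.0), frame_interval=3.0,
        duration=1200.0, spike_rate=1.0, rate_sigma=0.6, p_transmit=0.0,
        hotspots=(HotspotSpec(center=(75.0, 75.0), radius=10.0,
                              rate_multiplier=1.3, n_seeded=5),),
    )


def symmetric_coupling_config(seed: int) -> SimulationConfig:
    """Spatially homogeneous coupling with no planted direction bias, for
    the transmission-probability null (~0.5)."""
    return SimulationConfig(seed=seed, n_cells=50, field_size=(150.0, 150.0),
                            frame_interval=3.0, duration=600.0, spike_rate=0.5,
                            p_transmit=0.5)
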