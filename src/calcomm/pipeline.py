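"""End-to-end orchestration over one or many recordings.

``analyze_recording`` runs the full chain (normalize -> binarize ->
events -> shuffle test -> hotspots + validation + interaction profiles)
on one recording; ``run_pipeline`` maps it over a manifest and rolls the
per-condition statistics up into comparison tests.  The frame-interval
filter for pooled propagation-speed statistics (2.32-4 s/frame) is
applied at the roll-up stage only.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity import activation_rate, build_activity, local_density
from .events import adjacency_matrix, detect_events, pooled_speeds, summarize_event
from .hotspots import (
    detect_hotspots,
    interaction_profile,
    participation_counts,
    validate_hotspot,
)
from .spatial_stats import compare_conditions, mec, mec_rate, spatial_shuffle_test
from .traces import AnalysisParameters, Recording, normalize, read_recording

__all__ = ["RecordingResult", "StudyResult", "analyze_recording", "run_pipeline", "report"]

SPEED_POOL_INTERVAL = (2.32, 4.0)  # admissible s/frame for pooled speed stats


@dataclass
class RecordingResult:
    recording_id: str
    condition: str
    stage: str
    frame_interval: float
    n_cells: int
    n_frames: int
    n_events: int
    mec: float
    mec_rate: float
    mean_activation_rate: float
    mean_local_density: float
    shuffle: object  # ShuffleTestResult
    event_summaries: list
    speeds: list  # per-event propagation speeds
    hotspots: list  # list of (Hotspot, HotspotValidation | None, InteractionProfile)


@dataclass
class StudyResult:
    recordings: list
    comparisons: pd.DataFrame
    failures: list = field(default_factory=list)
    params: AnalysisParameters | None = None
    seed: int | None = None


def analyze_recording(
    recording: Recording,
    params: AnalysisParameters | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
    validate_hotspots: bool = True,
    hotspot_max_tries: int = 1000,
) -> RecordingResult:
    """Full single-recording analysis."""
    params = params or AnalysisParameters()
    norm = normalize(recording)
    activity = build_activity(norm, params)
    adj = adjacency_matrix(recording.positions, params.eps)
    events = detect_events(activity, recording.positions, params, recording.frame_interval, adjacency=adj)
    shuffle = spatial_shuffle_test(recording, activity, params, n_permutations=n_permutations, seed=seed)
    counts = participation_counts(events, recording.n_cells)
    candidates = detect_hotspots(counts, recording.positions, eps=params.eps)
    hotspot_rows = []
    for i, hs in enumerate(candidates):
        validation = None
        if validate_hotspots:
            hs_seed = None if seed is None else seed + 7919 * (i + 1)
            validation = validate_hotspot(
                hs, activity, recording.positions, params,
                frame_interval=recording.frame_interval,
                max_tries=hotspot_max_tries, seed=hs_seed,
            )
        profile = interaction_profile(hs, events, recording.positions, eps=params.eps)
        hotspot_rows.append((hs, validation, profile))
    _, mean_rate = activation_rate(activity, recording.frame_interval)
    _, mean_density = local_density(recording.positions, params.density_window)
    return RecordingResult(
        recording_id=str(recording.metadata.get("recording_id", "")),
        condition=str(recording.metadata.get("condition", "")),
        stage=str(recording.metadata.get("stage", "")),
        frame_interval=recording.frame_interval,
        n_cells=recording.n_cells,
        n_frames=recording.n_frames,
        n_events=len(events),
        mec=mec(events, recording.n_cells),
        mec_rate=mec_rate(events, recording.n_cells, recording.duration_s),
        mean_activation_rate=mean_rate,
        mean_local_density=mean_density,
        shuffle=shuffle,
        event_summaries=[summarize_event(e, recording.frame_interval) for e in events],
        speeds=pooled_speeds(events, recording.positions, recording.frame_interval, params.eps),
        hotspots=hotspot_rows,
    )


def run_pipeline(
    manifest,
    params: AnalysisParameters | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
    validate_hotspots: bool = True,
    hotspot_max_tries: int = 1000,
) -> StudyResult:
    """Analyze every recording in a manifest and compare conditions.

    ``manifest`` is a DataFrame-like with columns ``path, condition,
    stage, frame_interval_s`` (optional ``layout``), or a list of
    already-loaded :class:`Recording` objects.  A failing recording is
    flagged and the study continues.
    """
    params = params or AnalysisParameters()
    results, failures = [], []
    entries = manifest
    if isinstance(manifest, pd.DataFrame):
        entries = manifest.to_dict("records")
    for i, entry in enumerate(entries):
        rec_seed = None if seed is None else seed + 104729 * (i + 1)
        try:
            if isinstance(entry, Recording):
                rec = entry
            else:
                rec = read_recording(
                    entry["path"],
                    layout=entry.get("layout", "wide"),
                    frame_interval=float(entry["frame_interval_s"]),
                    metadata={
                        "condition": entry.get("condition", ""),
                        "stage": entry.get("stage", ""),
                        "recording_id": entry.get("recording_id", Path(str(entry["path"])).stem),
                    },
                )
            results.append(
                analyze_recording(
                    rec, params, n_permutations=n_permutations, seed=rec_seed,
                    validate_hotspots=validate_hotspots, hotspot_max_tries=hotspot_max_tries,
                )
            )
        except Exception as exc:  # noqa: BLE001 - recording-level isolation
            label = entry if isinstance(entry, str) else getattr(entry, "metadata", entry)
            failures.append({"entry": str(label), "error": f"{type(exc).__name__}: {exc}"})
            warnings.warn(f"recording {i} failed: {exc}", stacklevel=2)
    if entries and not results:
        raise RuntimeError(f"all {len(failures)} recordings failed")

    sig = {}
    magnitudes: dict = {}
    rates: dict = {}
    speeds: dict = {}
    for r in results:
        c = r.condition or "default"
        s, n = sig.get(c, (0, 0))
        sig[c] = (s + int(r.shuffle.significant), n + 1)
        magnitudes.setdefault(c, []).append(r.shuffle.magnitude)
        rates.setdefault(c, []).append(r.mec_rate)
        if SPEED_POOL_INTERVAL[0] <= r.frame_interval <= SPEED_POOL_INTERVAL[1]:
            speeds.setdefault(c, []).extend(r.speeds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons = compare_conditions(
            significance_by_condition=sig,
            metrics_by_condition={"magnitude": magnitudes, "mec_rate": rates, "speed_um_s": speeds},
            alpha=params.alpha,
        )
    return StudyResult(recordings=results, comparisons=comparisons, failures=failures,
                       params=params, seed=seed)


def report(study: StudyResult, outdir) -> list:
    """Write study tables and a human-readable summary; returns the paths.

    Idempotent: a second call overwrites the same files identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    rec_rows, hs_rows, profile_rows = [], [], []
    for r in study.recordings:
        rec_rows.append(
            {
                "recording_id": r.recording_id, "condition": r.condition, "stage": r.stage,
                "frame_interval_s": r.frame_interval, "n_cells": r.n_cells,
                "n_frames": r.n_frames, "n_events": r.n_events, "mec": r.mec,
                "mec_rate_per_min": r.mec_rate,
                "mean_activation_rate_per_min": r.mean_activation_rate,
                "mean_local_density": r.mean_local_density,
                "observed_mec": r.shuffle.observed_mec, "p_spatial": r.shuffle.p_spatial,
                "magnitude": r.shuffle.magnitude,
                "spatially_significant": r.shuffle.significant,
                "mean_speed_um_s": float(np.mean(r.speeds)) if r.speeds else np.nan,
            }
        )
        for hs, val, prof in r.hotspots:
            hs_rows.append(
                {
                    "recording_id": r.recording_id, "hotspot_id": hs.hotspot_id,
                    "size": hs.size, "members": ";".join(str(c) for c in sorted(hs.members)),
                    "threshold": hs.threshold, "lg_max": hs.lg_max, "hull_area_um2": hs.hull_area,
                    "p_value": val.p_value if val else np.nan,
                    "n_valid_permutations": val.n_valid_permutations if val else 0,
                    "status": val.status if val else "not_validated",
                }
            )
            profile_rows.append(
                {"recording_id": r.recording_id, "hotspot_id": hs.hotspot_id,
                 **dataclasses.asdict(prof)}
            )

    tables = {
        "study_summary.csv": pd.DataFrame(rec_rows),
        "hotspots.csv": pd.DataFrame(hs_rows),
        "interaction_profiles.csv": pd.DataFrame(profile_rows),
        "comparisons.csv": study.comparisons,
    }
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    provenance = {
        "calcomm_version": __version__,
        "seed": study.seed,
        "parameters": dataclasses.asdict(study.params) if study.params else None,
        "n_recordings": len(study.recordings),
        "n_failures": len(study.failures),
        "failures": study.failures,
    }
    prov_path = outdir / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    written.append(prov_path)

    lines = [f"calcomm study report ({len(study.recordings)} recordings)", ""]
    for r in study.recordings:
        sig = "spatially significant" if r.shuffle.significant else "not significant"
        lines.append(
            f"- {r.recording_id or '?'} [{r.condition}]: {r.n_events} events, "
            f"MEC {r.mec:.3f}, magnitude {r.shuffle.magnitude:.2f} ({sig}, p={r.shuffle.p_spatial:.3f}); "
            f"{len(r.hotspots)} hotspot candidate(s)"
        )
        for hs, val, prof in r.hotspots:
            status = val.status if val else "not_validated"
            lines.append(
                f"    hotspot {hs.hotspot_id}: {hs.size} cells, status={status}, "
                f"p_interact={prof.p_interact:.2f}"
            )
    if study.failures:
        lines.append("")
        lines.append(f"failed recordings: {len(study.failures)}")
        for f in study.failures:
            lines.append(f"    {f['entry']}: {f['error']}")
    summary_path = outdir / "summary.txt"
    summary_path.write_text("\n".join(lines) + "\n")
    written.append(summary_path)
    return written
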