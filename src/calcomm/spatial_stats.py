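"""Pairwise correlation-distance statistics and the spatial-shuffle test.

The central statistic is the mean number of collective events per cell
(MEC).  To test whether detected communities reflect local spatial
structure rather than chance co-activation, the cell-to-trace assignment
is permuted uniformly at random (equivalent to randomizing cell
locations), events are re-detected, and the observed MEC is compared to
the permuted distribution.  The magnitude is the ratio of the observed
MEC to the mean permuted MEC; a ratio of 1 means the spatial arrangement
carries no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .activity import ActivityMatrix
from .events import CollectiveEvent, adjacency_matrix, detect_events, neighbor_sets
from .traces import AnalysisParameters, Recording

__all__ = [
    "ShuffleTestResult",
    "pair_correlations",
    "close_far_split",
    "community_relation_correlation",
    "mec",
    "mec_rate",
    "spatial_shuffle_test",
    "compare_conditions",
    "significance_stars",
]


def pair_correlations(values: np.ndarray, positions: np.ndarray) -> pd.DataFrame:
    """Pearson correlation and distance for every unordered cell pair.

    Returns a table with one row per pair: ``cell_i, cell_j, distance, r,
    p, valid``.  Pairs involving a zero-variance trace are flagged
    ``valid=False`` with undefined ``r``.  The two-sided p-value uses the
    standard t approximation on the full-length traces.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n, T = values.shape
    if n < 2 or T < 3:
        raise ValueError("need >= 2 cells and >= 3 frames")
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = squareform(pdist(positions))
    ii, jj = np.triu_indices(n, 1)
    r = corr[ii, jj]
    valid = (sd[ii] > 0) & (sd[jj] > 0)
    r = np.where(valid, r, np.nan)
    r_clip = np.clip(r, -0.9999999, 0.9999999)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r_clip * np.sqrt((T - 2) / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=T - 2)
    p = np.where(valid, p, np.nan)
    return pd.DataFrame(
        {"cell_i": ii, "cell_j": jj, "distance": dist[ii, jj], "r": r, "p": p, "valid": valid}
    )


@dataclass
class CloseFarResult:
    """Close/far partition of the pair table with survival curves."""

    close: pd.DataFrame
    far: pd.DataFrame
    stats: dict  # per group: mean, sd, n
    kruskal_p: float  # NaN if a group is empty
    grid: np.ndarray
    survival: dict  # group -> P(r > x) evaluated on grid


def _survival(vals: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if vals.size == 0:
        return np.full(grid.size, np.nan)
    return (vals[None, :] > grid[:, None]).mean(axis=1)


def close_far_split(pairs: pd.DataFrame, cutoff: float = 14.0) -> CloseFarResult:
    """Split valid pairs into close (distance <= cutoff) and far (> cutoff).

    Exactly-at-cutoff pairs are close (the boundary is assigned to one
    group only).  Survival curves give, per group, the probability of a
    pair correlation exceeding each grid value; groups are compared with
    Kruskal-Wallis (skipped with a warning if a group is empty).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    valid = pairs[pairs["valid"]]
    close = valid[valid["distance"] <= cutoff]
    far = valid[valid["distance"] > cutoff]
    group_stats = {}
    for name, df in (("close", close), ("far", far)):
        group_stats[name] = {
            "mean": float(df["r"].mean()) if len(df) else np.nan,
            "sd": float(df["r"].std(ddof=1)) if len(df) > 1 else np.nan,
            "n": int(len(df)),
        }
    if len(close) and len(far):
        kw = float(stats.kruskal(close["r"], far["r"]).pvalue)
    else:
        warnings.warn("empty close or far group; Kruskal-Wallis skipped", stacklevel=2)
        kw = np.nan
    grid = np.linspace(-1.0, 1.0, 201)
    survival = {
        "close": _survival(close["r"].to_numpy(), grid),
        "far": _survival(far["r"].to_numpy(), grid),
    }
    return CloseFarResult(close=close, far=far, stats=group_stats, kruskal_p=kw, grid=grid, survival=survival)


def community_relation_correlation(
    pairs: pd.DataFrame, events: list[CollectiveEvent]
) -> tuple[pd.DataFrame, dict]:
    """Label pairs intra/inter-community and compare their correlations.

    A pair is ``intra`` if the two cells co-participated in at least one
    event, ``inter`` if both cells participate in events but never the
    same one, and ``none`` otherwise.  Returns the labelled table and a
    comparison dict (means, Kruskal-Wallis p).
    """
    in_any = set()
    for ev in events:
        in_any.update(ev.participants)
    together = set()
    for ev in events:
        members = sorted(ev.participants)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                together.add((a, b))
    labels = []
    for row in pairs.itertuples(index=False):
        a, b = int(row.cell_i), int(row.cell_j)
        if (a, b) in together or (b, a) in together:
            labels.append("intra")
        elif a in in_any and b in in_any:
            labels.append("inter")
        else:
            labels.append("none")
    out = pairs.copy()
    out["relation"] = labels
    intra = out[(out["relation"] == "intra") & out["valid"]]["r"]
    inter = out[(out["relation"] == "inter") & out["valid"]]["r"]
    comparison = {
        "mean_intra": float(intra.mean()) if len(intra) else np.nan,
        "mean_inter": float(inter.mean()) if len(inter) else np.nan,
        "n_intra": int(len(intra)),
        "n_inter": int(len(inter)),
        "kruskal_p": float(stats.kruskal(intra, inter).pvalue)
        if len(intra) and len(inter)
        else np.nan,
    }
    return out, comparison


def mec(events: list[CollectiveEvent], n_cells: int) -> float:
    """Mean events per cell: total distinct-event participations / cells."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    return sum(len(ev.participants) for ev in events) / n_cells


def mec_rate(events: list[CollectiveEvent], n_cells: int, duration_s: float) -> float:
    """MEC per minute of recording."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    return mec(events, n_cells) / (duration_s / 60.0)


@dataclass
class ShuffleTestResult:
    """Outcome of the spatial-shuffle MEC bootstrap."""

    observed_mec: float
    permuted_mecs: np.ndarray
    p_spatial: float
    magnitude: float
    n_permutations: int
    seed: int | None
    alpha: float = 0.05
    n_events: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_spatial <= self.alpha

    @classmethod
    def from_samples(
        cls,
        observed: float,
        permuted,
        seed: int | None = None,
        alpha: float = 0.05,
        n_events: int | None = None,
    ) -> "ShuffleTestResult":
        permuted = np.asarray(permuted, dtype=float)
        if permuted.size < 1:
            raise ValueError("need at least one permutation")
        p = float((permuted >= observed).mean())
        mean_perm = float(permuted.mean())
        if mean_perm > 0:
            magnitude = observed / mean_perm
        elif observed > 0:
            magnitude = np.inf
        else:
            magnitude, p = 1.0, 1.0
        return cls(
            observed_mec=float(observed),
            permuted_mecs=permuted,
            p_spatial=p,
            magnitude=float(magnitude),
            n_permutations=int(permuted.size),
            seed=seed,
            alpha=alpha,
            n_events=n_events,
        )


def spatial_shuffle_test(
    recording: Recording | np.ndarray,
    activity: ActivityMatrix,
    params: AnalysisParameters | None = None,
    n_permutations: int | None = None,
    seed: int | None = None,
) -> ShuffleTestResult:
    """Spatial-shuffle significance and magnitude of the observed MEC.

    Each permutation draws a uniform random permutation of the
    cell-to-trace assignment (positions fixed; fixed points allowed),
    re-detects events and records the MEC.  ``p_spatial`` is the fraction
    of permutations whose MEC is greater than or equal to the observed
    one (ties count as extreme); the magnitude is observed MEC over mean
    permuted MEC.

    ``recording`` may be a full :class:`Recording` or a bare position
    array.  Binarization is per-trace, so permuting binarized rows is
    identical to binarizing permuted traces; the precomputed activity is
    therefore permuted directly.
    """
    params = params or AnalysisParameters()
    n_perm = params.n_permutations if n_permutations is None else int(n_permutations)
    if n_perm < 1:
        raise ValueError("n_permutations must be >= 1")
    positions = recording.positions if isinstance(recording, Recording) else np.asarray(recording, float)
    fi = recording.frame_interval if isinstance(recording, Recording) else 1.0
    active = activity.active
    n = active.shape[0]
    nbrs = neighbor_sets(adjacency_matrix(positions, params.eps))
    observed_events = detect_events(active, positions, params, fi, adjacency=nbrs)
    observed = mec(observed_events, n)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        ev = detect_events(active[perm], positions, params, fi, adjacency=nbrs)
        permuted[k] = mec(ev, n)
    return ShuffleTestResult.from_samples(
        observed, permuted, seed=seed, alpha=params.alpha, n_events=len(observed_events)
    )


def significance_stars(p: float) -> str:
    """Star convention: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return ""
    for thr, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thr:
            return s
    return "ns"


def compare_conditions(
    significance_by_condition: dict | None = None,
    metrics_by_condition: dict | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-condition tests over per-recording results.

    ``significance_by_condition`` maps condition -> (n_significant,
    n_total) and is compared pairwise with Fisher's exact test (suited to
    the small per-condition sample sizes).  ``metrics_by_condition`` maps
    metric name -> {condition: list of values}; each metric is compared
    across conditions with Kruskal-Wallis.  Degenerate inputs (fewer than
    two conditions, empty groups) are skipped with a warning.
    """
    rows = []
    if significance_by_condition:
        conds = sorted(significance_by_condition)
        if len(conds) < 2:
            warnings.warn("need >= 2 conditions for Fisher comparisons", stacklevel=2)
        for i, a in enumerate(conds):
            for b in conds[i + 1 :]:
                sa, na = significance_by_condition[a]
                sb, nb = significance_by_condition[b]
                if na == 0 or nb == 0:
                    warnings.warn(f"empty condition in Fisher test {a} vs {b}", stacklevel=2)
                    continue
                table = [[sa, na - sa], [sb, nb - sb]]
                p = float(stats.fisher_exact(table).pvalue)
                rows.append(
                    {
                        "test": "fisher_significant_fraction",
                        "metric": "spatially_significant",
                        "conditions": f"{a} vs {b}",
                        "statistic": np.nan,
                        "p": p,
                        "stars": significance_stars(p),
                    }
                )
    if metrics_by_condition:
        for metric, groups in metrics_by_condition.items():
            usable = {c: np.asarray(v, float) for c, v in groups.items() if len(v) > 0}
            if len(usable) < 2:
                warnings.warn(f"metric {metric!r}: need >= 2 nonempty conditions", stacklevel=2)
                continue
            try:
                kw = stats.kruskal(*usable.values())
            except ValueError as exc:  # e.g. all values identical
                warnings.warn(f"metric {metric!r}: Kruskal-Wallis skipped ({exc})", stacklevel=2)
                continue
            p = float(kw.pvalue)
            rows.append(
                {
                    "test": "kruskal_wallis",
                    "metric": metric,
                    "conditions": " vs ".join(sorted(usable)),
                    "statistic": float(kw.statistic),
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows, columns=["test", "metric", "conditions", "statistic", "p", "stars"])
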