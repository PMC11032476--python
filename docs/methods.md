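# Methods

## Scope and model

`calcomm` analyzes recordings of dozens of cells with static 2-D
centroids (µm) and one fluorescence trace per cell sampled at a fixed
frame interval (the regimes targeted are 2.3–6.7 s/frame, fields of
~100–200 µm). The working model is that intracellular Ca²⁺ transients
appear as step-like rises with a decay of several seconds, that
transients propagate between cells only over short distances (on the
order of two cell diameters) with a finite speed, and that collective
behavior therefore manifests as spatiotemporally contiguous groups of
activations. Coordinates are treated as constant over a recording
(no drift correction) and distances are 2-D Euclidean; the axial
dimension of the tissue is ignored.

## Pipeline and parameters

All thresholds live in `AnalysisParameters`; the defaults are the
values of the published imaging protocol this pipeline targets and are
used throughout the test suites.

| parameter | default | unit | role |
|---|---|---|---|
| `eps` | 14 | µm | neighbor threshold for clustering, linking, hotspot components, speed pairs (~two cell diameters) |
| `min_total_event_size` | 3 | cells | smallest reported community |
| `min_cluster_size` | 1 | cells | per-frame cluster floor (1 allows single-cell growth steps) |
| `max_lag` | 15 | s | activation lag still linking into one event; converted to frames as `ceil(max_lag/frame_interval)` |
| `min_duration` | 1 | frames | shortest event lifetime |
| `smooth_k`, `bias_k` | 3, 25 | frames | short median smoothing / long median baseline |
| `peak_thr`, `bin_thr` | 0.3, 0.4 | — | run-peak and frame thresholds on the rescaled residual |
| `close_far_cutoff` | 14 | µm | close/far pair split (boundary pairs are close) |
| `density_window` | 14 | µm | side of the axis-aligned density square |
| `n_permutations` | 1000 | — | spatial-shuffle repetitions |
| `alpha` | 0.05 | — | significance level everywhere |

Detrending is defined as: running median (window `smooth_k`) → running
median baseline (window `bias_k`) subtracted → negatives clipped →
rescaled by the per-cell maximum (zero-max rows stay zero). Median
windows must be odd; even inputs are incremented and windows longer
than the trace are truncated, both with warnings. Running medians use
nearest-value edge padding. This fixed, testable definition is this
package's dialect of median-based detrending; it is validated against
simulated ground truth (onset recall and precision ≥ 0.9 at
signal-to-noise ratio 5), not against any external implementation.

Event detection is incremental: per frame, active cells are clustered
by single linkage at `eps`; a cluster links to a live event when any of
its cells is within `eps` of a member that was active in the previous
lag window; a cluster linking several events merges them (union,
smallest id kept); events close after a full lag window of silence.
An equivalent characterization — connected components of the graph on
(cell, active-run) nodes with edges for pairs within `eps` whose runs
are within the lag of each other — is implemented independently as a
brute-force oracle (`brute_force_events`, ≤12 cells) and the two are
asserted equal on hundreds of random instances.

Conventions worth noting:

- A cell's activation time inside an event is its **first** active
  frame there; re-activations do not create new speed pairs.
- Simultaneous activations (Δt = 0) are excluded from speed means; an
  event with no sequential adjacent pair has speed 0, so fully
  synchronous events count as zero-speed rather than being dropped.
- The permutation p-value counts ties as extreme (`≥`).
- In the close/far split, pairs exactly at the cutoff are *close*
  (the printed convention double-counts the boundary; one side had to
  be chosen).
- Hotspot thresholds are real-valued (`max(5, LG_max/2)`, no
  rounding); candidate components need ≥3 members (a 1–2 cell
  component is not a community).
- In the swap bootstrap, the matching order is re-randomized per
  permutation and duplicate matching maps are kept but logged; the
  hotspot MEC of a permutation is computed over the member *positions*
  of the original candidate.
- Pearson p-values use the standard t approximation on full-length
  traces with no autocorrelation correction, and the pair table is not
  multiplicity-corrected — both deliberate, documented limitations
  matching common practice for these exploratory scatter analyses.
- Pair correlations are computed on normalized traces; Pearson r is
  invariant to the per-cell affine normalization, so this choice is
  consequence-free.
- Constant traces normalize to zero, never spike, but stay in the
  roster: they count for density, shuffling and hotspot geometry.

## Synthetic data

The generator (`calcomm.synthetic`) emulates the statistical structure
the analysis assumes, not the biophysics: cells are placed uniformly,
in Thomas-process clusters, or on a chain; source spikes are per-cell
Poisson processes (optionally with mean-preserving lognormal rate
heterogeneity across cells); each spike transmits independently to
every neighbor within the coupling radius with probability
`p_transmit`, after a delay `distance/speed` jittered by ±20 %, with a
no-reactivation guard per cascade. Hotspot regions (disc- or
chain-shaped) multiply the source rate and the outgoing transmission
probability of the cells inside them. Fluorescence is a noisy baseline
plus, per spike, a kernel with instant rise, a ~5 s near-peak plateau
and an exponential decay (τ = 4 s); overlapping kernels combine by
maximum, mimicking indicator saturation. The plateau length reflects
that Ca²⁺ transients in this setting outlast single frames at 2.3–6.7
s sampling — a sub-frame transient would be undetectable by any
binarization and is inconsistent with cells remaining active across
several frames; the default amplitude/noise (20 vs 2.5) corresponds to
a clearly resolvable indicator (SNR 8), and the detection-quality tests
deliberately lower this to SNR 5.

What the generator does **not** emulate: photobleaching and slow drift
(the baseline is stationary, so the detrending stage is exercised only
mildly), movement artifacts, indicator kinetics (rise time is
instantaneous), refractoriness across cascades, 3-D geometry and
anisotropic coupling. Passing tests therefore show that the statistics
are computed correctly and are well calibrated under the stated
assumptions — not that those assumptions hold for any particular
microscope or tissue.

### Named study conditions

- `null_config` — 50 cells uniform in 150×150 µm, 1 spike/min, 150
  frames at 3 s, no coupling. Used to calibrate the shuffle test: over
  200 such recordings the declared-significant fraction stays within
  0.05 + 2 binomial SE and the mean magnitude is within 0.05 of 1.
- `chain_speed_config` — 12 cells spaced 10 µm on a chain (adjacent
  pairs within `eps`, second neighbors beyond it), certain
  transmission, planted speed 1.6 µm/s, 2.5 s frames. The pooled
  per-event speed estimator recovers the planted speed within 15 %;
  the residual upward bias (~5–8 %) comes from frame quantization of
  activation times and occasional colliding cascades.
- `planted_hotspot_config` — one chain-arranged hotspot of 6 seeded
  cells (~10.8 µm apart) among 50, 30-min recordings, quiet
  heterogeneous background (0.3 spikes/min, lognormal σ = 0.5), with
  transmission boosted to 0.9 inside the hotspot and the members'
  source rate *reduced* (×0.17). Two constraints shape this preset:
  the swap bootstrap needs non-member cells at least as active as the
  members (so member activation counts must stay within the background
  distribution), and the chance co-activation rate at the hotspot
  positions — which sets the bootstrap's null MEC — grows steeply with
  local density and activity (a dense seeded disc is itself a density
  hotspot and drowns the signal). A background-density chain driven by
  coupling rather than firing rate satisfies both; recovery (Jaccard ≥
  0.5 against the planted membership) and validation power ≥ 0.8 are
  asserted over a fixed 20-simulation batch.
- `confounded_hotspot_config` — no coupling at all; a dense 5-cell
  subset fires ×1.3 faster against a heavy-tailed background
  (σ = 0.6). Candidates arise from density and activity alone; because
  matched swap partners must have ≥ as many activations, the permuted
  recordings are stochastically at least as active and the bootstrap
  stays conservative: the falsely-validated fraction is asserted ≤
  0.05 + 2 binomial SE.
- `symmetric_coupling_config` — homogeneous coupling, no planted
  direction; the transmission probability of an arbitrary cell subset
  pools to ≈ 0.5.

## Numerical and engineering choices

- Detection runs in a few milliseconds per 50 × 150 recording
  (precomputed neighbor sets, pure-Python frame loop), which is what
  makes 200-recording × 200-permutation calibrations desk-scale.
- Binarization is strictly per-trace, so the shuffle test permutes the
  rows of the precomputed binary activity instead of re-binarizing
  permuted traces; a dedicated test asserts the two routes are
  identical.
- Convex hulls use Qhull; degenerate (collinear) hotspot geometry
  yields a `None` hull with zero area rather than an error.
- CSV round trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read).
- All stochastic components (generator, shuffle test, swap bootstrap)
  take explicit integer seeds; identical seeds reproduce results
  bit-identically.
- The transform/cluster-shaped stages also expose scikit-learn-style
  estimator facades (`TraceNormalizer`, `SpikeBinarizer`,
  `CollectiveEventDetector`, `HotspotDetector`) with
  `get_params`/`set_params` and trailing-underscore fitted attributes;
  the permutation tests and the simulator are plain functions, as they
  are not fit/transform shaped.

## Worked-example snippet

The README's printed numbers come from:

```python
import numpy as np
import calcomm as cc
from calcomm.synthetic import SimulationConfig, simulate

cfg = SimulationConfig(seed=42, n_cells=50, duration=600.0, frame_interval=3.0,
                       spike_rate=0.5, p_transmit=0.6)
rec, gt = simulate(cfg)
result = cc.analyze_recording(rec, n_permutations=200, seed=0, validate_hotspots=False)
print(f"cells: {rec.n_cells}, frames: {rec.n_frames} ({rec.duration_min:.1f} min at {rec.frame_interval} s/frame)")
print(f"collective events detected: {result.n_events}")
sizes = [s.size for s in result.event_summaries]
print(f"event sizes: min {min(sizes)}, median {int(np.median(sizes))}, max {max(sizes)}")
print(f"MEC (mean events per cell): {result.mec:.3f}")
print(f"spatial-shuffle test: p = {result.shuffle.p_spatial:.3f}, magnitude = {result.shuffle.magnitude:.2f}")
print(f"mean activation rate: {result.mean_activation_rate:.2f} /min; mean local density: {result.mean_local_density:.2f} cells")
sp = [s for s in result.speeds if s > 0]
print(f"mean propagation speed over {len(sp)} events with sequential pairs: {np.mean(sp):.2f} um/s")
```

## Known limitations

- The event linker's generous lag window (±15 s) chains chance
  activations in dense, highly active regions; at high activity the
  event count saturates and all recurrence statistics compress. The
  calibration suites operate below that regime; users analyzing very
  active tissue should examine the permuted MEC distributions, not
  just p-values.
- Hotspot validation inherits a mild winner's-curse from candidate
  selection (members are chosen for high observed counts); the
  ≥-activation matching counteracts it but only when the eligible pool
  is comfortably more active than the members.
- `min_cluster_size > 1` is supported by the detector but the
  brute-force oracle (and hence the equivalence guarantee) covers only
  the default of 1.
- Speed estimates are quantized by the frame interval; pooled speed
  statistics should be restricted to comparable frame intervals
  (the pipeline applies the 2.32–4 s window for pooled statistics).
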