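# Methods

This document describes the generative model behind the synthetic data, the
analysis algorithms, the numerical conventions, and the known limitations.
All defaults listed here are the values used by `PipelineConfig` and by the
module-level function signatures.

## 1. Synthetic data model (`synthgen`)

The generator produces data with the statistical structure of extracellular
recordings made from a honey bee carried on a quadcopter flying a repeated
route over a field. It is the reference against which every analysis stage
is validated; its defaults are the study conditions and are not adjusted to
make analyses succeed.

### 1.1 Flight telemetry

`gen_trefoil_telemetry` builds a constant-speed trefoil (three-lobed
cloverleaf) flight at 5.5 m/s and 15 m altitude, sampled at 100 Hz. One
repetition starts at a corner pose, flies straight across the feeder
position and `leg_beyond_m` past it, then turns right back over the feeder
from a bearing rotated 120° clockwise — three lobes in total — and returns
to the start pose. Consecutive lobes are joined with exact right-turn /
straight / right-turn (Dubins RSR) connections at `turn_radius_m` (default
15 m), so each repetition is a closed loop retraced identically by the
next. Yaw is the path heading; yaw rate is its finite-difference
derivative. The function returns the telemetry track plus the exact
`[start, end)` repetition bounds.

### 1.2 Spike trains

`gen_spike_trains` draws each unit as an inhomogeneous Poisson process with

```
lambda(t) = baseline_rate_hz + rate_gain * |yaw_rate(t - lag_s)|
```

(defaults 5 Hz, 80 Hz per rad/s, 0.7 s), sampled by thinning against the
global rate maximum on a 5e-5 s time grid, independently per unit
(`default_rng([seed, unit])`). A dead time of `refractory_s +
refractory_margin_s` (4 ms + 1 ms) is enforced by forward deletion. The
1 ms margin is deliberate: a pure dead-time process piles interspike
intervals directly at the floor, whereas well-isolated units show near-zero
density just above their absolute refractory period; the margin reproduces
that gap so that downstream jitter (±1 detection sample, template-matching
dedup at ±2 ms) cannot push sorted intervals under 4 ms.

### 1.3 Spike waveforms

Templates (`make_template`) are sums of Gaussian lobes over a 29-sample
(1.45 ms at 20 kHz) window: a negative trough of depth −1 at the center,
a repolarization overshoot after it, and for triphasic shapes a positive
deflection before it. Lobe positions and widths are expressed in units of
the trough width so the shapes scale consistently. Two constraints on the
default set are load-bearing:

- **Trough width is capped near 3 samples (σ).** With the 4×noise
  threshold, wider troughs have shoulders deep enough that additive noise
  creates a secondary local minimum ≥ 0.35 ms from the true trough — the
  detector's minimum peak separation — producing double detections and
  refractory violations in the sorted units.
- **Pairwise template cosine similarity is kept ≤ ~0.5.** The flight-
  dependent amplitude envelope stretches each unit's feature cloud along
  its template direction; templates that point in similar directions
  produce elongated, bridged clusters that density clustering merges.

Each template is tapered by a raised-cosine ramp over the outer quarter of
its window so the waveform returns to baseline smoothly (no step when
injected), then renormalized to trough depth −1.

### 1.4 Recording synthesis

`gen_recording` writes a two-channel, 16-bit, 20 kHz recording:

```
channel_a = 2.0 * common(t) + 0.5 * spikes(t) + independent_a(t)
channel_b = 1.0 * common(t) - 0.5 * spikes(t) + independent_b(t)
```

- **Common mode**: motor-harmonic tones at 600/1200/2400 Hz (amplitudes
  10/8/7 model units) with random phases, scaled over time by an
  acceleration-derived envelope (copter maneuvers are noisier), plus
  Poisson-timed 2 ms decaying broadband bursts at 0.2 Hz.
- **Spikes**: each spike adds `12 × template` (times an optional
  time-dependent attenuation callable), split with opposite polarity
  across the channels, so the gain-matched differential cancels the common
  mode and reassembles the full waveform.
- **Independent noise**: unit-SD Gaussian per channel, FFT-band-limited to
  300 Hz – 10 kHz (the recording hardware's passband), variance-preserving.

Output is quantized at 250 counts per model unit; clipping above 1% of
samples is logged.

### 1.5 Terrain

`gen_terrain` makes a height grid (Gaussian-filtered noise, default 2 m
relief smoothed over 10 m, or flat) with a polygonal field mask. The grid
origin is the southwest corner; row 0 is the north edge.

## 2. Preprocessing (`preprocess`)

- `mad` is the raw median absolute deviation; robust noise is
  `1.4826 × MAD` where 1.4826 = 1/Φ⁻¹(0.75) makes it unbiased for the SD
  of Gaussian noise.
- `estimate_subtraction_gain` grid-searches g over [0, 4] in 0.01 steps to
  minimize the robust noise of `a − g·b`, evaluated on an evenly strided
  subsample above 400k samples, then refines between the grid neighbors
  with bounded scalar minimization. Ties break to the smallest gain, and
  the refinement is accepted only on strict improvement (a flat objective,
  e.g. a dead reference channel, keeps the grid optimum).
- `local_robust_normalize` renormalizes in 1 s windows hopped every 50 ms
  (interpolating the scale between window centers) to flatten the
  flight-dependent noise envelope.
- `clean_recording` chains per-channel robust normalization, gain
  estimation, the differential, and local renormalization.

## 3. Detection (`detection`)

`detect_spikes` finds negative troughs below `−4 × robust noise` with a
minimum separation of 0.35 ms (7 samples at 20 kHz; the deeper trough wins
within that window). `extract_waveforms` cuts 29-sample windows with the
trough at index 14 (events too close to the signal edge are dropped).

`template_matching_detect` slides a Pearson correlation of the unit's
median template over the signal, detects correlation peaks above
`4 × robust noise` of the correlation trace, and discards candidates within
2 ms of an already-known event — so the merged event set is a strict
superset of the threshold detections. This recovers spikes during episodes
of attenuated amplitude that the fixed threshold misses.

Ground-truth matching (`match_events`) is greedy one-to-one within ±1 ms,
nearest pairs first; F1 is computed from that matching.

## 4. Sorting (`sorting`)

1. **Features**: full-depth Haar wavelet decomposition (periodization mode)
   of each waveform, edge-padded from 29 to 32 samples (1 left, 2 right);
   the transform is orthogonal (Parseval holds against the padded
   waveform).
2. **Reduction**: PCA keeping every component explaining ≥ 1% of variance.
3. **Outliers**: Local Outlier Factor (20 neighbors) flags points excluded
   from clustering.
4. **Clustering**: HDBSCAN with `min_cluster_size = 100`; smaller density
   modes are noise (label −1). Because excess-of-mass cluster selection
   never reports the hierarchy root, a recording dominated by a single
   unit would come back empty; when the first pass finds no cluster the
   clustering is retried allowing a single cluster. Labels are renumbered
   by first occurrence, so for time-sorted spikes unit 0 fired first.
5. **Units**: per-cluster median template, spike times, and interspike-
   interval statistics (`fraction_isi_below_4ms` is the physiological
   plausibility check: a well-isolated unit has none).

Sorting quality is reported as the adjusted Rand index computed over the
events that are both matched to a ground-truth spike (±1 ms) and assigned
to a cluster (label ≥ 0); unmatched detections have no defined true label
and noise-labeled events have no predicted one.

## 5. Rate analysis (`rateanalysis`)

- `bin_rates`: fixed 100 ms bins (right-open; counts conserved), rates in
  Hz. `smooth_rates`: centered boxcar over 3 s.
- `bin_yaw_speed`: mean |yaw rate| (or signed) per bin from telemetry.
- `lagged_crosscorr`: Pearson correlation of the rate series against the
  behavioral series shifted by 0..max_lag bins; the peak lag estimates the
  behavior-to-spike latency at bin resolution.
- `segment_repetitions`: a repetition starts when the track enters a disc
  around the route start while heading within 0.01 rad of the initial
  bearing; intervals end at the next entry. A crossing at the very end of
  the flight is the closing pass of the last repetition, not a new one
  (minimum-duration guard).
- `sliding_autocorrelation`: Pearson correlation of the first repetition's
  rate profile against the full series at every bin offset; peaks at the
  other repetitions' start offsets indicate route-locked activity.

## 6. Visual-field projection (`beeview`)

- `build_eye_model`: deterministic quasi-uniform ommatidial directions
  (golden-angle azimuth folded into a 300° horizontal field of view —
  a 60° rear blind wedge — elevation uniform in sin over a 160° vertical
  span); default 5000 ommatidia.
- `raycast`: rays are rotated by yaw (ENU, counterclockwise positive) and
  marched in half-cell steps until a sample falls at or below the terrain;
  the crossing is then refined by solving the ray-surface intersection
  exactly within the last step, clamped to that step. `RayHit` carries both
  the hit cell (row/col, hit class field / outside / none) and the refined
  metric intersection (`x_m`, `y_m`, NaN on no hit). On flat terrain the
  refined intersection is exact to rounding, and rotating the pose rotates
  the hit pattern to numerical precision.
- `project_rates`: for each rate bin (optionally excluding bins with
  |yaw rate| above 0.3 rad/s), the pose at the bin center is raycast and
  each unique field pixel in view accumulates the bin's rate; the output
  maps per-pixel mean rate and visit counts.
- Terrain I/O uses the 6-line ESRI ASCII grid header (values written with
  6 significant digits) with the field mask in a JSON sidecar.

## 7. Pipeline and provenance (`session`, `cli`)

Recordings are two-channel 16-bit WAV; telemetry is CSV at 100 Hz with
strictly increasing timestamps. `session.align` interpolates telemetry to
arbitrary recording times (yaw via shortest-arc interpolation) and rejects
non-overlapping clocks. `PipelineConfig` holds every parameter (JSON
round-trip, unknown keys rejected); a 12-hex-digit SHA-256 hash of the
config is stamped into every output file for provenance. The CLI exposes
each stage on files (`simulate`, `preprocess`, `detect`, `sort`, `rates`,
`correlate`, `map`) and `run-all` for the full chain.

## 8. Problem sizes and runtime

Default study condition: a 1-repetition trefoil (~122 s flight, 2.4 M
samples per channel) generates in ~3 s, preprocesses in ~7 s, detects in
~0.1 s and sorts in ~1 s on one CPU. The full test suite runs in ~5 min;
`scripts/acceptance.py` in ~4 min. Memory stays well under 1 GiB.

## 9. Scope and limitations

- The generator covers the statistical structure relevant to validating
  this pipeline — common-mode artifacts, flight-dependent noise and
  amplitude envelopes, rate-behavior coupling, repeated trajectories — not
  a biophysical simulation of neurons or of copter aerodynamics.
- Spike waveforms are stationary per unit (no bursting-related amplitude
  decrement) and overlapping spikes from different units superimpose
  linearly; the sorter does not resolve near-coincident overlaps.
- The rate-behavior link is a single-lag, rectified-yaw-rate linear gain;
  real responses are likely nonlinear and multivariate.
- The trefoil is flown at exactly constant speed with exact arcs; wind,
  altitude variation and GPS noise are not modeled.
- The eye model is geometric only (no optics, spatial acuity or
  photoreceptor dynamics), and the terrain has no vertical structures, so
  ray occlusion is purely topographic.
- Telemetry and recording clocks are assumed synchronized; no clock-drift
  estimation is performed.
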