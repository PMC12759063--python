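# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `ivtk`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute themselves.

## Tracks and units

A track is a time-ordered sequence of one cell's centroids in µm and
seconds, 2D or 3D (z present for all points or none), with strictly
increasing timestamps. All loaders convert to these units on entry
(TrackMate `FRAME` columns require an explicit frame interval; JSON track
records must declare `time_units` and are refused when ambiguous, since a
frame index misread as seconds silently rescales every speed). Durations
are always computed from timestamps, never point counts, so irregular
sampling is handled correctly.

Resampling interpolates each axis linearly onto a grid anchored at the
first timestamp (default Δt = 10 s) and never extrapolates. Fragmenting
into fixed-duration windows (default 500 s) assigns each point to the
half-open window `[k·w, (k+1)·w)` after the track start and discards the
trailing remainder; the fragments therefore partition the retained points,
at the cost that a uniformly sampled fragment's last sample lies one Δt
before the window edge. Tracklets are fixed-step sub-tracks (default 20
steps, stride = steps − overlap with overlap ≤ 15) used to equalize track
length before metric comparison.

## Motility metrics

Speed is path length over duration (µm/min); directionality is net
displacement over path length; both are invariant under rigid motions.
The arrest coefficient is the duration-weighted fraction of inter-point
intervals whose instantaneous speed falls strictly below a threshold.
The threshold defaults to 2 µm/min — a common choice for T cells, whose
arrested phases sit well below it and motile phases well above — and is
exposed in the configuration and recorded in outputs, because the arrest
coefficient is meaningless without it. For equal-duration steps the
weighting reduces to the plain fraction of arrested steps; the weighted
form keeps irregularly sampled tracks honest.

MSD and velocity autocovariance require uniform sampling (resample
first); both average over overlapping pairs. Turning angles skip
zero-length steps, whose direction is undefined, rather than counting
them as 0°.

Mixing 2D and 3D tracks in one comparison table is refused: a 2D
projection shortens paths, so pooled statistics would be biased. Each
record carries its dimensionality.

### Residual speeds

Pooling track speeds across videos confounds population differences with
video-level effects (tissue site, depth, temperature, acquisition).
When every video contains a shared reference population, subtracting the
per-video mean reference speed from every track in that video removes the
video offset; the residuals can then be pooled across videos. A video
without reference tracks is an error naming the video — silently dropping
it would bias the pooled comparison.

### Sampling-rate bias

Measured speed decreases with the frame interval Δt deterministically:
subsampling replaces two steps by their chord, and the triangle
inequality makes the path — hence the speed — non-increasing in the
subsampling factor. The bias is summarized by fitting
`speed = a·exp(b·Δt)` with nonlinear least squares (scipy `curve_fit`),
initialized from the log-linear fit. Solving the nonlinear problem
directly, rather than regressing log-speed, avoids the log-transform's
bias and tolerates near-zero speeds; the initialization floors speeds at
1e−12 to keep the seed finite.

## Motility-pattern profiling

Tracks shorter than 500 s are dropped (too little signal for windowed
features), the rest resampled to 10 s. Each sliding window comprises
five samples (50 s) and slides by one, so a track with S samples yields
S − 4 windows. Window features: directionality, square displacement
|p_end − p_start|², mean speed, and an arrest feature 1/(MSD_w + ε) with
MSD_w the mean squared displacement from the window start. The inverse-MSD
form avoids the discretization a thresholded arrest coefficient suffers
on five-sample windows; ε (default 1e−3 µm²) caps the feature at 1/ε for
perfectly still windows and is configurable.

Features are z-scored over the windows of **all** tracks pooled, not per
track: per-track normalization would erase the level differences that
distinguish, say, arrested from directed cells, and degenerates for
constant features. A zero-variance feature maps to 0. The stored
(mean, SD) can be applied to held-out tracks.

Track similarity is dependent multivariate DTW: one warping path aligns
the two 4-vector series, with Euclidean local cost and no band
constraint, so tracks of different durations compare naturally. The DP
recursion is numba-compiled; the test suite checks it exactly against a
brute-force path-enumeration oracle on short series. DTW here is a
dissimilarity, not a metric (no triangle inequality) — downstream steps
only need the dissimilarity.

The N×N distance matrix is embedded with UMAP (`metric="precomputed"`,
2 components, 5 neighbors, `min_dist` 0.1, fixed `random_state`, which
also forces single-threaded, reproducible execution). Clustering runs on
the embedded points after per-axis min-max normalization to [0, 1]:

- local density ρ_i = Σ_j exp(−(d_ij/d_c)²), with d_c the 2nd percentile
  of pairwise distances (a standard density-peak heuristic; configurable);
- δ_i = distance to the nearest point of higher density (ties broken to
  the lower index; the global density maximum takes the largest pairwise
  distance);
- the k highest γ = ρ·δ points become centers (ties by γ then index);
- every point is assigned to the center of cheapest shortest-path cost
  over the graph whose edges connect pairs at distance ≤ 0.1 in the
  normalized coordinates (edge weight = distance; Dijkstra via
  scipy.sparse.csgraph). The 0.1 pruning threshold is interpreted in
  normalized coordinates to make it scale-free, and is configurable.
  Points unreachable from every center fall back to the nearest center by
  direct distance (the pruning exists for speed, not to define outliers);
  a "noise" labeling mode is available instead.

k is a caller decision; the ρ, δ, γ decision-graph values are always
returned/exported so users can pick k from the decision graph. The CLI
default is 10; the archetype-recovery tests use k = 4 because four
archetypes are planted. Cluster profiles are per-cluster metric means,
min-max normalized across clusters; with k = 1 the normalization is
degenerate and all values are reported as 0.5.

## Imaging and quality

Quality indices are computed on the 8-bit-normalized
maximum-intensity-projection movie of one channel — the rendering a
viewer sees, and the only domain where the uint8 saturation band
(245–255) is defined. Rendering normalization maps [min, q] linearly to
[0, 255], q the (1 − 0.01) quantile of the whole movie, values above q
clipping to 255; a constant movie maps to zeros.

- **CR** (contrast): |Var(ref) − Var(movie)| / Var(ref), where ref
  stretches the movie's 1st–99th percentiles to full range (consistent
  with the 1 % rendering rule; percentiles configurable). 0 = the movie
  already fills its range.
- **NR** (noise): PSNR in dB between the movie and its per-frame 3×3
  median-filtered copy (reflection at edges; the smallest standard
  denoising kernel, configurable). MSE = 0 reports +∞.
- **PB** (photobleaching): OLS slope of per-frame mean intensity vs
  frame index.
- **SAT**: fraction of pixels in [245, 255].
- **SV** (signal variation): coefficient of variation of per-frame mean
  intensities (population SD / mean). The per-frame-mean CV reading is a
  documented choice: it is scale-free and captures "variation over
  time", whereas a pooled per-pixel SD would mostly measure spatial
  contrast.

Goodness mappings (each onto [0, 1], 1 = no artifact):
CR_good = 1 − min(CR, 1); NR_good = min(PSNR/50 dB, 1) with ∞ → 1;
PB_good = 1 − min(max(0, −slope)·(F−1)/µ₀, 1), i.e. the fractional
intensity loss over the movie relative to the first-frame mean µ₀;
SAT_good = 1 − SAT; SV_good = 1 − min(CV, 1). The composite is their
weighted mean, unweighted by default; weights are configuration. The
mappings and weights are design choices — the raw indices are always
reported alongside so users can re-weight.

### Z-recovery

A maximum-intensity projection stores, per (x, y), the value of the
brightest z-plane. For each 2D track point, the estimator looks up the
frame from the timestamp (which must land on a frame within 1e−6
tolerance), converts (x, y) to the nearest pixel (half-up rounding,
0-based), and takes argmax over z of the intensity there — equivalent to
matching the projection value, but immune to float-equality pitfalls.
Ties resolve to the lowest z index, deterministically. Validation is the
coefficient of determination R² of estimated vs true z; above 0.8 is the
conventional accuracy bar. The estimator is exact on noiseless
single-blob stacks at every depth (swept in the tests).

## Synthetic generators

**Tracks.** Discrete-time steps at Δt (default 10 s) with step length
speed·Δt/60 while moving. Directed walkers perturb their unit heading by
Gaussian noise of SD (1 − persistence)·π radians per step (small-angle
directional diffusion, identical in 2D and 3D); Brownian walkers draw a
fresh uniform direction per step, so MSD(kΔt) = k·L² and D = L²/(4Δt) in
2D — the property the MSD tests exploit. Arrested cells are a stationary
AR(1) jiggle with stationary positional SD `jitter_sd` (default 0.2 µm)
and lag-one correlation 0.9: the positional spread matches the nominal
jitter while consecutive centroids stay close, as for a real arrested
cell (i.i.d. positional jitter would put mean step speeds above the
2 µm/min arrest threshold at these defaults, which no arrested cell
should exceed). Run-and-pause walkers switch between the directed and
arrested processes as a two-state Markov chain (default rates 0.01 s⁻¹
each, i.e. ~100-s phases). Defaults per archetype: directed 10 µm/min at
persistence 0.97; brownian 8 µm/min; run-and-pause 10 µm/min at
persistence 0.95 — speeds in the range reported for motile leukocytes,
with 600-s tracks. Everything is a pure function of spec + seed.

**Movies.** Frames are background + 3D Gaussian blobs (σ 1.5 µm default)
centered on the tracks' true positions, scaled by (1 − bleach_rate)^f,
translated by a uniform drift per frame, clipped at the detector full
scale (default 255), plus additive Gaussian noise, clipped to the
detector range. Saturation is modeled as detector clipping because a
pure amplitude scaling is invariant under the quantile-based rendering
normalization and would never saturate the rendered movie. Drifted
content may leave the field of view — that is precisely how tissue drift
degrades a recording — while the track coordinates themselves must lie
inside the field. Ground truth (z indices, bleach series) is returned
alongside.

The z-recovery benchmark movie holds one blob (σ 1.2 µm) wandering
smoothly in x, y and across whole z-slices, in a 20×15×48×48 stack with
noise SD = amplitude/SNR, SNR 5 by default — enough noise to stress the
argmax estimator without breaking it. The true z lives on slice centers
because depth annotations are per-slice; this also makes the noiseless
limit exactly R² = 1.

What the generators do **not** emulate: cell shape and contact (blobs are
isotropic Gaussians of constant size), local tissue deformation (drift is
a rigid translation), autofluorescence and second-harmonic structures,
detection/linking errors of real trackers, and heterogeneity within an
archetype beyond its seeded randomness. Passing tests therefore
demonstrate correctness of the computations and recoverability under the
stated models, not performance on any particular biological dataset.

## Problem sizes and determinism

The test suite and acceptance script are sized for a single CPU: 20
movies of 20×15×48×48 voxels for depth recovery, 120-track cohorts
(4 × 30, 600 s at 10 s) for profiling recovery over 5 seeds,
200-track cohorts for diffusion statistics, 60 tracks × 5 subsampling
factors for the sampling-bias fit. All random draws flow from explicit
seeds (numpy `default_rng` / `SeedSequence`); UMAP runs with a fixed
`random_state`; density-peak ties break by index. Reruns are
bit-identical.

## Known limitations

- DTW costs grow with the product of series lengths; the all-pairs matrix
  is O(N²) in tracks. Hundreds of tracks are comfortable; tens of
  thousands call for banding or pruning not implemented here.
- The quality composite's goodness mappings are reasonable but arbitrary
  at the margins (the 50-dB PSNR full-marks point, the CV cap); raw
  indices are reported so alternatives cost nothing.
- estimate_z trusts the brightest-plane assumption; overlapping cells at
  the same (x, y) or strong depth-dependent attenuation violate it.
- The native CSV/JSON dialects cover TrackMate-style exports; Imaris
  binary formats and OME-XML metadata are out of scope.
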