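# ivtk — intravital-microscopy cell-track and video analysis

`ivtk` is a Python toolkit for quantitative analysis of immune-cell
motility in intravital microscopy (IVM) recordings: per-track motility
metrics, unsupervised motility-pattern profiling, depth recovery from
2D-projected tracks, video quality scoring, and the corrections needed
when pooling data across videos acquired with different settings. It is
aimed at experimentalists and image analysts working with cell-tracking
output (FIJI/TrackMate exports, JSON track records) and 3D+time image
stacks (TIFF/HDF5), and at method developers who need labeled synthetic
tracks and movies to benchmark against.

## What it computes

**Motility metrics** for a track of centroids $p_0 \dots p_n$ at times
$t_0 \dots t_n$ (µm, seconds):

- speed $= L/T$ with path length $L=\sum_i \lVert p_{i+1}-p_i \rVert$ and
  duration $T$ in minutes (µm/min);
- directionality (straightness) $= \lVert p_n - p_0 \rVert / L \in [0,1]$;
- arrest coefficient: duration-weighted fraction of steps with
  instantaneous speed below a threshold (default 2 µm/min);
- square displacement $\lVert p_i - p_0\rVert^2$, MSD
  $\mathrm{MSD}(k)=\langle\lVert p_{i+k}-p_i\rVert^2\rangle_i$, velocity
  autocovariance $\langle v_i \cdot v_{i+k}\rangle_i$, mean turning angle;
- tracklet extraction (20 steps, ≤ 15 overlap), per-video control-based
  residual speeds, and the exponential sampling-rate bias fit
  $\mathrm{speed} = a\,e^{b\,\Delta t}$.

**Motility-pattern profiling**: tracks ≥ 500 s are resampled to 10 s,
summarized per sliding 50-s window (five samples) by directionality,
square displacement, mean speed and an inverse-MSD arrest feature,
z-scored, compared by dependent multivariate dynamic time warping (DTW),
embedded in 2D with UMAP (`min_dist` 0.1, 5 neighbors) and clustered by
density peaks: each point gets a local density $\rho$ and a distance
$\delta$ to the nearest denser point; the $k$ points with the highest
$\gamma=\rho\,\delta$ seed the clusters, and assignment follows shortest
paths over a distance-pruned graph (edges ≤ 0.1 in normalized
coordinates), which tolerates non-convex cluster shapes.

**Imaging**: maximum-intensity projection, 8-bit rendering normalization
(discarding the brightest 1 % of pixels), five video quality indices —
contrast (CR), noise (NR, PSNR vs a median-filtered copy), photobleaching
(PB, slope of per-frame mean intensity), saturation (SAT, fraction of
uint8 pixels in 245–255) and signal variation (SV) — mapped to goodness
subscores whose mean is a composite quality score in [0, 1]; and
z-recovery, which assigns each 2D track point the z-slice whose intensity
at (x, y) attains the projection maximum, validated by R² against known
depths (> 0.8 = accurate by convention).

**Synthetic data**: labeled track generators for four motility archetypes
(directed, arrested, brownian, run-and-pause) and 3D+time Gaussian-blob
movies with controllable bleaching, noise, drift and saturation — every
analysis above is testable offline with ground truth.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/02_sampling_rate_bias.py` measures the same 60 Brownian
tracks at coarser and coarser frame intervals:

```
frame interval    10 s   mean measured speed  8.00 µm/min
frame interval    20 s   mean measured speed  5.08 µm/min
frame interval    40 s   mean measured speed  3.62 µm/min
frame interval    80 s   mean measured speed  2.52 µm/min
frame interval   160 s   mean measured speed  1.74 µm/min

exp1 fit: speed = 8.21 · exp(-0.0160 · Δt)   rmse 0.84 µm/min
```

The motion never changes — only the sampling does — yet the measured
speed falls by a factor of 4.6, because coarse sampling straightens out
sub-interval wiggles. The fitted decay quantifies the bias; speeds from
videos with different frame intervals are not comparable without it.

`python examples/05_motility_profiling.py` runs the full profiling
pipeline on 120 synthetic tracks from four planted archetypes and recovers
them perfectly (rows = planted, columns = recovered cluster):

```
planted archetype vs recovered cluster:
cluster         1   2   3   4
arrested        0  30   0   0
brownian        0   0  30   0
directed       30   0   0   0
run_and_pause   0   0   0  30
```

and `python examples/04_z_recovery.py` recovers blob depth from noisy
movies (SNR ≈ 5): `median R² 0.930, 16/20 movies above the 0.8 accuracy
convention`.

## Command line

The same pipelines are exposed as `ivtk metrics`, `ivtk profile`,
`ivtk quality`, `ivtk zrecover` and `ivtk simulate`; every run writes a
provenance JSON (config, input digests, version, seed) next to its
outputs. See `ivtk --help`.

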