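"""Motility-pattern profiling: windowed features → multivariate DTW →
UMAP embedding → density-peak/graph clustering → cluster profiles.

Each track is summarized as a four-dimensional time series over a sliding
50-s window (five 10-s samples): directionality, square displacement, mean
speed, and an arrest feature taken as the inverse windowed MSD (the inverse
avoids the discretization a thresholded arrest coefficient suffers on such
short windows). Pooled z-scoring puts the four features on one scale, and
dependent multivariate dynamic time warping — one warping path over the
4-vector series — yields an N×N distance matrix that is well defined for
tracks of different durations. The matrix is embedded in 2D with UMAP and
clustered by density peaks: points are ranked by local density ρ and by the
distance δ to the nearest denser point, centers are the top-k by γ = ρ·δ,
and the remaining points follow shortest paths over a distance-pruned graph
to their cheapest center. Unlike k-means this handles non-convex cluster
shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .motility import motility_table
from .tracks_io import Track, filter_by_duration, resample_track

__all__ = [
    "WindowedFeatureSeries",
    "ClusterResult",
    "ProfilingResult",
    "window_features",
    "normalize_features",
    "dtw_distance",
    "dtw_distance_matrix",
    "embed",
    "density_peak_cluster",
    "cluster_profile",
    "profile_pipeline",
]

FEATURE_NAMES = ("directionality", "square_displacement", "mean_speed", "inv_msd_arrest")


@dataclass
class WindowedFeatureSeries:
    """Per-track sliding-window feature matrix (W windows × 4 features)."""

    track_id: str
    values: np.ndarray
    window_start_times: np.ndarray
    normalization: tuple[np.ndarray, np.ndarray] | None = None  # (mean, sd)


@dataclass
class ClusterResult:
    """Density-peak labels (1..k) with the decision-graph scores.

    rho is the Gaussian-kernel local density, delta the distance to the
    nearest denser point, gamma their product; centers are the indices of
    the k highest-gamma points, ordered so cluster label i+1 belongs to
    centers[i].
    """

    labels: np.ndarray
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    centers: np.ndarray
    d_c: float
    prune_threshold: float


@dataclass
class ProfilingResult:
    """All artifacts of one profiling run."""

    track_ids: list[str]
    features: list[WindowedFeatureSeries]
    distance_matrix: np.ndarray
    embedding: np.ndarray
    clusters: ClusterResult
    profile: pd.DataFrame
    metrics: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# windowed features
# ---------------------------------------------------------------------------


def window_features(
    track: Track,
    window_s: float = 50.0,
    dt_s: float = 10.0,
    epsilon_um2: float = 1e-3,
) -> WindowedFeatureSeries:
    """Sliding-window 4-feature series for one uniformly sampled track.

    Windows comprise ``window_s/dt_s`` samples (five 10-s time points for
    the defaults — a 50-s window) and slide by one sample, so a track with
    S samples yields S − 4 windows. Per window: directionality, square displacement
    ``|p_end − p_start|²``, mean speed (window path length over window
    duration, µm/min), and the arrest feature ``1/(MSD_w + ε)`` where MSD_w
    is the mean squared displacement from the window start. ε floors the
    arrest feature to ``1/ε`` for perfectly still windows.
    """
    dt = track.sampling_interval()
    if dt is None or abs(dt - dt_s) > 1e-6 * dt_s:
        raise ValueError(
            f"track {track.track_id!r} must be uniformly sampled at {dt_s}s; resample first"
        )
    w_pts = int(round(window_s / dt_s))  # samples per window (5 at defaults)
    n = len(track)
    if n < w_pts:
        raise ValueError(
            f"track {track.track_id!r}: {n} samples < one {window_s}s window"
        )
    pos = track.positions
    t = track.t
    n_win = n - w_pts + 1
    vals = np.empty((n_win, 4))
    step_len = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dur_min = (w_pts - 1) * dt_s / 60.0
    for i in range(n_win):
        seg = pos[i : i + w_pts]
        disp = np.linalg.norm(seg[-1] - seg[0])
        path = step_len[i : i + w_pts - 1].sum()
        sq = (seg - seg[0]) ** 2
        msd_w = float(np.sum(sq, axis=1).mean())
        vals[i, 0] = disp / path if path > 0 else 0.0
        vals[i, 1] = disp**2
        vals[i, 2] = path / dur_min
        vals[i, 3] = 1.0 / (msd_w + epsilon_um2)
    return WindowedFeatureSeries(
        track_id=track.track_id, values=vals, window_start_times=t[:n_win].copy()
    )


def normalize_features(
    series: list[WindowedFeatureSeries],
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[list[WindowedFeatureSeries], tuple[np.ndarray, np.ndarray]]:
    """Z-score each feature over the pooled windows of all tracks.

    Returns normalized copies plus the (mean, sd) used, so held-out series
    can be normalized consistently. A zero-variance feature maps to 0.
    """
    pooled = np.vstack([s.values for s in series])
    if pooled.shape[0] < 2:
        raise ValueError("need >=2 windows in total to normalize")
    if stats is None:
        mean = pooled.mean(axis=0)
        sd = pooled.std(axis=0, ddof=0)
    else:
        mean, sd = stats
    safe_sd = np.where(sd > 0, sd, 1.0)
    out = [
        WindowedFeatureSeries(
            track_id=s.track_id,
            values=np.where(sd > 0, (s.values - mean) / safe_sd, 0.0),
            window_start_times=s.window_start_times,
            normalization=(mean, sd),
        )
        for s in series
    ]
    return out, (mean, sd)


# ---------------------------------------------------------------------------
# multivariate DTW
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _dtw_dp(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - jitted
    n, m = a.shape[0], b.shape[0]
    big = np.inf
    acc = np.full((n + 1, m + 1), big)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = 0.0
            for f in range(a.shape[1]):
                diff = a[i - 1, f] - b[j - 1, f]
                d += diff * diff
            cost = np.sqrt(d)
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = cost + best
    return acc[n, m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dependent multivariate DTW distance between two feature series.

    A single warping path aligns the two sequences of 4-vectors; the local
    cost is the Euclidean distance between aligned vectors and the distance
    is the minimal cumulative cost (no band constraint), so series of
    different lengths are comparable.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("series must be 2D with matching feature dimension")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("empty series")
    return float(_dtw_dp(a, b))


def dtw_distance_matrix(series: list[WindowedFeatureSeries] | list[np.ndarray]) -> np.ndarray:
    """Symmetric zero-diagonal N×N matrix of pairwise DTW distances."""
    mats = [s.values if isinstance(s, WindowedFeatureSeries) else np.asarray(s) for s in series]
    n = len(mats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(mats[i], mats[j])
    return D


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def embed(
    D: np.ndarray,
    min_distance: float = 0.1,
    neighbors: int = 5,
    seed: int = 42,
) -> np.ndarray:
    """2D UMAP embedding of a precomputed distance matrix.

    Deterministic for a fixed seed (UMAP runs single-threaded when given a
    random_state). Requires N >= neighbors + 1.
    """
    import umap  # deferred: numba compilation on first import is slow

    D = np.asarray(D, dtype=float)
    if D.shape[0] < neighbors + 1:
        raise ValueError(f"need at least {neighbors + 1} samples for {neighbors} neighbors")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=neighbors,
            min_dist=min_distance,
            metric="precomputed",
            random_state=seed,
        )
        emb = reducer.fit_transform(D)
    return np.asarray(emb, dtype=float)


# ---------------------------------------------------------------------------
# density-peak clustering
# ---------------------------------------------------------------------------


def _minmax(points: np.ndarray) -> np.ndarray:
    lo = points.min(axis=0)
    rng = points.max(axis=0) - lo
    rng = np.where(rng > 0, rng, 1.0)
    return (points - lo) / rng


def density_peak_cluster(
    points: np.ndarray,
    k: int,
    prune_threshold: float = 0.1,
    dc_percentile: float = 2.0,
    unreachable: str = "nearest",
) -> ClusterResult:
    """Density-peak clustering with shortest-path assignment on a pruned graph.

    Coordinates are min-max normalized per axis to [0, 1]. The local
    density is ``ρ_i = Σ_j exp(−(d_ij/d_c)²)`` with ``d_c`` the
    *dc_percentile*-th percentile of pairwise distances; ``δ_i`` is the
    distance to the nearest point of higher density (the global density
    maximum takes the largest pairwise distance). The k points with the
    highest ``γ = ρ·δ`` become centers; every other point is assigned to
    the center with the cheapest shortest path over the graph whose edges
    connect pairs closer than *prune_threshold* (edge weight = distance).
    Points unreachable from every center fall back to the nearest center by
    direct distance (``unreachable="nearest"``) or keep label 0
    (``unreachable="noise"``).

    Density ties break to the lower point index; center-selection ties break
    by γ then index. Labels are 1..k, with label i+1 at ``centers[i]``.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    norm = _minmax(pts)
    dist = squareform(pdist(norm)) if n > 1 else np.zeros((1, 1))

    if n == 1:
        return ClusterResult(
            labels=np.array([1]), rho=np.array([1.0]), delta=np.array([0.0]),
            gamma=np.array([0.0]), centers=np.array([0]), d_c=0.0,
            prune_threshold=prune_threshold,
        )

    off_diag = dist[np.triu_indices(n, k=1)]
    d_c = float(np.percentile(off_diag, dc_percentile))
    if d_c <= 0:
        d_c = max(off_diag[off_diag > 0].min(initial=1.0), 1e-12)
    rho = np.exp(-((dist / d_c) ** 2)).sum(axis=1) - 1.0  # exclude self term

    # density order: higher rho first, ties to the lower index
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    max_dist = float(off_diag.max())
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = max_dist
        else:
            delta[i] = dist[i, order[:pos]].min()
    gamma = rho * delta

    center_order = np.lexsort((np.arange(n), -gamma))
    centers = np.array(sorted(center_order[:k], key=lambda i: (-gamma[i], i)))

    # pruned graph: keep edges not longer than the threshold; duplicate points
    # (zero distance) get a vanishing weight so csr does not drop the edge
    adj = np.where(dist <= prune_threshold, np.maximum(dist, 1e-15), 0.0)
    np.fill_diagonal(adj, 0.0)
    costs = dijkstra(csr_matrix(adj), directed=False, indices=centers)

    labels = np.zeros(n, dtype=int)
    reach = np.isfinite(costs).any(axis=0)
    best = np.argmin(costs, axis=0)
    labels[reach] = best[reach] + 1
    labels[centers] = np.arange(k) + 1  # centers always belong to themselves
    if unreachable == "nearest":
        if (~reach).any():
            direct = dist[np.ix_(centers, np.nonzero(~reach)[0])]
            labels[~reach] = np.argmin(direct, axis=0) + 1
    elif unreachable != "noise":
        raise ValueError("unreachable must be 'nearest' or 'noise'")
    return ClusterResult(
        labels=labels, rho=rho, delta=delta, gamma=gamma, centers=centers,
        d_c=d_c, prune_threshold=prune_threshold,
    )


# ---------------------------------------------------------------------------
# cluster profiles and the full pipeline
# ---------------------------------------------------------------------------


def cluster_profile(
    labels: np.ndarray | ClusterResult,
    records: pd.DataFrame,
    metric_cols: tuple[str, ...] = (
        "speed",
        "directionality",
        "arrest_coefficient",
        "displacement",
        "path_length",
    ),
) -> pd.DataFrame:
    """Per-cluster mean of each metric, min-max normalized across clusters.

    With a single cluster the normalization is degenerate and every value is
    reported as 0.5. Rows are indexed by cluster label.
    """
    if isinstance(labels, ClusterResult):
        labels = labels.labels
    labels = np.asarray(labels)
    if len(labels) != len(records):
        raise ValueError("labels and records length mismatch")
    df = records.copy()
    df["_cluster"] = labels
    if (df.groupby("_cluster").size() == 0).any():
        raise ValueError("empty cluster")
    means = df.groupby("_cluster")[list(metric_cols)].mean()
    if len(means) == 1:
        return means * 0 + 0.5
    lo = means.min(axis=0)
    rng = means.max(axis=0) - lo
    out = (means - lo).div(rng.where(rng > 0, 1.0), axis=1)
    out.loc[:, rng == 0] = 0.5
    return out


def profile_pipeline(
    tracks: list[Track],
    k: int = 10,
    min_duration_s: float = 500.0,
    dt_s: float = 10.0,
    window_s: float = 50.0,
    epsilon_um2: float = 1e-3,
    umap_neighbors: int = 5,
    umap_min_distance: float = 0.1,
    prune_threshold: float = 0.1,
    dc_percentile: float = 2.0,
    arrest_threshold: float = 2.0,
    seed: int = 42,
) -> ProfilingResult:
    """Run the full motility-profiling pipeline on raw tracks.

    Composes: duration filter → 10-s resampling → 50-s windowed features →
    pooled z-scoring → multivariate DTW distance matrix → UMAP(2D) →
    density-peak clustering (k clusters) → min-max cluster profiles over the
    per-track motility metrics.
    """
    kept = filter_by_duration(tracks, min_duration_s)
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} tracks pass the {min_duration_s}s duration filter")
    resampled = [resample_track(t, dt_s) for t in kept]
    feats = [window_features(t, window_s, dt_s, epsilon_um2) for t in resampled]
    normed, _ = normalize_features(feats)
    D = dtw_distance_matrix(normed)
    emb = embed(D, min_distance=umap_min_distance, neighbors=umap_neighbors, seed=seed)
    clusters = density_peak_cluster(
        emb, k=k, prune_threshold=prune_threshold, dc_percentile=dc_percentile
    )
    metrics = motility_table(resampled, arrest_threshold=arrest_threshold)
    profile = cluster_profile(clusters, metrics)
    return ProfilingResult(
        track_ids=[t.track_id for t in resampled],
        features=normed,
        distance_matrix=D,
        embedding=emb,
        clusters=clusters,
        profile=profile,
        metrics=metrics,
        seed=seed,
    )
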