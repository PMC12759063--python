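"""Per-track motility metrics, control-based speed correction and
sampling-rate decay fitting.

Metrics follow the standard cell-migration definitions: speed is total path
length over duration (µm/min), directionality (straightness) is net
displacement over path length, the arrest coefficient is the fraction of a
track's time spent below an instantaneous-speed threshold, and MSD /
velocity autocovariance characterize the motion mode (linear MSD for
diffusive, quadratic for ballistic motion).

Measured speed is biased by the acquisition frame interval: coarser sampling
straightens out sub-interval wiggles, so speed decreases with Δt. That bias
is summarized by fitting an exponential decay ``speed = a·exp(b·Δt)``
(:func:`fit_speed_decay`), and removed across videos by referencing each
track to a control population imaged in the same video
(:func:`residual_speeds`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracks_io import Track

__all__ = [
    "MotilityRecord",
    "DecayFit",
    "path_length",
    "displacement",
    "track_speed",
    "directionality",
    "square_displacement",
    "arrest_coefficient",
    "msd",
    "velocity_autocovariance",
    "mean_turning_angle",
    "motility_record",
    "motility_table",
    "residual_speeds",
    "fit_speed_decay",
]

DEFAULT_ARREST_THRESHOLD = 2.0  # µm/min


@dataclass(frozen=True)
class MotilityRecord:
    """Summary metrics for one track. Speeds in µm/min, lengths in µm."""

    track_id: str
    speed: float
    directionality: float
    arrest_coefficient: float
    displacement: float
    path_length: float
    duration_min: float
    mean_turning_angle: float  # degrees; NaN for tracks with <2 usable turns
    ndim: int
    video_id: str = ""
    cell_type: str = ""


@dataclass(frozen=True)
class DecayFit:
    """Exponential decay fit ``speed = a·exp(b·Δt)`` with Δt in seconds."""

    a: float  # amplitude, µm/min
    b: float  # rate, 1/s (negative when subsampling slows measured speed)
    residual_rmse: float  # µm/min

    def predict(self, dt_s) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(dt_s, dtype=float))


def _steps(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """Step displacement vectors (µm) and step durations (s)."""
    pos = track.positions
    return np.diff(pos, axis=0), np.diff(track.t)


def path_length(track: Track) -> float:
    """Total length of the polyline through all centroids, in µm."""
    vec, _ = _steps(track)
    return float(np.linalg.norm(vec, axis=1).sum()) if len(vec) else 0.0


def displacement(track: Track) -> float:
    """Straight-line distance from first to last centroid, in µm."""
    pos = track.positions
    return float(np.linalg.norm(pos[-1] - pos[0]))


def track_speed(track: Track) -> float:
    """Mean speed: path length divided by duration, in µm/min."""
    if len(track) < 2:
        raise ValueError(f"track {track.track_id!r}: need >=2 points for speed")
    dur_min = track.duration_s / 60.0
    if dur_min <= 0:
        raise ValueError(f"track {track.track_id!r}: zero duration")
    return path_length(track) / dur_min


def directionality(track: Track) -> float:
    """Straightness: displacement / path length, in [0, 1]; 0 for a still track."""
    if len(track) < 2:
        raise ValueError(f"track {track.track_id!r}: need >=2 points")
    pl = path_length(track)
    if pl == 0.0:
        return 0.0
    return min(displacement(track) / pl, 1.0)


def square_displacement(track: Track) -> np.ndarray:
    """Squared distance of every point from the track origin, µm²; first is 0."""
    pos = track.positions
    return np.sum((pos - pos[0]) ** 2, axis=1)


def arrest_coefficient(track: Track, speed_threshold: float = DEFAULT_ARREST_THRESHOLD) -> float:
    """Duration-weighted fraction of time with instantaneous speed below threshold.

    Each inter-point interval contributes its duration when its speed
    (step length / step duration, µm/min) is strictly below
    *speed_threshold*; for equal-duration steps this reduces to the fraction
    of arrested steps. 1 means fully arrested.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.track_id!r}: need >=2 points")
    vec, dts = _steps(track)
    speeds = np.linalg.norm(vec, axis=1) / (dts / 60.0)
    return float(dts[speeds < speed_threshold].sum() / dts.sum())


def _require_uniform(track: Track) -> float:
    dt = track.sampling_interval()
    if dt is None:
        raise ValueError(
            f"track {track.track_id!r} is not uniformly sampled; resample first"
        )
    return dt


def msd(track: Track, max_lag: int) -> np.ndarray:
    """Mean squared displacement over overlapping pairs, µm², lags 0..max_lag."""
    _require_uniform(track)
    n = len(track)
    if not (0 <= max_lag < n):
        raise ValueError("max_lag must be < number of points")
    pos = track.positions
    out = np.empty(max_lag + 1)
    out[0] = 0.0
    for k in range(1, max_lag + 1):
        d = pos[k:] - pos[:-k]
        out[k] = np.mean(np.sum(d * d, axis=1))
    return out


def velocity_autocovariance(track: Track, max_lag: int) -> np.ndarray:
    """Mean dot product of step velocities k steps apart, (µm/min)²."""
    dt = _require_uniform(track)
    vec, _ = _steps(track)
    v = vec / (dt / 60.0)
    n = len(v)
    if not (0 <= max_lag < n):
        raise ValueError("max_lag must be < number of steps")
    out = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        out[k] = np.mean(np.sum(v[: n - k] * v[k:], axis=1))
    return out


def mean_turning_angle(track: Track) -> float:
    """Mean angle between consecutive step vectors, degrees in [0, 180].

    Zero-length steps have no direction and are skipped; at least two
    usable (non-zero) consecutive steps are required.
    """
    if len(track) < 3:
        raise ValueError(f"track {track.track_id!r}: need >=3 points for turning angles")
    vec, _ = _steps(track)
    norms = np.linalg.norm(vec, axis=1)
    usable = vec[norms > 0]
    if len(usable) < 2:
        raise ValueError(f"track {track.track_id!r}: fewer than 2 non-zero steps")
    u = usable / np.linalg.norm(usable, axis=1, keepdims=True)
    cosang = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)).mean())


def motility_record(
    track: Track, arrest_threshold: float = DEFAULT_ARREST_THRESHOLD
) -> MotilityRecord:
    """All summary metrics for one track in a single record."""
    try:
        mta = mean_turning_angle(track)
    except ValueError:
        mta = float("nan")
    return MotilityRecord(
        track_id=track.track_id,
        speed=track_speed(track),
        directionality=directionality(track),
        arrest_coefficient=arrest_coefficient(track, arrest_threshold),
        displacement=displacement(track),
        path_length=path_length(track),
        duration_min=track.duration_s / 60.0,
        mean_turning_angle=mta,
        ndim=track.ndim,
        video_id=track.video_id,
        cell_type=track.cell_type,
    )


def motility_table(
    tracks, arrest_threshold: float = DEFAULT_ARREST_THRESHOLD
) -> pd.DataFrame:
    """One MotilityRecord row per track, as a DataFrame.

    Raises if 2D and 3D tracks are mixed: their metrics are not directly
    comparable (a 2D projection shortens paths).
    """
    records = [motility_record(t, arrest_threshold) for t in tracks]
    if len({r.ndim for r in records}) > 1:
        raise ValueError("refusing to mix 2D and 3D tracks in one metric table")
    return pd.DataFrame([vars(r) for r in records])


def residual_speeds(
    records: pd.DataFrame,
    control_population: str,
    population_col: str = "cell_type",
    video_col: str = "video_id",
    speed_col: str = "speed",
) -> pd.DataFrame:
    """Per-video control-referenced speeds, pooled across videos.

    Subtracts from each track's speed the mean speed of the
    *control_population* tracks of the same video, removing video-level
    acquisition effects so populations from different videos can be pooled.
    Returns a copy with a ``residual_speed`` column.
    """
    out = records.copy()
    control = out[out[population_col] == control_population]
    means = control.groupby(video_col)[speed_col].mean()
    missing = sorted(set(out[video_col]) - set(means.index))
    if missing:
        raise ValueError(
            f"videos without any {control_population!r} control tracks: {missing}"
        )
    out["residual_speed"] = out[speed_col] - out[video_col].map(means)
    return out


def fit_speed_decay(points) -> DecayFit:
    """Fit ``speed = a·exp(b·Δt)`` to (Δt seconds, speed µm/min) pairs.

    Solved as a nonlinear least-squares problem initialized from the
    log-linear fit, so near-zero rates and noisy values are handled without
    the bias of a pure log transform.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >=3 (dt, speed) pairs")
    dt, sp = pts[:, 0], pts[:, 1]
    if np.unique(dt).size < 2:
        raise ValueError("degenerate fit: all dt values identical")
    # log-linear initial guess; floor speeds to keep the log finite
    logs = np.log(np.maximum(sp, 1e-12))
    b0, loga0 = np.polyfit(dt, logs, 1)
    p, _ = curve_fit(
        lambda x, a, b: a * np.exp(b * x),
        dt,
        sp,
        p0=(float(np.exp(loga0)), float(b0)),
        maxfev=20000,
    )
    a, b = float(p[0]), float(p[1])
    rmse = float(np.sqrt(np.mean((a * np.exp(b * dt) - sp) ** 2)))
    return DecayFit(a=a, b=b, residual_rmse=rmse)
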