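"""Image-stack operations, video quality indices, and z-recovery.

Works on 3D+time single-channel stacks ordered T×Z×Y×X. The quality
indices mirror what an experimentalist inspects in an intravital recording:
contrast (CR), noise (NR, a PSNR against a median-filtered copy),
photobleaching (PB, trend of per-frame mean intensity), saturation (SAT,
fraction of near-max 8-bit pixels) and signal variation over time (SV).
They are computed on the 8-bit-normalized maximum-intensity-projection
movie — the same rendering a viewer sees — because the saturation
definition (uint8 values 245–255) only exists after rendering.

Z-recovery exploits the fact that a maximum-intensity projection stores,
per (x, y), the brightest z-plane's value: for a cell tracked on the 2D
projection, the z-slice whose intensity at (x, y) attains that maximum is
the cell's depth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
from scipy.ndimage import median_filter

from .tracks_io import Track

__all__ = [
    "ImageStack",
    "QualityReport",
    "ZEstimate",
    "read_stack",
    "write_stack",
    "max_intensity_projection",
    "normalize_8bit",
    "saturation_index",
    "photobleaching_index",
    "signal_variation_index",
    "contrast_index",
    "noise_index",
    "quality_report",
    "estimate_z",
    "validate_z",
]


@dataclass
class ImageStack:
    """A single-channel 3D+time stack.

    data: array ordered T×Z×Y×X (Z may be 1); non-negative intensities.
    voxel_size_um: physical size of one voxel along (x, y, z), in µm.
    frame_interval_s: time between consecutive frames, seconds.
    bit_depth: bit depth of the source acquisition.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval_s: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"stack must be T×Z×Y×X, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all stack dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_um) or self.frame_interval_s <= 0:
            raise ValueError("voxel sizes and frame interval must be positive")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self):  # (T, Z, Y, X)
        return self.data.shape


@dataclass
class QualityReport:
    """Five raw indices, five goodness subscores in [0,1], and their mean."""

    raw: dict[str, float]
    goodness: dict[str, float]
    composite: float
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _enc(v):
            return "inf" if isinstance(v, float) and math.isinf(v) else v

        payload = {
            "raw": {k: _enc(v) for k, v in self.raw.items()},
            "goodness": self.goodness,
            "composite": self.composite,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class ZEstimate:
    """Recovered depth per track point: 0-based z index and z in µm."""

    track_id: str
    z_index: np.ndarray
    z_um: np.ndarray
    r_squared: float | None = None


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    frame_interval_s: float | None = None,
    n_z: int | None = None,
) -> ImageStack:
    """Load a stack from HDF5 (``/stack`` dataset with attributes) or TIFF.

    HDF5 files written by :func:`write_stack` carry ``voxel_size_um`` and
    ``frame_interval_s`` attributes; files without them are refused unless
    the values are passed explicitly. TIFF pages are ordered T-then-Z, so
    *n_z* is required for TIFF unless the file stores a 4D series.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["stack"]
            data = ds[()]
            vs = ds.attrs.get("voxel_size_um")
            fi = ds.attrs.get("frame_interval_s")
            bd = int(ds.attrs.get("bit_depth", 16))
        vs = tuple(vs) if vs is not None else voxel_size_um
        fi = float(fi) if fi is not None else frame_interval_s
        if vs is None or fi is None:
            raise ValueError(
                f"{path}: missing voxel_size_um/frame_interval_s attributes; "
                "pass them explicitly"
            )
        return ImageStack(data, tuple(float(v) for v in vs), float(fi), bd)
    if path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 3:
            if n_z is None:
                raise ValueError(f"{path}: pages are T×Z interleaved; pass n_z")
            t = data.shape[0] // n_z
            data = data[: t * n_z].reshape(t, n_z, *data.shape[1:])
        elif data.ndim != 4:
            raise ValueError(f"{path}: expected 3D or 4D TIFF, got {data.ndim}D")
        if voxel_size_um is None or frame_interval_s is None:
            raise ValueError(f"{path}: pass voxel_size_um and frame_interval_s for TIFF")
        return ImageStack(data, voxel_size_um, frame_interval_s)
    raise ValueError(f"unsupported stack format: {path.suffix!r}")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to HDF5 (with metadata attributes) or TIFF (T-then-Z pages)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("stack", data=stack.data)
            ds.attrs["voxel_size_um"] = np.asarray(stack.voxel_size_um, dtype=float)
            ds.attrs["frame_interval_s"] = float(stack.frame_interval_s)
            ds.attrs["bit_depth"] = stack.bit_depth
    elif path.suffix in (".tif", ".tiff"):
        t, z, y, x = stack.data.shape
        tifffile.imwrite(path, stack.data.reshape(t * z, y, x))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def max_intensity_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Per-frame maximum over z: T×Z×Y×X → T×Y×X."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    return data.max(axis=1)


def normalize_8bit(movie: np.ndarray, saturate_fraction: float = 0.01) -> np.ndarray:
    """Linear rescale of a movie to uint8, discarding the brightest pixels.

    Maps ``[min, q]`` to ``[0, 255]`` where ``q`` is the
    ``1 - saturate_fraction`` quantile over the whole movie; values above
    ``q`` clip to 255. A constant movie maps to all zeros.
    """
    if not (0 <= saturate_fraction < 1):
        raise ValueError("saturate_fraction must be in [0, 1)")
    movie = np.asarray(movie, dtype=float)
    lo = movie.min()
    q = np.quantile(movie, 1.0 - saturate_fraction)
    if q <= lo:
        return np.zeros(movie.shape, dtype=np.uint8)
    scaled = (movie - lo) * (255.0 / (q - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# quality indices
# ---------------------------------------------------------------------------


def saturation_index(movie_8bit: np.ndarray) -> float:
    """Fraction of pixels with uint8 value in [245, 255]."""
    m = np.asarray(movie_8bit)
    return float(np.count_nonzero(m >= 245) / m.size)


def photobleaching_index(movie: np.ndarray) -> float:
    """OLS slope of per-frame mean intensity against frame index.

    Negative values indicate fluorescence loss over the recording.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] < 2:
        raise ValueError("need >=2 frames for a bleaching slope")
    means = movie.reshape(movie.shape[0], -1).mean(axis=1)
    slope, _ = np.polyfit(np.arange(len(means)), means, 1)
    return float(slope)


def signal_variation_index(movie: np.ndarray) -> float:
    """Coefficient of variation of per-frame mean intensities (population SD)."""
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] < 2:
        raise ValueError("need >=2 frames for signal variation")
    means = movie.reshape(movie.shape[0], -1).mean(axis=1)
    mu = means.mean()
    if mu == 0:
        return 0.0
    return float(means.std(ddof=0) / mu)


def _stretch_reference(movie: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Contrast-optimized reference: stretch the 1st–99th percentiles to full range."""
    movie = np.asarray(movie, dtype=float)
    lo, hi = np.percentile(movie, [p_low, p_high])
    if hi <= lo:
        raise ValueError("reference undefined: movie has no dynamic range")
    full = 255.0 if movie.max() <= 255 else movie.max()
    return np.clip((movie - lo) * (full / (hi - lo)), 0, full)


def contrast_index(movie: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> float:
    """Relative variance gap to a contrast-optimized reference.

    ``|Var(reference) − Var(original)| / Var(reference)``; 0 means the movie
    already uses its dynamic range, larger values mean poorer contrast.
    """
    movie = np.asarray(movie, dtype=float)
    ref = _stretch_reference(movie, p_low, p_high)
    var_ref = ref.var()
    if var_ref == 0:
        raise ValueError("reference variance is zero")
    return float(abs(var_ref - movie.var()) / var_ref)


def noise_index(movie_8bit: np.ndarray, filter_size: int = 3) -> float:
    """PSNR (dB) of the movie against its per-frame median-filtered copy.

    Higher is cleaner; a perfectly clean movie (identical to its filtered
    copy) returns +inf.
    """
    m = np.asarray(movie_8bit, dtype=float)
    den = median_filter(m, size=(1, filter_size, filter_size), mode="reflect")
    mse = np.mean((m - den) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


def quality_report(
    stack: ImageStack,
    channel: int | None = None,
    saturate_fraction: float = 0.01,
    psnr_full_marks_db: float = 50.0,
    weights: dict[str, float] | None = None,
) -> QualityReport:
    """Compute the five quality indices and the composite score for one channel.

    The stack data may be 5D (T×C×Z×Y×X) with *channel* selecting one
    channel, or plain 4D. Raw indices are computed on the 8-bit-normalized
    MIP movie; each is mapped to a goodness subscore in [0, 1] ("worse
    artifact → lower score") and the composite is their weighted mean
    (unweighted by default):

    * ``CR_good = 1 − min(CR, 1)``
    * ``NR_good = min(PSNR / psnr_full_marks_db, 1)`` (inf → 1)
    * ``PB_good = 1 − min(max(0, −slope)·(F−1)/µ₀, 1)`` — fractional
      intensity loss over the movie, µ₀ the first-frame mean
    * ``SAT_good = 1 − SAT``
    * ``SV_good = 1 − min(CV, 1)``
    """
    data = stack.data
    if data.ndim == 5:
        if channel is None:
            raise ValueError("multi-channel stack: select a channel")
        data = data[:, channel]
    movie8 = normalize_8bit(max_intensity_projection(data), saturate_fraction)

    cr = contrast_index(movie8)
    psnr = noise_index(movie8)
    pb = photobleaching_index(movie8)
    sat = saturation_index(movie8)
    sv = signal_variation_index(movie8)

    mu0 = float(movie8[0].mean())
    n_frames = movie8.shape[0]
    frac_loss = (max(0.0, -pb) * (n_frames - 1) / mu0) if mu0 > 0 else 0.0
    goodness = {
        "CR": 1.0 - min(cr, 1.0),
        "NR": 1.0 if math.isinf(psnr) else min(psnr / psnr_full_marks_db, 1.0),
        "PB": 1.0 - min(frac_loss, 1.0),
        "SAT": 1.0 - sat,
        "SV": 1.0 - min(sv, 1.0),
    }
    w = {k: 1.0 for k in goodness} if weights is None else dict(weights)
    total = sum(w.values())
    composite = sum(goodness[k] * w[k] for k in goodness) / total
    return QualityReport(
        raw={"CR": cr, "NR": psnr, "PB": pb, "SAT": sat, "SV": sv},
        goodness=goodness,
        composite=float(composite),
        params={
            "saturate_fraction": saturate_fraction,
            "psnr_full_marks_db": psnr_full_marks_db,
            "weights": w,
            "channel": channel,
        },
    )


# ---------------------------------------------------------------------------
# z recovery
# ---------------------------------------------------------------------------


def _to_pixel(value_um: float, voxel_um: float, n: int, label: str) -> int:
    # round half-up to the nearest pixel, 0-based
    idx = int(math.floor(value_um / voxel_um + 0.5))
    if not (0 <= idx < n):
        raise ValueError(f"{label}={value_um} µm maps to pixel {idx}, outside [0, {n})")
    return idx


def estimate_z(track2d: Track, stack: ImageStack, frame_tol: float = 1e-6) -> ZEstimate:
    """Recover the z coordinate of each 2D track point from the 3D stack.

    For each point, the frame is looked up from the timestamp and the z
    index is the argmax over z of the intensity at the nearest pixel (y, x)
    — the plane a maximum-intensity projection took that pixel from. Ties
    resolve to the lowest z index.
    """
    t_dim, z_dim, y_dim, x_dim = stack.shape
    vx, vy, vz = stack.voxel_size_um
    z_idx = np.empty(len(track2d), dtype=int)
    for i, p in enumerate(track2d.points):
        f = p.t / stack.frame_interval_s
        frame = int(round(f))
        if abs(f - frame) > frame_tol or not (0 <= frame < t_dim):
            raise ValueError(
                f"track {track2d.track_id!r}: t={p.t}s has no matching frame "
                f"(interval {stack.frame_interval_s}s, {t_dim} frames)"
            )
        xi = _to_pixel(p.x, vx, x_dim, "x")
        yi = _to_pixel(p.y, vy, y_dim, "y")
        z_idx[i] = int(np.argmax(stack.data[frame, :, yi, xi]))
    return ZEstimate(
        track_id=track2d.track_id, z_index=z_idx, z_um=z_idx.astype(float) * vz
    )


def validate_z(estimated_um, truth_um) -> float:
    """Coefficient of determination (R²) of estimated against true z.

    1 is perfect recovery, 0 no better than the mean of the truth; values
    above 0.8 are conventionally read as accurate depth estimation.
    """
    est = np.asarray(estimated_um, dtype=float)
    tru = np.asarray(truth_um, dtype=float)
    if est.shape != tru.shape or est.size < 2:
        raise ValueError("estimated and truth must have equal length >= 2")
    ss_tot = np.sum((tru - tru.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("truth is constant; R² undefined")
    ss_res = np.sum((tru - est) ** 2)
    return float(1.0 - ss_res / ss_tot)
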