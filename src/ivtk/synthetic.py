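"""Ground-truth-labeled synthetic tracks and blob movies.

The generators emulate the ingredients the analyses assume, so every module
is testable without downloads:

* **tracks** — four motility archetypes seen in intravital recordings of
  immune cells: *directed* (persistent walker, e.g. chemotaxing
  neutrophils), *arrested* (cells jiggling in place, e.g. synapse-forming
  T cells), *brownian* (patrolling / meandering motion) and
  *run_and_pause* (two-state switching between directed runs and arrests).
* **movies** — 3D+time stacks of Gaussian blobs following known 3D tracks,
  optionally degraded with photobleaching, field drift, additive Gaussian
  noise and intensity saturation, with the ground truth recorded alongside.

Everything is a pure function of its spec + seed, so outputs are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging_quality import ImageStack
from .tracks_io import Track, TrackPoint

__all__ = [
    "ArchetypeSpec",
    "MovieSpec",
    "ARCHETYPES",
    "archetype_spec",
    "gen_track",
    "gen_cohort",
    "gen_brownian_cohort",
    "gen_movie",
    "gen_quality_pair",
    "gen_zrecovery_movie",
]

ARCHETYPES = ("directed", "arrested", "brownian", "run_and_pause")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one synthetic motility archetype.

    speed_mean is the walker's speed while moving (µm/min); persistence in
    [0, 1] sets the per-step directional correlation (heading perturbation
    SD = (1 − persistence)·π radians); pause_rate / run_rate (1/s) are the
    two-state switching rates of the run-and-pause walker; jitter_sd (µm)
    is the stationary positional SD of an arrested cell, realized as an
    AR(1) jiggle with lag-one correlation 0.9 so consecutive centroids stay
    close, as they do for a real arrested cell.
    """

    mode: str
    speed_mean: float = 10.0  # µm/min
    persistence: float = 0.95
    pause_rate: float = 0.01  # 1/s, run -> pause
    run_rate: float = 0.01  # 1/s, pause -> run
    jitter_sd: float = 0.2  # µm
    duration_s: float = 600.0
    dt_s: float = 10.0
    ndim: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ARCHETYPES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {ARCHETYPES}")
        if not (0 <= self.persistence <= 1):
            raise ValueError("persistence must be in [0, 1]")
        if self.pause_rate < 0 or self.run_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.duration_s < self.dt_s or self.dt_s <= 0:
            raise ValueError("duration must be >= dt > 0")
        if self.ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")


#: per-archetype defaults chosen to mirror typical leukocyte behavior:
#: directed cells move fast and straight, Brownian patrollers are slower
#: and uncorrelated, run-and-pause alternates ~100-s phases of each.
_ARCHETYPE_DEFAULTS = {
    "directed": dict(speed_mean=10.0, persistence=0.97),
    "arrested": dict(speed_mean=0.0, jitter_sd=0.2),
    "brownian": dict(speed_mean=8.0, persistence=0.0),
    "run_and_pause": dict(speed_mean=10.0, persistence=0.95, pause_rate=0.01, run_rate=0.01),
}

_AR1_CORR = 0.9  # lag-one correlation of arrested jiggle


def archetype_spec(mode: str, seed: int = 0, **overrides) -> ArchetypeSpec:
    """An :class:`ArchetypeSpec` with the standard defaults for *mode*."""
    params = dict(_ARCHETYPE_DEFAULTS[mode]) if mode in _ARCHETYPE_DEFAULTS else {}
    params.update(overrides)
    return ArchetypeSpec(mode=mode, seed=seed, **params)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _random_unit(rng: np.random.Generator, ndim: int) -> np.ndarray:
    return _unit(rng.normal(size=ndim))


def _perturb_heading(u: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    # small-angle directional diffusion: works identically in 2D and 3D
    return _unit(u + sigma * rng.normal(size=u.size))


def _jitter_series(n: int, sd: float, ndim: int, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) positional jitter with stationary SD *sd* per axis."""
    innov_sd = sd * np.sqrt(1.0 - _AR1_CORR**2)
    out = np.empty((n, ndim))
    out[0] = rng.normal(scale=sd, size=ndim) if sd > 0 else 0.0
    for i in range(1, n):
        out[i] = _AR1_CORR * out[i - 1] + (
            rng.normal(scale=innov_sd, size=ndim) if sd > 0 else 0.0
        )
    return out


def gen_track(
    spec: ArchetypeSpec,
    track_id: str = "syn0",
    video_id: str = "synthetic",
    origin: np.ndarray | None = None,
) -> Track:
    """Generate one track from *spec*; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_s / spec.dt_s))
    n = n_steps + 1
    step_len = spec.speed_mean * spec.dt_s / 60.0  # µm per step while moving
    sigma = (1.0 - spec.persistence) * np.pi
    origin = np.zeros(spec.ndim) if origin is None else np.asarray(origin, dtype=float)

    pos = np.empty((n, spec.ndim))
    if spec.mode == "arrested":
        pos = origin + _jitter_series(n, spec.jitter_sd, spec.ndim, rng)
    elif spec.mode in ("directed", "brownian"):
        u = _random_unit(rng, spec.ndim)
        pos[0] = origin
        for i in range(1, n):
            if spec.mode == "brownian":
                u = _random_unit(rng, spec.ndim)
            else:
                u = _perturb_heading(u, sigma, rng)
            pos[i] = pos[i - 1] + step_len * u
    else:  # run_and_pause
        u = _random_unit(rng, spec.ndim)
        running = True
        p_stop = min(spec.pause_rate * spec.dt_s, 1.0)
        p_go = min(spec.run_rate * spec.dt_s, 1.0)
        jig_sd = spec.jitter_sd * np.sqrt(1.0 - _AR1_CORR**2)
        pos[0] = origin
        anchor = origin.copy()
        jig = np.zeros(spec.ndim)
        for i in range(1, n):
            if running and rng.random() < p_stop:
                running = False
                anchor = pos[i - 1].copy()
                jig = np.zeros(spec.ndim)
            elif not running and rng.random() < p_go:
                running = True
                u = _random_unit(rng, spec.ndim)
            if running:
                u = _perturb_heading(u, sigma, rng)
                pos[i] = pos[i - 1] + step_len * u
            else:
                jig = _AR1_CORR * jig + rng.normal(scale=jig_sd, size=spec.ndim)
                pos[i] = anchor + jig

    t = spec.dt_s * np.arange(n)
    pts = [TrackPoint(float(ti), *map(float, row)) for ti, row in zip(t, pos)]
    return Track(
        track_id=track_id,
        points=pts,
        video_id=video_id,
        cell_type=spec.mode,
        frame_interval_s=spec.dt_s,
    )


def gen_cohort(
    counts: dict[str, int],
    seed: int = 0,
    overrides: dict[str, dict] | None = None,
    **spec_kwargs,
) -> tuple[list[Track], pd.DataFrame]:
    """Generate a labeled cohort, e.g. ``{"directed": 30, "arrested": 30}``.

    Returns the tracks (unique ids ``<mode><i>``) and a label table with one
    row per track. Per-track seeds are spawned from *seed* so the cohort is
    reproducible as a whole.
    """
    if sum(counts.values()) < 1:
        raise ValueError("empty cohort")
    seeds = np.random.SeedSequence(seed).generate_state(sum(counts.values()))
    tracks, rows = [], []
    i = 0
    for mode, n in counts.items():
        kw = dict(spec_kwargs)
        kw.update((overrides or {}).get(mode, {}))
        for j in range(n):
            spec = archetype_spec(mode, seed=int(seeds[i] % (2**31)), **kw)
            tr = gen_track(spec, track_id=f"{mode}{j}")
            tracks.append(tr)
            rows.append({"track_id": tr.track_id, "label": mode})
            i += 1
    return tracks, pd.DataFrame(rows)


def gen_brownian_cohort(
    n_tracks: int = 200,
    speed_mean: float = 8.0,
    duration_s: float = 600.0,
    dt_s: float = 10.0,
    seed: int = 7,
) -> tuple[list[Track], float]:
    """Brownian cohort plus its nominal diffusion coefficient D (µm²/s).

    The walker takes fixed-length steps L = speed·dt/60 in uniformly random
    directions, so MSD(k·dt) = k·L² and the 2D diffusion coefficient is
    D = L²/(4·dt).
    """
    tracks, _ = gen_cohort(
        {"brownian": n_tracks}, seed=seed,
        overrides={"brownian": dict(speed_mean=speed_mean, persistence=0.0)},
        duration_s=duration_s, dt_s=dt_s,
    )
    step = speed_mean * dt_s / 60.0
    return tracks, step**2 / (4.0 * dt_s)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MovieSpec:
    """Parameters of a synthetic blob movie.

    dims is (T, Z, Y, X) in voxels; blob_sigma_um the isotropic Gaussian
    blob SD; bleach_rate the fractional intensity loss per frame;
    drift_velocity_um the uniform field translation per frame along (x, y)
    — drifting content may leave the field of view, as real tissue drift
    does; saturation_boost multiplies blob amplitude to push pixels past
    detector_max, the detector full-scale at which intensities clip.
    """

    dims: tuple[int, int, int, int] = (20, 15, 64, 64)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval_s: float = 10.0
    blob_sigma_um: float = 1.5
    blob_amplitude: float = 100.0
    background: float = 10.0
    noise_sd: float = 0.0
    bleach_rate: float = 0.0
    saturation_boost: float = 1.0
    drift_velocity_um: tuple[float, float] = (0.0, 0.0)
    detector_max: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if any(d < 1 for d in self.dims):
            raise ValueError("all movie dims must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.bleach_rate < 1):
            raise ValueError("bleach_rate must be in [0, 1)")


def gen_movie(spec: MovieSpec, tracks3d: list[Track]) -> tuple[ImageStack, dict]:
    """Render 3D Gaussian blobs following *tracks3d* into a noisy stack.

    Each frame is ``background + Σ blobs`` scaled by ``(1 − bleach_rate)^f``
    with the whole field translated by the drift, clipped at the detector
    full scale, plus additive Gaussian noise (clipped to the detector
    range). Returns the stack and a truth dict with the per-track true z
    indices, the imposed bleach series and the blob positions per frame.
    Track coordinates themselves must lie inside the field; drifted content
    may leave it (fluorescence loss, as with real tissue drift).
    """
    t_dim, z_dim, y_dim, x_dim = spec.dims
    vx, vy, vz = spec.voxel_size_um
    rng = np.random.default_rng(spec.seed)
    sig_vox = np.array([spec.blob_sigma_um / vz, spec.blob_sigma_um / vy, spec.blob_sigma_um / vx])
    amp = spec.blob_amplitude * spec.saturation_boost

    # per-track voxel-space positions per frame
    blob_pos = []  # list of (frame, zc, yc, xc), drift applied
    truth_z: dict[str, np.ndarray] = {}
    bad: list[str] = []
    for tr in tracks3d:
        if not tr.has_z:
            raise ValueError(f"track {tr.track_id!r}: movies need 3D tracks")
        zs = np.empty(len(tr), dtype=int)
        for i, p in enumerate(tr.points):
            f = int(round(p.t / spec.frame_interval_s))
            xc, yc, zc = p.x / vx, p.y / vy, p.z / vz
            if not (0 <= f < t_dim and 0 <= xc < x_dim and 0 <= yc < y_dim and 0 <= zc < z_dim):
                bad.append(f"{tr.track_id}@t={p.t}")
                continue
            dx = spec.drift_velocity_um[0] * f / vx
            dy = spec.drift_velocity_um[1] * f / vy
            blob_pos.append((f, zc, yc + dy, xc + dx))
            zs[i] = int(np.floor(zc + 0.5))
        truth_z[tr.track_id] = zs
    if bad:
        raise ValueError(f"track points out of bounds: {bad}")

    data = np.full(spec.dims, float(spec.background))
    half = np.ceil(4 * sig_vox).astype(int)
    for f, zc, yc, xc in blob_pos:
        # window around the (possibly drifted-out) center, clamped to the field
        z0 = min(max(0, int(np.floor(zc)) - half[0]), z_dim)
        z1 = max(z0, min(z_dim, int(np.floor(zc)) + half[0] + 1))
        y0 = min(max(0, int(np.floor(yc)) - half[1]), y_dim)
        y1 = max(y0, min(y_dim, int(np.floor(yc)) + half[1] + 1))
        x0 = min(max(0, int(np.floor(xc)) - half[2]), x_dim)
        x1 = max(x0, min(x_dim, int(np.floor(xc)) + half[2] + 1))
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        g = np.exp(
            -(
                (zz - zc) ** 2 / (2 * sig_vox[0] ** 2)
                + (yy - yc) ** 2 / (2 * sig_vox[1] ** 2)
                + (xx - xc) ** 2 / (2 * sig_vox[2] ** 2)
            )
        )
        data[f, z0:z1, y0:y1, x0:x1] += amp * g

    bleach = (1.0 - spec.bleach_rate) ** np.arange(t_dim)
    data = spec.background + (data - spec.background) * bleach[:, None, None, None]
    data = np.clip(data, None, spec.detector_max)  # detector full-scale clip
    if spec.noise_sd > 0:
        data = data + rng.normal(scale=spec.noise_sd, size=spec.dims)
    data = np.clip(data, 0.0, spec.detector_max)
    stack = ImageStack(data, spec.voxel_size_um, spec.frame_interval_s, bit_depth=16)
    truth = {"z_index": truth_z, "bleach_series": bleach, "spec": spec}
    return stack, truth


def _scatter_blob_tracks(
    rng: np.random.Generator,
    spec: MovieSpec,
    n_blobs: int,
    margin_um: float = 6.0,
) -> list[Track]:
    """Static 3D 'tracks' (one point per frame) scattered inside the field."""
    t_dim, z_dim, y_dim, x_dim = spec.dims
    vx, vy, vz = spec.voxel_size_um
    tracks = []
    for i in range(n_blobs):
        x = rng.uniform(margin_um, (x_dim - 1) * vx - margin_um)
        y = rng.uniform(margin_um, (y_dim - 1) * vy - margin_um)
        z = rng.uniform(2 * vz, (z_dim - 3) * vz)
        pts = [
            TrackPoint(f * spec.frame_interval_s, x, y, z) for f in range(t_dim)
        ]
        tracks.append(Track(track_id=f"blob{i}", points=pts, video_id="synthetic"))
    return tracks


def gen_quality_pair(seed: int = 0) -> tuple[ImageStack, ImageStack]:
    """A clean stack and the same content degraded with artifacts.

    The clean movie has many blobs of varied brightness (so the rendered
    histogram fills its dynamic range), no bleaching, drift or added noise;
    the artifacted copy injects photobleaching, field drift and Gaussian
    noise. Used for composite-quality ordering checks.
    """
    base = MovieSpec(dims=(15, 8, 72, 72), frame_interval_s=10.0, blob_sigma_um=2.5,
                     blob_amplitude=120.0, background=20.0, seed=seed)
    rng = np.random.default_rng(seed)
    tracks = _scatter_blob_tracks(rng, base, n_blobs=40)
    clean, _ = gen_movie(base, tracks)
    bad_spec = replace(base, bleach_rate=0.08, noise_sd=15.0,
                       drift_velocity_um=(3.0, 0.0))
    artifacted, _ = gen_movie(bad_spec, tracks)
    return clean, artifacted


def gen_zrecovery_movie(
    seed: int,
    snr: float = 5.0,
    dims: tuple[int, int, int, int] = (20, 15, 48, 48),
) -> tuple[ImageStack, Track, np.ndarray]:
    """One wandering blob in a noisy stack, for depth-recovery validation.

    The blob follows a 3D random walk whose z component steps across whole
    slices (depth annotations are per-slice, so the ground truth lives on
    slice centers and a perfect estimator reaches R² = 1); additive noise
    SD is ``blob_amplitude / snr``. Returns the stack, the 2D track
    (x, y, t as observed on the projection) and the true z in µm per point.
    """
    t_dim, z_dim, y_dim, x_dim = dims
    rng = np.random.default_rng(seed)
    spec = MovieSpec(
        dims=dims, frame_interval_s=10.0, blob_sigma_um=1.2,
        blob_amplitude=100.0, background=10.0,
        noise_sd=100.0 / snr, seed=seed,
    )
    # smooth 3D wander staying inside the field; z on integer slice indices
    x = np.empty(t_dim)
    y = np.empty(t_dim)
    z = np.empty(t_dim)
    x[0], y[0] = rng.uniform(10, x_dim - 10, 2)
    z[0] = float(rng.integers(4, z_dim - 4))
    for f in range(1, t_dim):
        x[f] = np.clip(x[f - 1] + rng.normal(0, 1.5), 6, x_dim - 7)
        y[f] = np.clip(y[f - 1] + rng.normal(0, 1.5), 6, y_dim - 7)
        z[f] = np.clip(z[f - 1] + round(rng.normal(0, 1.2)), 3, z_dim - 4)
    pts3d = [
        TrackPoint(f * spec.frame_interval_s, float(x[f]), float(y[f]), float(z[f]))
        for f in range(t_dim)
    ]
    track3d = Track(track_id=f"zblob{seed}", points=pts3d, video_id="synthetic")
    stack, _ = gen_movie(spec, [track3d])
    track2d = Track(
        track_id=track3d.track_id,
        points=[TrackPoint(p.t, p.x, p.y) for p in pts3d],
        video_id="synthetic",
    )
    true_z_um = z * spec.voxel_size_um[2]
    return stack, track2d, true_z_um
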