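"""Reading, writing, validating and reshaping cell tracks.

A :class:`Track` is the unit of all motility analysis: the time-ordered
sequence of one cell's centroid positions, in micrometres and seconds.
Three on-disk dialects are supported:

* ``native_csv`` — one row per point with columns
  ``track_id, video_id, cell_type, t_s, x_um, y_um[, z_um]``;
* ``trackmate_csv`` — the spots table exported by FIJI/TrackMate
  (``TRACK_ID``, ``POSITION_X/Y[/Z]`` and either ``POSITION_T`` in seconds
  or ``FRAME`` plus a frame interval);
* ``immunemap_json`` — an array of records carrying track metadata and a
  centroid list, with an explicit ``time_units`` field.

All loaders convert to µm / seconds on the way in, so downstream code never
sees pixels or frame indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrackPoint",
    "Track",
    "TrackValidationError",
    "read_tracks",
    "write_tracks",
    "resample_track",
    "filter_by_duration",
    "fragment_track",
    "subsample_track",
    "extract_tracklets",
]

DIALECTS_READ = ("native_csv", "trackmate_csv", "immunemap_json")
DIALECTS_WRITE = ("native_csv", "immunemap_json")

#: relative tolerance used when deciding whether sampling is uniform
_UNIFORM_RTOL = 1e-6


class TrackValidationError(ValueError):
    """A track violates its structural invariants."""


@dataclass(frozen=True)
class TrackPoint:
    """A single centroid: time in seconds, position in µm (z optional)."""

    t: float
    x: float
    y: float
    z: float | None = None


@dataclass
class Track:
    """An ordered, validated cell track.

    Parameters
    ----------
    track_id:
        Identifier unique within the collection it belongs to.
    points:
        Centroids sorted by time; timestamps must be strictly increasing,
        coordinates finite, and z present either for all points or none.
    video_id, cell_type:
        Free-text provenance labels.
    frame_interval_s:
        Native acquisition interval, if known (seconds).
    """

    track_id: str
    points: list[TrackPoint]
    video_id: str = ""
    cell_type: str = ""
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.points = [
            p if isinstance(p, TrackPoint) else TrackPoint(*p) for p in self.points
        ]
        _validate(self)

    # -- array views -------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        """Timestamps in seconds, shape (n,)."""
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def has_z(self) -> bool:
        return self.points[0].z is not None

    @property
    def ndim(self) -> int:
        return 3 if self.has_z else 2

    @property
    def positions(self) -> np.ndarray:
        """Positions in µm, shape (n, 2) or (n, 3)."""
        if self.has_z:
            return np.array([(p.x, p.y, p.z) for p in self.points], dtype=float)
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    # -- derived scalars ---------------------------------------------

    def __len__(self) -> int:
        return len(self.points)

    @property
    def duration_s(self) -> float:
        return self.points[-1].t - self.points[0].t

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1

    def sampling_interval(self) -> float | None:
        """The uniform Δt in seconds, or None if sampling is irregular."""
        if len(self.points) < 2:
            return None
        dts = np.diff(self.t)
        dt = dts[0]
        if dt <= 0:
            return None
        if np.allclose(dts, dt, rtol=_UNIFORM_RTOL, atol=_UNIFORM_RTOL * dt):
            return float(dt)
        return None

    @property
    def is_uniform(self) -> bool:
        return self.sampling_interval() is not None

    def replace_points(self, t, xyz, suffix: str = "") -> "Track":
        """New track with the same metadata and the given point arrays."""
        xyz = np.asarray(xyz, dtype=float)
        pts = [
            TrackPoint(float(ti), *(float(c) for c in row))
            for ti, row in zip(np.asarray(t, dtype=float), xyz)
        ]
        return Track(
            track_id=self.track_id + suffix,
            points=pts,
            video_id=self.video_id,
            cell_type=self.cell_type,
            frame_interval_s=self.frame_interval_s,
        )


def _validate(track: Track) -> None:
    if not track.points:
        raise TrackValidationError(f"track {track.track_id!r}: no points")
    zs = [p.z is None for p in track.points]
    if any(zs) and not all(zs):
        raise TrackValidationError(
            f"track {track.track_id!r}: z must be present for all points or none"
        )
    prev = -math.inf
    for p in track.points:
        vals = (p.t, p.x, p.y) if p.z is None else (p.t, p.x, p.y, p.z)
        if not all(math.isfinite(v) for v in vals):
            raise TrackValidationError(
                f"track {track.track_id!r}: non-finite value at t={p.t}"
            )
        if p.t <= prev:
            raise TrackValidationError(
                f"track {track.track_id!r}: timestamps not strictly increasing "
                f"at t={p.t}"
            )
        prev = p.t


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_tracks(
    path: str | Path,
    dialect: str,
    frame_interval_s: float | None = None,
) -> list[Track]:
    """Load tracks from *path*, converting units to µm / seconds.

    Parameters
    ----------
    dialect:
        One of ``native_csv``, ``trackmate_csv``, ``immunemap_json``.
    frame_interval_s:
        Required for TrackMate exports that carry only a ``FRAME`` column;
        timestamps are then ``frame * frame_interval_s``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native_csv":
        return _read_native_csv(path)
    if dialect == "trackmate_csv":
        return _read_trackmate_csv(path, frame_interval_s)
    if dialect == "immunemap_json":
        return _read_immunemap_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS_READ}")


def _build_tracks(df: pd.DataFrame, frame_interval_s: float | None = None) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        dup = grp["t_s"].duplicated()
        if dup.any():
            t_bad = grp.loc[dup, "t_s"].iloc[0]
            raise TrackValidationError(
                f"track {tid!r}: duplicate timestamp t={t_bad}"
            )
        has_z = "z_um" in grp.columns and grp["z_um"].notna().all()
        pts = [
            TrackPoint(
                float(r.t_s),
                float(r.x_um),
                float(r.y_um),
                float(r.z_um) if has_z else None,
            )
            for r in grp.itertuples()
        ]
        tracks.append(
            Track(
                track_id=str(tid),
                points=pts,
                video_id=str(grp["video_id"].iloc[0]) if "video_id" in grp else "",
                cell_type=str(grp["cell_type"].iloc[0]) if "cell_type" in grp else "",
                frame_interval_s=frame_interval_s,
            )
        )
    return tracks


def _read_native_csv(path: Path) -> list[Track]:
    df = pd.read_csv(path, dtype={"track_id": str, "video_id": str, "cell_type": str})
    required = {"track_id", "t_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing native CSV columns {sorted(missing)}")
    for col in ("t_s", "x_um", "y_um") + (("z_um",) if "z_um" in df.columns else ()):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "z_um" in df.columns and df["z_um"].isna().all():
        df = df.drop(columns=["z_um"])
    return _build_tracks(df)


def _read_trackmate_csv(path: Path, frame_interval_s: float | None) -> list[Track]:
    df = pd.read_csv(path)
    cols = {c.upper(): c for c in df.columns}
    if "TRACK_ID" not in cols or "POSITION_X" not in cols:
        raise ValueError(f"{path}: not a TrackMate spots export (TRACK_ID/POSITION_X missing)")
    # TrackMate CSVs often repeat human-readable header rows; drop non-numeric ones.
    num = pd.to_numeric(df[cols["POSITION_X"]], errors="coerce")
    df = df[num.notna()].copy()
    out = pd.DataFrame(
        {
            "track_id": df[cols["TRACK_ID"]].astype(str),
            "x_um": pd.to_numeric(df[cols["POSITION_X"]]),
            "y_um": pd.to_numeric(df[cols["POSITION_Y"]]),
        }
    )
    if "POSITION_Z" in cols:
        z = pd.to_numeric(df[cols["POSITION_Z"]], errors="coerce")
        if z.notna().all() and not (z == 0).all():
            out["z_um"] = z
    if "POSITION_T" in cols:
        out["t_s"] = pd.to_numeric(df[cols["POSITION_T"]])
    elif "FRAME" in cols:
        if frame_interval_s is None:
            raise ValueError(
                f"{path}: only FRAME present; pass frame_interval_s to convert to seconds"
            )
        out["t_s"] = pd.to_numeric(df[cols["FRAME"]]) * float(frame_interval_s)
    else:
        raise ValueError(f"{path}: neither POSITION_T nor FRAME column present")
    out["video_id"] = path.stem
    out["cell_type"] = ""
    return _build_tracks(out, frame_interval_s=frame_interval_s)


def _read_immunemap_json(path: Path) -> list[Track]:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a JSON array of track records")
    tracks = []
    for i, rec in enumerate(records):
        units = rec.get("time_units")
        if units not in ("s", "frames"):
            raise ValueError(
                f"{path}: record {i} has ambiguous time_units {units!r} "
                "(must be 's' or 'frames')"
            )
        dt = rec.get("frame_interval_s")
        if units == "frames":
            if not dt:
                raise ValueError(
                    f"{path}: record {i} uses frame units without frame_interval_s"
                )
            scale = float(dt)
        else:
            scale = 1.0
        pts = [
            TrackPoint(
                float(p["t"]) * scale,
                float(p["x"]),
                float(p["y"]),
                float(p["z"]) if p.get("z") is not None else None,
            )
            for p in rec["points"]
        ]
        tracks.append(
            Track(
                track_id=str(rec.get("track_id", i)),
                points=pts,
                video_id=str(rec.get("video_id", "")),
                cell_type=str(rec.get("cell_type", "")),
                frame_interval_s=float(dt) if dt else None,
            )
        )
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path, dialect: str = "native_csv") -> None:
    """Write *tracks* to *path*; round-trips through :func:`read_tracks`."""
    path = Path(path)
    tracks = list(tracks)
    if dialect == "native_csv":
        rows = []
        any_z = any(t.has_z for t in tracks)
        for tr in tracks:
            for p in tr.points:
                row = {
                    "track_id": tr.track_id,
                    "video_id": tr.video_id,
                    "cell_type": tr.cell_type,
                    "t_s": p.t,
                    "x_um": p.x,
                    "y_um": p.y,
                }
                if any_z:
                    row["z_um"] = p.z if p.z is not None else np.nan
                rows.append(row)
        cols = ["track_id", "video_id", "cell_type", "t_s", "x_um", "y_um"]
        if any_z:
            cols.append("z_um")
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    elif dialect == "immunemap_json":
        records = []
        for tr in tracks:
            rec = {
                "track_id": tr.track_id,
                "video_id": tr.video_id,
                "cell_type": tr.cell_type,
                "time_units": "s",
                "points": [
                    {"t": p.t, "x": p.x, "y": p.y, **({"z": p.z} if p.z is not None else {})}
                    for p in tr.points
                ],
            }
            if tr.frame_interval_s is not None:
                rec["frame_interval_s"] = tr.frame_interval_s
            records.append(rec)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS_WRITE}")


# ---------------------------------------------------------------------------
# reshaping operations
# ---------------------------------------------------------------------------


def resample_track(track: Track, dt: float = 10.0) -> Track:
    """Linearly interpolate *track* onto a uniform grid of step *dt* seconds.

    The grid is anchored at the track's first timestamp and never
    extrapolates past the last one.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.track_id!r}: cannot resample a single point")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = track.t
    n_out = int(math.floor((t[-1] - t[0]) / dt + _UNIFORM_RTOL)) + 1
    grid = t[0] + dt * np.arange(n_out)
    pos = track.positions
    out = np.column_stack([np.interp(grid, t, pos[:, a]) for a in range(pos.shape[1])])
    new = track.replace_points(grid, out)
    new.frame_interval_s = float(dt)
    return new


def filter_by_duration(tracks: Iterable[Track], min_duration_s: float = 500.0) -> list[Track]:
    """Keep tracks whose timestamp span is at least *min_duration_s* (inclusive)."""
    return [t for t in tracks if t.duration_s >= min_duration_s]


def fragment_track(track: Track, fragment_duration_s: float = 500.0) -> list[Track]:
    """Cut a track into consecutive fragments of fixed duration.

    Fragment ``k`` holds the points whose time offset from the first point
    falls in the half-open window ``[k*w, (k+1)*w)``; the trailing remainder
    (shorter than one window) is discarded, so the fragments partition the
    retained points. Fragment ids suffix the parent id with ``#k``.
    """
    if fragment_duration_s <= 0:
        raise ValueError("fragment_duration_s must be positive")
    w = fragment_duration_s
    rel = track.t - track.points[0].t
    n_frag = int(math.floor(track.duration_s / w + _UNIFORM_RTOL))
    frags = []
    pos = track.positions
    for k in range(n_frag):
        sel = (rel >= k * w - _UNIFORM_RTOL * w) & (rel < (k + 1) * w - _UNIFORM_RTOL * w)
        idx = np.nonzero(sel)[0]
        if idx.size == 0:
            continue
        frags.append(track.replace_points(track.t[idx], pos[idx], suffix=f"#{k}"))
    return frags


def subsample_track(track: Track, factor: int) -> Track:
    """Keep every *factor*-th point of a uniformly sampled track.

    Emulates acquiring the same cell at a coarser frame interval; the
    effective Δt is multiplied by *factor*.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    dt = track.sampling_interval()
    if dt is None:
        raise ValueError(
            f"track {track.track_id!r} is not uniformly sampled; "
            "resample_track() it first"
        )
    if factor == 1:
        return track
    idx = np.arange(0, len(track), factor)
    new = track.replace_points(track.t[idx], track.positions[idx])
    new.frame_interval_s = dt * factor
    return new


def extract_tracklets(track: Track, n_steps: int = 20, max_overlap: int = 15) -> list[Track]:
    """Extract equal-length sub-tracks ("tracklets") with bounded overlap.

    Each tracklet has exactly *n_steps* steps (``n_steps + 1`` points);
    successive start indices are spaced by ``n_steps - max_overlap``. An
    incomplete final window is dropped, equalizing durations so per-tracklet
    metrics are comparable across tracks of different lengths.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not (0 <= max_overlap < n_steps):
        raise ValueError("max_overlap must satisfy 0 <= max_overlap < n_steps")
    stride = n_steps - max_overlap
    out = []
    pos = track.positions
    for k, start in enumerate(range(0, len(track) - n_steps, stride)):
        idx = np.arange(start, start + n_steps + 1)
        out.append(track.replace_points(track.t[idx], pos[idx], suffix=f"~{k}"))
    return out
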