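"""Flat key-value run configuration shared by the CLI subcommands.

The on-disk format is deliberately plain text (``key = value`` lines,
``#`` comments) so a run's configuration diffs cleanly and can be mirrored
into output directories for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Every tunable of the toolkit, with its default.

    Units: thresholds/speeds in µm/min, durations/intervals in seconds,
    epsilon in µm², prune threshold in min-max-normalized embedding units.
    """

    arrest_threshold: float = 2.0          # µm/min
    min_duration_s: float = 500.0
    resample_dt_s: float = 10.0
    window_s: float = 50.0
    epsilon_um2: float = 1e-3
    umap_neighbors: int = 5
    umap_min_distance: float = 0.1
    k_clusters: int = 10
    dc_percentile: float = 2.0
    prune_threshold: float = 0.1
    saturate_fraction: float = 0.01
    psnr_full_marks_db: float = 50.0
    weight_cr: float = 1.0
    weight_nr: float = 1.0
    weight_pb: float = 1.0
    weight_sat: float = 1.0
    weight_sv: float = 1.0
    tracklet_steps: int = 20
    tracklet_max_overlap: int = 15
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.saturate_fraction < 1):
            raise ValueError("saturate_fraction must be in [0, 1)")
        if self.arrest_threshold < 0 or self.min_duration_s < 0:
            raise ValueError("thresholds must be non-negative")
        if self.resample_dt_s <= 0 or self.window_s <= 0 or self.epsilon_um2 <= 0:
            raise ValueError("dt, window and epsilon must be positive")
        if self.k_clusters < 1 or self.umap_neighbors < 1:
            raise ValueError("k_clusters and umap_neighbors must be >= 1")
        if not (0 <= self.tracklet_max_overlap < self.tracklet_steps):
            raise ValueError("tracklet overlap must be in [0, tracklet_steps)")

    def quality_weights(self) -> dict[str, float]:
        return {
            "CR": self.weight_cr, "NR": self.weight_nr, "PB": self.weight_pb,
            "SAT": self.weight_sat, "SV": self.weight_sv,
        }

    def dump(self, path: str | Path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Parse a key-value config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(RunConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = int if known[key] in ("int", int) else float
        values[key] = caster(val)
    values.update(overrides)
    return RunConfig(**values)
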