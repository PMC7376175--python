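"""Run configuration: every tunable of the pipeline in one serializable record.

Defaults reproduce the reference analysis protocol: 21 slices of 2 mm,
360 angular samples, 10 Fourier coefficients with DC retained, 95%
variance retention, stepwise entry/removal at 0.05/0.10. A copy of the
configuration is written next to every pipeline output (the run
manifest) so results are reproducible from (inputs, manifest, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    n_slices: int = 21
    thickness_mm: float = 2.0
    n_theta: int = 360
    n_coeff: int = 10
    include_dc: bool = True
    variance_threshold: float = 0.95
    p_enter: float = 0.05
    p_remove: float = 0.10
    entry_correction: str = "bonferroni"
    scaling_variant: str = "rss"
    spline_smoothing: float = 1.0
    min_segment_points: int = 1000
    min_slice_points: int = 30
    max_gap_deg: float = 15.0
    n_shape_candidates: int = 11
    n_radar: int = 5
    n_extreme_pcs: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def write_manifest(self, directory: str | Path, **extra) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"config": self.to_dict(), **extra}
        out = directory / "manifest.json"
        with open(out, "w") as fh:
            json.dump(manifest, fh, indent=1)
        return out
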