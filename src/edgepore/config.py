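"""Flat analysis configuration with explicit, serialisable defaults.

Every constant used by the analysis stages lives here; nothing is hidden in
analysis code.  The document round-trips losslessly through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    slab_thickness: float = 2.8  # nm
    slice_increment: float = 0.1  # nm
    contact_cutoff: float = 0.5  # nm, heavy-atom residue contacts
    shell_cutoff: float = 0.35  # nm, ion first hydration shell
    temperature: float = 300.0  # K
    stride: float = 100.0  # ps between retained samples
    discard: float = 500_000.0  # ps of initial equilibration removed
    density_bin: float = 0.1  # nm
    edge_lateral_cutoff: float = 1.0  # nm
    bulk_window: tuple[float, float] = (2.5, 3.5)  # nm, |z| interval
    pool_thresholds: tuple[float, float] = (0.3, 0.6)  # nm
    crossing_slab_halfwidth: float = 1.4  # nm
    crossing_bulk_margin: float = 0.4  # nm
    center_mode: str = "mass"  # bilayer-center weighting: mass | geometric
    seed: int = 0

    def __post_init__(self) -> None:
        self.bulk_window = tuple(self.bulk_window)  # type: ignore[assignment]
        self.pool_thresholds = tuple(self.pool_thresholds)  # type: ignore[assignment]
        for name in (
            "slab_thickness",
            "slice_increment",
            "contact_cutoff",
            "shell_cutoff",
            "temperature",
            "density_bin",
            "edge_lateral_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.pool_thresholds[0] < self.pool_thresholds[1]:
            raise ValueError("pool thresholds must be strictly increasing")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bulk_window"] = list(self.bulk_window)
        d["pool_thresholds"] = list(self.pool_thresholds)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
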