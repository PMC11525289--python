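"""Run configuration with the pipeline's operational defaults.

Defaults follow the published operating point of the method: 1.5 µm/pixel
acquisition scale, watershed tolerance 3, particle size window
[35, 2000) µm mFD, an 80% minimum mean recovery for the size-limit rule
and an operational resolution of 1 particle per subsample. Any value can
be overridden from a TOML file or CLI flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    pixel_size_um: float = 1.5
    exposure_gain: float = 1.5
    black_level: int = 30
    classifier: str = "forest"  # forest | rule
    n_trees: int = 100
    seed: int = 0
    watershed_tolerance: float = 3.0
    min_mfd_um: float = 35.0
    max_mfd_um: float = 2000.0
    recovery_thresholds_um: tuple[float, ...] = (
        10.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0,
    )
    min_recovery_pct: float = 80.0
    loess_span: float = 0.75
    operational_resolution: float = 1.0
    mass_density_g_cm3: float = 1.8
    mass_thickness_k: float = 0.4

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.classifier not in ("forest", "rule"):
            raise ValueError("classifier must be 'forest' or 'rule'")
        if not (0 <= self.min_mfd_um < self.max_mfd_um):
            raise ValueError("need 0 <= min_mfd_um < max_mfd_um")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "recovery_thresholds_um" in data:
            data["recovery_thresholds_um"] = tuple(data["recovery_thresholds_um"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recovery_thresholds_um"] = list(d["recovery_thresholds_um"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
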