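"""Analysis configuration with the documented defaults.

Every threshold the analysis depends on lives here so a run is fully
described by (inputs, config, seed). All lengths are um, angles
degrees.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    # core model
    coincidence_tol: float = 1.0        # mother-end/daughter-start gap tolerance
    default_wall_thickness: float = 15.0  # per side, for SWC without inner diameters
    # segment metrics
    order_scheme: str = "generation"    # or "trunk-following"
    diam_agg: str = "mean"              # or "median"
    direct_anchor: str = "midpoint"     # or "endpoint"
    # branching
    angle_chord: float = 100.0          # chord length for axis directions
    lateral_angle_threshold: float = 30.0
    lateral_asymmetry_threshold: float = 2.0
    murray_exponent: float = 3.0
    bootstrap_resamples: int = 1000
    # ring units
    unit_length: float = 50.0
    remainder_policy: str = "drop"      # or "keep"
    diam_bin_pitch: float = 50.0
    dist_bin_pitch: float = 1000.0
    normalize_to_n: int = 8
    # anomalies
    tortuosity_threshold: float = 8.0   # percent, strict >
    parallel_max_gap: float = 200.0
    parallel_max_angle: float = 15.0
    parallel_min_overlap: float = 250.0
    broken_angle_threshold: float = 60.0
    # statistics
    alpha: float = 0.05
    min_expected: float = 1.0           # sparse-bin pooling floor

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
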