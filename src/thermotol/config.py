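"""Analysis configuration shared by the DSC and T-F0 pipelines.

All tunables that the CLI exposes through ``--config <yaml>`` live here.
Defaults follow the measurement protocol: 0.1 K grid, a 10 K band for the
baseline line, a 3 K band for the steep-decline line starting the search at
29 °C, an exotherm search region above 50 °C, and peak/dip prominence at 5 %
of the curve's heat-flow range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # shared curve handling
    grid_step: float = 0.1           # K, uniform resampling step
    endo_up: bool = False            # negate heat flow on read (vendor convention)
    # DSC band fits
    band_width_first: float = 10.0   # K
    band_width_second: float = 3.0   # K
    band_start: float = 29.0         # °C, lower limit for the first-band search
    search_min_exo: float = 50.0     # °C, exotherm search region lower edge
    search_min_endo: float = 40.0    # °C, endotherm search floor when no exotherm
    prominence_frac: float = 0.05    # fraction of heat-flow range
    prominence_window: float = 10.0  # K, window for measuring prominence
                                     # against the surrounding signal (0 = whole curve)
    linearity_r2: float = 0.98       # heat-killed single-line criterion
    slope_tol: float = 1e-6          # mW g-1 K-1, near-parallel guard
    # T-F0 extraction
    tf0_baseline_band: float = 5.0   # K
    tf0_rise_band: float = 3.0       # K
    tf0_smooth_window: float = 0.0   # K, centered moving mean; 0 disables

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
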