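"""Run configuration: YAML-serializable parameters for a full analysis.

Analysis constants default to the values the method is defined with: 1-mm
cwv bins, bins valid from 6 points, cwv retained below 73 mm, wet days at
0.01 mm day⁻¹, and a 10⁻⁹ mm h⁻¹ epsilon in the quantile ratio.  The
default run simulates the 0–18°S, 65–50°W study box at 0.75° resolution
for two years — large enough (≈8.4 million cell-hours) for stable binned
quartiles while staying desk-scale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .grid import Grid, make_grid
from .synthetic import CwvProcess, FtParams, PickupLaw

__all__ = ["GridConfig", "AnalysisParams", "RunConfig"]


@dataclass
class GridConfig:
    south: float = -18.0
    north: float = 0.0
    west: float = -65.0
    east: float = -50.0
    resolution: float = 0.75

    def build(self) -> Grid:
        return make_grid(self.south, self.north, self.west, self.east, self.resolution)


@dataclass
class AnalysisParams:
    bin_width: float = 1.0  # mm
    min_count: int = 6
    max_cwv: float = 73.0  # mm
    wet_day_cutoff: float = 0.01  # mm day⁻¹
    ratio_eps: float = 1e-9  # mm h⁻¹
    quartiles: tuple[int, ...] = (25, 50, 75)

    def __post_init__(self) -> None:
        self.quartiles = tuple(int(q) for q in self.quartiles)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: grid, period, generator
    parameters, analysis constants, and the seed."""

    grid: GridConfig = field(default_factory=GridConfig)
    start: str = "2003-01-01"
    n_hours: int = 17544  # two years, 2003-2004
    cwv: CwvProcess = field(default_factory=CwvProcess)
    pickup: PickupLaw = field(default_factory=PickupLaw)
    ft: FtParams = field(default_factory=FtParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.grid, dict):
            self.grid = GridConfig(**self.grid)
        if isinstance(self.cwv, dict):
            self.cwv = CwvProcess(**self.cwv)
        if isinstance(self.pickup, dict):
            self.pickup = PickupLaw(**self.pickup)
        if isinstance(self.ft, dict):
            self.ft = FtParams(**self.ft)
        if isinstance(self.analysis, dict):
            self.analysis = AnalysisParams(**self.analysis)
        self.cwv.clip = tuple(float(c) for c in self.cwv.clip)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cwv"]["clip"] = list(self.cwv.clip)
        d["analysis"]["quartiles"] = list(self.analysis.quartiles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
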