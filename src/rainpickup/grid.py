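"""Regular latitude–longitude analysis grids.

Conventions: latitudes are negative southward and longitudes negative
westward, so a study box spanning 0–18°S and 65–50°W is
``make_grid(south=-18, north=0, west=-65, east=-50, resolution=0.25)``.
Cell centers sit half a cell inward from the box edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "make_grid"]


@dataclass(frozen=True)
class Grid:
    """A regular lat/lon grid over a bounding box.

    Cells are ordered row-major: latitude varies slowest (south to north),
    longitude fastest (west to east).
    """

    south: float
    north: float
    west: float
    east: float
    resolution: float

    @property
    def n_lat(self) -> int:
        return int(round((self.north - self.south) / self.resolution))

    @property
    def n_lon(self) -> int:
        return int(round((self.east - self.west) / self.resolution))

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lats(self) -> np.ndarray:
        """Cell-center latitudes, ascending (south to north)."""
        half = self.resolution / 2.0
        return self.south + half + self.resolution * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        """Cell-center longitudes, ascending (west to east)."""
        half = self.resolution / 2.0
        return self.west + half + self.resolution * np.arange(self.n_lon)

    def cell_centers(self) -> np.ndarray:
        """All (lat, lon) cell centers as an (n_cells, 2) array, row-major."""
        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        return np.column_stack([la.ravel(), lo.ravel()])


def _n_steps(extent: float, resolution: float, name: str) -> int:
    steps = extent / resolution
    if abs(steps - round(steps)) > 1e-9 * max(1.0, abs(steps)):
        raise ValueError(
            f"{name} extent of {extent}° is not divisible by the "
            f"resolution of {resolution}°"
        )
    return int(round(steps))


def make_grid(
    south: float, north: float, west: float, east: float, resolution: float
) -> Grid:
    """Construct a regular grid, validating box/resolution compatibility.

    Raises
    ------
    ValueError
        If the box is degenerate, the resolution is not positive, or either
        box dimension is not an integer multiple of the resolution (the
        error names the offending dimension).
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if north <= south:
        raise ValueError(f"north ({north}) must exceed south ({south})")
    if east <= west:
        raise ValueError(f"east ({east}) must exceed west ({west})")
    _n_steps(north - south, resolution, "latitude")
    _n_steps(east - west, resolution, "longitude")
    return Grid(south, north, west, east, resolution)
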