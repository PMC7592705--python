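"""Analysis grid: the common geographic pixel lattice all layers align to.

The master grid is a regular longitude/latitude raster anchored at its
top-left (north-west) corner, emulating the ~0.00025 deg (~30 m) grid of the
annual tree-cover-loss product. Coarser layers (the 300 m land-cover epochs)
use the same origin with a larger cell and must nest within — every fine
pixel center falls inside exactly one coarse cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AnalysisGrid"]


@dataclass(frozen=True)
class AnalysisGrid:
    """A regular geographic raster grid.

    Parameters
    ----------
    origin_lon, origin_lat : float
        Longitude/latitude of the **top-left corner** of the top-left pixel,
        in decimal degrees.
    cell_size : float
        Square cell edge in decimal degrees (> 0).
    n_rows, n_cols : int
        Grid dimensions; rows increase southward, columns eastward.
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}"
            )
        if not -90.0 <= self.origin_lat <= 90.0:
            raise ValueError(f"origin_lat out of range: {self.origin_lat}")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the grid footprint."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a single pixel center."""
        return (
            self.origin_lon + (col + 0.5) * self.cell_size,
            self.origin_lat - (row + 0.5) * self.cell_size,
        )

    def lat_edges(self) -> np.ndarray:
        """Latitudes of the n_rows + 1 horizontal cell edges, north to south."""
        return self.origin_lat - np.arange(self.n_rows + 1) * self.cell_size

    # -- relations to other grids ----------------------------------------

    def coarsen(self, factor: int) -> "AnalysisGrid":
        """A coarser grid with the same origin whose extent covers this one.

        Dimensions are rounded up, so the coarse grid may overhang south/east;
        the fine grid always nests within it.
        """
        if factor < 1:
            raise ValueError(f"coarsen factor must be >= 1, got {factor}")
        return AnalysisGrid(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size * factor,
            n_rows=math.ceil(self.n_rows / factor),
            n_cols=math.ceil(self.n_cols / factor),
        )

    def contains_grid(self, other: "AnalysisGrid") -> bool:
        """Whether ``other``'s footprint lies within this grid's footprint."""
        tol = 1e-9 * self.cell_size
        w, s, e, n = self.extent
        ow, os_, oe, on = other.extent
        return ow >= w - tol and os_ >= s - tol and oe <= e + tol and on <= n + tol

    def same_grid(self, other: "AnalysisGrid", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )
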