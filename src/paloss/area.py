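"""Geodesic pixel areas on the authalic sphere.

Areas are reported in hectares downstream ("Mha" at the reporting stage).
On a sphere of radius R, a grid cell bounded by meridians dLambda apart and
parallels at latitudes phi_t (north) and phi_b (south) has exact area

    A = R^2 * dLambda * (sin(phi_t) - sin(phi_b))

which depends on the row only. The default radius is the authalic Earth
radius, so a grid tiling the whole sphere sums exactly to 4*pi*R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import AnalysisGrid

__all__ = ["PixelAreaModel", "AUTHALIC_RADIUS_M"]

AUTHALIC_RADIUS_M = 6_371_007.181

M2_PER_HA = 10_000.0


@dataclass(frozen=True)
class PixelAreaModel:
    """Spherical-zone pixel area model.

    sphere_radius : meters; default is the authalic Earth radius, chosen so
    whole-sphere area is conserved exactly.
    """

    sphere_radius: float = AUTHALIC_RADIUS_M

    def pixel_area(self, row: int, grid: AnalysisGrid) -> float:
        """Exact spherical area (m^2) of one pixel in ``row`` (any column)."""
        if not 0 <= row < grid.n_rows:
            raise ValueError(f"row {row} outside grid with {grid.n_rows} rows")
        return float(self.row_areas(grid)[row])

    def row_areas(self, grid: AnalysisGrid) -> np.ndarray:
        """Per-row pixel area in m^2, shape (n_rows,). Strictly positive and
        decreasing toward the poles."""
        edges = np.deg2rad(grid.lat_edges())
        dlam = np.deg2rad(grid.cell_size)
        r2 = self.sphere_radius**2
        return r2 * dlam * (np.sin(edges[:-1]) - np.sin(edges[1:]))

    def row_areas_ha(self, grid: AnalysisGrid) -> np.ndarray:
        return self.row_areas(grid) / M2_PER_HA
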