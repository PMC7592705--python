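"""GeoTIFF raster I/O on the analysis grid.

Rasters are single-band GeoTIFFs georeferenced with the standard GeoTIFF
tags ModelPixelScaleTag (33550) and ModelTiepointTag (33922), tying raster
coordinate (0, 0) to the grid's top-left corner in geographic lon/lat.
Written with :mod:`tifffile`; no CRS keys are emitted (coordinates are
geographic degrees throughout the pipeline).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .grid import AnalysisGrid

__all__ = ["write_raster", "read_raster"]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


def write_raster(path: str | Path, array: np.ndarray, grid: AnalysisGrid) -> Path:
    """Write ``array`` as a georeferenced single-band GeoTIFF."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise ValueError(
            f"array shape {array.shape} does not match grid shape {grid.shape}"
        )
    path = Path(path)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
        ),
    ]
    tifffile.imwrite(path, array, extratags=extratags)
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, AnalysisGrid]:
    """Read a GeoTIFF written by :func:`write_raster`; returns (array, grid)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
    if abs(sx - sy) > 1e-12 * max(sx, sy):
        raise ValueError(f"{path}: non-square pixels ({sx} x {sy}) unsupported")
    # tie = (i, j, k, lon, lat, z) anchoring raster (i, j) to model space
    if tie[0] != 0.0 or tie[1] != 0.0:
        raise ValueError(f"{path}: tiepoint must anchor raster origin (0, 0)")
    grid = AnalysisGrid(
        origin_lon=float(tie[3]),
        origin_lat=float(tie[4]),
        cell_size=float(sx),
        n_rows=array.shape[0],
        n_cols=array.shape[1],
    )
    return array, grid
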