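"""Shared test helpers: run the pipeline tabulation from a scene bundle, and
compare two stratum tables for float-precision identity."""

import numpy as np

from paloss.overlay import assign_followup, build_forest_mask, resample_landcover
from paloss.pa import filter_pas, rasterize_pas
from paloss.raster_io import read_raster
from paloss.reclass import ReclassMap
from paloss.regions import RegionMap
from paloss.tabulate import FOREST_KEYS, LOSS_KEYS, SummaryTable, tabulate_loss
from paloss.vector_io import read_pa_layer


def run_tabulation(bundle, threshold=50.0) -> SummaryTable:
    """The pipeline's ingest/overlay/tabulate stages from a bundle's files."""
    canopy, grid = read_raster(bundle.canopy_raster_path)
    loss, _ = read_raster(bundle.loss_year_raster_path)
    records = filter_pas(read_pa_layer(bundle.pa_vector_path))
    pa_grid = rasterize_pas(records, grid)
    forest = build_forest_mask(canopy, threshold)
    m = ReclassMap.default()
    stack = {}
    for epoch, p in bundle.landcover_raster_paths.items():
        arr, cgrid = read_raster(p)
        stack[epoch] = resample_landcover(arr, cgrid, grid)
    followup = assign_followup(loss, stack, forest, m)
    return tabulate_loss(pa_grid, forest, loss, followup, RegionMap.default())


def assert_tables_equal(a: SummaryTable, b: SummaryTable) -> None:
    """Same strata, areas equal to float precision (1e-9 relative)."""
    for da, db, keys in (
        (a.loss, b.loss, LOSS_KEYS),
        (a.forest, b.forest, FOREST_KEYS),
    ):
        m = da.merge(db, on=keys, how="outer", suffixes=("_a", "_b"), indicator=True)
        assert (m["_merge"] == "both").all(), m[m["_merge"] != "both"]
        np.testing.assert_allclose(m["area_ha_a"], m["area_ha_b"], rtol=1e-9, atol=0)
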