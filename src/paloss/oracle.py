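"""Independent brute-force tabulation oracle.

Re-implements the whole screening procedure by literal per-pixel looping —
point-in-polygon per pixel center, inline strictness order, inline period
binning, inline establishment rule, inline containing-cell lookup into the
land-cover epochs, inline spherical-zone pixel area — sharing **no code
path** with the pipeline modules (only file reading via tifffile/json and
geometry predicates via shapely). Used as the equivalence oracle for the
pipeline's tabulation on desk-scale scenes; it is deliberately slow.
"""

from __future__ import annotations

import csv
import json
import math
from importlib import resources
from pathlib import Path

import pandas as pd
import tifffile
from shapely.geometry import Point, shape

__all__ = ["oracle_tabulate"]

_RANK = {
    "Ia": 1, "Ib": 2, "II": 3, "III": 4, "IV": 5, "V": 6, "VI": 7,
    "Not Applicable": 8, "Not Assigned": 8, "Not Reported": 8,
}
_PERIOD = [
    (2001, 2004, "P2001_2004", 2005),
    (2005, 2009, "P2005_2009", 2010),
    (2010, 2014, "P2010_2014", 2015),
    (2015, 2018, "P2015_2018", None),
]
_RADIUS_M = 6_371_007.181

_LOSS_COLS = [
    "pa_id", "iucn_category", "iso3", "region", "loss_year", "period",
    "followup_class", "area_ha",
]
_FOREST_COLS = ["pa_id", "iucn_category", "iso3", "region", "area_ha"]


def _read_tif(path):
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        scale = page.tags[33550].value
        tie = page.tags[33922].value
    return arr, float(tie[3]), float(tie[4]), float(scale[0])


def _read_reclass(path=None) -> dict[int, str]:
    if path is None:
        ref = resources.files("paloss.data").joinpath("reclass_esa_cci.csv")
        with resources.as_file(ref) as p:
            return _read_reclass(p)
    out = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if row and row[0] != "code" and not row[0].startswith("#"):
                out[int(row[0])] = row[1].strip()
    return out


def _read_regions(path=None) -> dict[str, str]:
    if path is None:
        ref = resources.files("paloss.data").joinpath("regions.csv")
        with resources.as_file(ref) as p:
            return _read_regions(p)
    out = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if row and row[0] != "iso3" and not row[0].startswith("#"):
                out[row[0].strip()] = row[1].strip()
    return out


def oracle_tabulate(bundle, reclass_path=None, region_path=None):
    """Tabulate a generated scene by direct per-pixel enumeration.

    Takes a ``SceneBundle`` (only its file paths and canopy threshold are
    used) and returns a ``SummaryTable`` with the same schema as the
    pipeline's ``tabulate_loss``. Missing layers are rejected.
    """
    from .tabulate import SummaryTable  # schema container only

    paths = [bundle.pa_vector_path, bundle.canopy_raster_path,
             bundle.loss_year_raster_path,
             *bundle.landcover_raster_paths.values()]
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"scene bundle incomplete, missing: {missing}")
    for epoch in (2005, 2010, 2015):
        if epoch not in bundle.landcover_raster_paths:
            raise FileNotFoundError(f"scene bundle missing land-cover epoch {epoch}")

    threshold = float(getattr(bundle, "canopy_threshold", 50.0))
    reclass = _read_reclass(reclass_path)
    regions = _read_regions(region_path)

    # -- vector layer: keep designated, non-marine, polygonal records ------
    with open(bundle.pa_vector_path, encoding="utf-8") as fh:
        doc = json.load(fh)
    pas = []
    for feat in doc["features"]:
        pr = feat["properties"]
        geom = shape(feat["geometry"])
        if pr["MARINE"] == 2:
            continue
        if pr["STATUS"] not in ("Designated", "Inscribed", "Established"):
            continue
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            continue
        year = pr["STATUS_YR"]
        pas.append(
            {
                "id": int(pr["WDPAID"]),
                "cat": pr["IUCN_CAT"],
                "iso3": pr["ISO3"],
                "est": 2000 if year in (None, "", 0) else int(year),
                "geom": geom,
            }
        )
    pas.sort(key=lambda p: (_RANK[p["cat"]], p["id"]))

    # -- rasters -----------------------------------------------------------
    canopy, lon0, lat0, cs = _read_tif(bundle.canopy_raster_path)
    loss, llon0, llat0, lcs = _read_tif(bundle.loss_year_raster_path)
    if (llon0, llat0, lcs) != (lon0, lat0, cs) or loss.shape != canopy.shape:
        raise ValueError("canopy and loss rasters are not on one grid")
    epochs = {}
    for epoch, p in bundle.landcover_raster_paths.items():
        epochs[epoch] = _read_tif(p)

    n_rows, n_cols = canopy.shape
    loss_acc: dict[tuple, float] = {}
    forest_acc: dict[tuple, float] = {}

    for i in range(n_rows):
        lat_c = lat0 - (i + 0.5) * cs
        phi_t = math.radians(lat0 - i * cs)
        phi_b = math.radians(lat0 - (i + 1) * cs)
        area_ha = (
            _RADIUS_M**2 * math.radians(cs) * (math.sin(phi_t) - math.sin(phi_b))
        ) / 1e4
        for j in range(n_cols):
            lon_c = lon0 + (j + 0.5) * cs
            if canopy[i, j] < threshold:
                continue
            pt = Point(lon_c, lat_c)
            winner = None
            for p in pas:  # sorted strictest-first: first hit wins
                if pt.within(p["geom"]):
                    winner = p
                    break
            if winner is None:
                key_f = (0, "none", "none", "none")
            else:
                key_f = (
                    winner["id"], winner["cat"], winner["iso3"],
                    regions[winner["iso3"]],
                )
            forest_acc[key_f] = forest_acc.get(key_f, 0.0) + area_ha

            k = int(loss[i, j])
            if k == 0:
                continue
            year = 2000 + k
            if winner is not None and not year > winner["est"]:
                continue
            period = followup = None
            for lo, hi, name, epoch in _PERIOD:
                if lo <= year <= hi:
                    period = name
                    if epoch is None:
                        followup = "unassigned"
                    else:
                        arr, elon0, elat0, ecs = epochs[epoch]
                        ci = int((elat0 - lat_c) // ecs)
                        cj = int((lon_c - elon0) // ecs)
                        followup = reclass[int(arr[ci, cj])]
                    break
            key_l = key_f + (year, period, followup)
            loss_acc[key_l] = loss_acc.get(key_l, 0.0) + area_ha

    loss_df = pd.DataFrame(
        [k + (v,) for k, v in sorted(loss_acc.items())],
        columns=_LOSS_COLS,
    )
    forest_df = pd.DataFrame(
        [k + (v,) for k, v in sorted(forest_acc.items())],
        columns=_FOREST_COLS,
    )
    return SummaryTable(loss=loss_df, forest=forest_df)
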