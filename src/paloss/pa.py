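"""Protected-area filtering and rasterization.

Implements the screening rules applied to the WDPA-style layer before any
raster work:

* drop fully marine records (MARINE = 2; coastal PAs keep their terrestrial
  forest and are retained),
* drop records that were proposed but never formally designated,
* drop records without polygonal geometry (point-only records),
* keep every IUCN category, including "Not Applicable" / "Not Assigned" /
  "Not Reported",
* records with a missing establishment year are treated as established
  before 2001.

Where PA polygons overlap, a pixel is attributed to the most stringent IUCN
category (Ia strictest ... VI, then the uncategorized labels, ties broken by
lower identifier), and the filtered layer is burnt onto the ~30 m analysis
grid by the pixel-center rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.validation import make_valid

from .grid import AnalysisGrid
from .vector_io import PARecord

__all__ = [
    "IUCN_CATEGORIES",
    "CATEGORY_CODES",
    "strictness_rank",
    "filter_pas",
    "rasterize_pas",
    "PAGrid",
]

#: All category labels accepted on input, strictest first.
IUCN_CATEGORIES = (
    "Ia",
    "Ib",
    "II",
    "III",
    "IV",
    "V",
    "VI",
    "Not Applicable",
    "Not Assigned",
    "Not Reported",
)

#: Stable integer code per category for the category raster (0 = unprotected).
CATEGORY_CODES = {cat: i + 1 for i, cat in enumerate(IUCN_CATEGORIES)}
CATEGORY_LABELS = {v: k for k, v in CATEGORY_CODES.items()}

# Ia..VI get ranks 1..7; the three uncategorized labels share the least
# strict rank (ties among them fall through to the pa_id tie-break).
_UNCATEGORIZED_RANK = 8
_RANKS = {cat: min(i + 1, _UNCATEGORIZED_RANK) for i, cat in enumerate(IUCN_CATEGORIES)}

#: Statuses that count as formally designated.
DESIGNATED_STATUSES = ("Designated", "Inscribed", "Established")


def strictness_rank(category: str) -> int:
    """Total strictness order over IUCN categories; smaller = stricter.

    Ia < Ib < II < III < IV < V < VI < {Not Applicable, Not Assigned,
    Not Reported} (the three uncategorized labels tie).
    """
    try:
        return _RANKS[category]
    except KeyError:
        raise ValueError(f"unknown IUCN category label: {category!r}") from None


def filter_pas(
    records: list[PARecord],
    keep_statuses: tuple[str, ...] = DESIGNATED_STATUSES,
    drop_marine_flag: int = 2,
) -> list[PARecord]:
    """Apply the screening filters; the result is idempotent under re-filtering.

    Coastal records (MARINE = 1) are retained by default — only fully marine
    records are dropped. All IUCN categories are retained (unknown labels are
    rejected, not silently dropped).
    """
    kept = []
    for r in records:
        strictness_rank(r.iucn_category)  # reject unknown labels loudly
        if r.marine_flag == drop_marine_flag:
            continue
        if r.status not in keep_statuses:
            continue
        if not r.is_polygonal:
            continue
        kept.append(r)
    return kept


@dataclass(frozen=True)
class PAGrid:
    """Rasterized protected-area layer.

    pa_id_raster : int32, winning PA id per pixel (0 = unprotected).
    category_raster : uint8 category code per pixel (0 = unprotected), the
        strictest category among PAs covering the pixel.
    attributes : pa_id -> PARecord for every rasterized record.
    """

    pa_id_raster: np.ndarray
    category_raster: np.ndarray
    grid: AnalysisGrid
    attributes: dict[int, PARecord]

    def establishment_years(self) -> dict[int, int]:
        return {
            pid: rec.effective_establishment_year
            for pid, rec in self.attributes.items()
        }

    def iso3_lookup(self) -> dict[int, str]:
        return {pid: rec.iso3 for pid, rec in self.attributes.items()}


def _repaired(rec: PARecord) -> PARecord:
    geom = rec.geometry
    if geom.is_valid:
        return rec
    fixed = make_valid(geom)
    if fixed.geom_type == "GeometryCollection":
        polys = [g for g in fixed.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        fixed = shapely.union_all(polys) if polys else None
    if fixed is None or fixed.is_empty or fixed.geom_type not in (
        "Polygon",
        "MultiPolygon",
    ):
        raise ValueError(f"PA {rec.pa_id}: invalid geometry could not be repaired")
    return rec.with_geometry(fixed)


def rasterize_pas(records: list[PARecord], grid: AnalysisGrid) -> PAGrid:
    """Burn filtered PA records onto ``grid`` with strictest-protection
    precedence.

    A pixel is covered by a PA iff its center point lies inside the polygon
    (pixel-center rule, not area-weighted). Among covering PAs, the strictest
    category wins; ties are broken by the lower pa_id. Invalid geometries are
    repaired when possible, otherwise rejected with the offending id.
    """
    for r in records:
        if not r.is_polygonal:
            raise ValueError(f"PA {r.pa_id}: non-polygonal geometry; filter first")
    records = [_repaired(r) for r in records]

    pa_id = np.zeros(grid.shape, dtype=np.int32)
    category = np.zeros(grid.shape, dtype=np.uint8)

    lon = grid.lon_centers()
    lat = grid.lat_centers()
    xx, yy = np.meshgrid(lon, lat)

    # Paint in strictness order, filling only still-unclaimed pixels: the
    # first record covering a pixel is the (strictest, lowest-id) winner.
    for rec in sorted(records, key=lambda r: (strictness_rank(r.iucn_category), r.pa_id)):
        free = pa_id == 0
        if not free.any():
            break
        inside = shapely.contains_xy(rec.geometry, xx[free], yy[free])
        if not inside.any():
            continue
        rows, cols = np.nonzero(free)
        rows, cols = rows[inside], cols[inside]
        pa_id[rows, cols] = rec.pa_id
        category[rows, cols] = CATEGORY_CODES[rec.iucn_category]

    return PAGrid(
        pa_id_raster=pa_id,
        category_raster=category,
        grid=grid,
        attributes={r.pa_id: r for r in records},
    )
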