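"""Protected-area vector layer I/O (GeoJSON with WDPA-style attributes).

Each feature carries the WDPA-style fields WDPAID, IUCN_CAT, STATUS,
STATUS_YR, MARINE, ISO3 (names configurable). Geometries are parsed with
shapely; points are preserved on read so the filtering stage can drop them
explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = ["PARecord", "FieldMap", "read_pa_layer", "write_pa_layer"]

#: Establishment year assumed for records with missing STATUS_YR: treated as
#: established before the first analysis year (2001).
PRE_ANALYSIS_YEAR = 2000


@dataclass(frozen=True)
class FieldMap:
    """Attribute-field names in the source layer (WDPA defaults)."""

    pa_id: str = "WDPAID"
    iucn_category: str = "IUCN_CAT"
    status: str = "STATUS"
    status_year: str = "STATUS_YR"
    marine_flag: str = "MARINE"
    iso3: str = "ISO3"


@dataclass(frozen=True)
class PARecord:
    """One protected-area record.

    marine_flag follows WDPA coding: 0 terrestrial, 1 coastal, 2 marine.
    status_year is None when the establishment year was not reported.
    """

    pa_id: int
    iucn_category: str
    status: str
    status_year: Optional[int]
    marine_flag: int
    iso3: str
    geometry: BaseGeometry

    @property
    def effective_establishment_year(self) -> int:
        """STATUS_YR, or a pre-2001 year when missing (loss in any analysis
        year is then counted)."""
        return self.status_year if self.status_year is not None else PRE_ANALYSIS_YEAR

    @property
    def is_polygonal(self) -> bool:
        return self.geometry.geom_type in ("Polygon", "MultiPolygon")

    def with_geometry(self, geom: BaseGeometry) -> "PARecord":
        return replace(self, geometry=geom)


def _require(props: dict, key: str, feature_idx: int):
    if key not in props:
        ident = props.get("WDPAID", f"feature #{feature_idx}")
        raise ValueError(f"PA record {ident}: missing required field '{key}'")
    return props[key]


def read_pa_layer(path: str | Path, fields: FieldMap = FieldMap()) -> list[PARecord]:
    """Read a GeoJSON FeatureCollection of PA records."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    records = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        year = _require(props, fields.status_year, i)
        records.append(
            PARecord(
                pa_id=int(_require(props, fields.pa_id, i)),
                iucn_category=str(_require(props, fields.iucn_category, i)),
                status=str(_require(props, fields.status, i)),
                status_year=None if year in (None, "", 0) else int(year),
                marine_flag=int(_require(props, fields.marine_flag, i)),
                iso3=str(_require(props, fields.iso3, i)),
                geometry=shape(feat["geometry"]),
            )
        )
    ids = [r.pa_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate pa_id values in {path}: {dupes}")
    return records


def write_pa_layer(
    path: str | Path, records: list[PARecord], fields: FieldMap = FieldMap()
) -> Path:
    path = Path(path)
    features = []
    for r in records:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    fields.pa_id: r.pa_id,
                    fields.iucn_category: r.iucn_category,
                    fields.status: r.status,
                    fields.status_year: r.status_year,
                    fields.marine_flag: r.marine_flag,
                    fields.iso3: r.iso3,
                    "GEOM_TYPE": r.geometry.geom_type,
                },
                "geometry": mapping(r.geometry),
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=None, separators=(",", ":"), sort_keys=True)
    return path
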