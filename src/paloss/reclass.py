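"""ESA-CCI legend reclassification to the seven follow-up classes.

The 300 m land-cover legend (22 classes plus regional sub-codes) is
consolidated to seven follow-up categories: forest, shrubland, grassland,
three agriculture-related classes kept separate (cropland; mosaic cropland,
>50% cropland mixed with natural vegetation; mosaic vegetation, <50%
cropland), and 'other' (urban, bare, water, snow/ice, sparse and flooded
non-woody cover). The default table ships with the package and any two-column
(code, class) CSV or YAML mapping can be substituted; maps are validated for
totality against the rasters they are applied to.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "FOLLOWUP_CLASSES",
    "UNASSIGNED",
    "FOLLOWUP_CODES",
    "ReclassMap",
]

#: The seven follow-up land-cover classes, in fixed reporting order.
FOLLOWUP_CLASSES = (
    "forest",
    "shrubland",
    "grassland",
    "cropland",
    "mosaic_cropland",
    "mosaic_vegetation",
    "other",
)

#: Label for loss in 2015-2018, after the latest (2015) land-cover epoch.
UNASSIGNED = "unassigned"

#: Integer codes used in follow-up rasters: 0 = no follow-up defined,
#: 1..7 = FOLLOWUP_CLASSES, 8 = unassigned (loss after the last epoch).
FOLLOWUP_CODES = {name: i + 1 for i, name in enumerate(FOLLOWUP_CLASSES)}
FOLLOWUP_CODES[UNASSIGNED] = len(FOLLOWUP_CLASSES) + 1
FOLLOWUP_LABELS = {v: k for k, v in FOLLOWUP_CODES.items()}


@dataclass(frozen=True)
class ReclassMap:
    """Validated legend-code -> follow-up-class mapping."""

    mapping: dict[int, str]

    def __post_init__(self) -> None:
        bad = sorted(
            (c, cls) for c, cls in self.mapping.items() if cls not in FOLLOWUP_CLASSES
        )
        if bad:
            raise ValueError(
                f"reclass map assigns classes outside {FOLLOWUP_CLASSES}: {bad}"
            )

    @classmethod
    def default(cls) -> "ReclassMap":
        ref = resources.files("paloss.data").joinpath("reclass_esa_cci.csv")
        with resources.as_file(ref) as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReclassMap":
        mapping: dict[int, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or row[0].startswith("#") or row[0] == "code":
                    continue
                if len(row) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns (code, class)")
                try:
                    code = int(row[0])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer legend code {row[0]!r}"
                    ) from None
                if code in mapping:
                    raise ValueError(f"{path}:{lineno}: duplicate code {code}")
                mapping[code] = row[1].strip()
        return cls(mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReclassMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls({int(k): str(v) for k, v in raw.items()})

    def __call__(self, code: int) -> str:
        """Class for one legend code; unmapped codes are rejected."""
        try:
            return self.mapping[int(code)]
        except KeyError:
            raise KeyError(f"legend code {code} is not in the reclass map") from None

    def apply(self, array: np.ndarray) -> np.ndarray:
        """Map a legend-code raster to follow-up codes 1..7 (uint8).

        Totality is enforced: any code present in ``array`` but absent from
        the map aborts with the offending codes listed.
        """
        codes = np.unique(array)
        missing = sorted(int(c) for c in codes if int(c) not in self.mapping)
        if missing:
            raise KeyError(f"legend codes not in the reclass map: {missing}")
        lut = np.zeros(int(codes.max()) + 1, dtype=np.uint8)
        for c in codes:
            lut[int(c)] = FOLLOWUP_CODES[self.mapping[int(c)]]
        return lut[array]
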