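"""Country (ISO3) to reporting-region assignment.

Seven reporting regions are used for regional shares of PA forest loss
(South and Central America, North America, Eastern Europe, Western Europe,
Africa and the Middle East, Southeast Asia, Rest of Asia and Oceania). The
membership table ships as an editable CSV; any iso3 -> region CSV may be
substituted. The map must be total over the iso3 codes present in the PA
layer being tabulated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["RegionMap"]

#: Region label attached to unprotected-area strata (no country attribution).
NO_REGION = "none"


@dataclass(frozen=True)
class RegionMap:
    mapping: dict[str, str]

    @classmethod
    def default(cls) -> "RegionMap":
        ref = resources.files("paloss.data").joinpath("regions.csv")
        with resources.as_file(ref) as p:
            return cls.from_csv(p)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegionMap":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or row[0].startswith("#") or row[0] == "iso3":
                    continue
                if len(row) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns (iso3, region)")
                if row[0] in mapping:
                    raise ValueError(f"{path}:{lineno}: duplicate iso3 {row[0]}")
                mapping[row[0].strip()] = row[1].strip()
        return cls(mapping)

    def __call__(self, iso3: str) -> str:
        if iso3 == NO_REGION:
            return NO_REGION
        try:
            return self.mapping[iso3]
        except KeyError:
            raise KeyError(f"iso3 code {iso3!r} has no region assignment") from None

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.mapping))
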