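"""Forest mask, loss-period binning, resampling, and follow-up assignment.

A pixel counts as forest when its year-2000 canopy cover is >= the threshold
(default 50%). Annual loss years 2001-2018 are binned into four periods:
2001-2004, 2005-2009 and 2010-2014, whose follow-up land cover is read from
the 2005, 2010 and 2015 land-cover epochs respectively, and 2015-2018, whose
loss is reported but carries no follow-up class because no later land-cover
epoch exists. Loss occurring in or before a PA's establishment year is
excluded from that PA's tally (strictly: counted iff loss_year >
establishment_year; a missing establishment year means established before
2001, so everything counts).

The 300 m land-cover epochs are brought onto the 30 m analysis grid by
nearest-neighbor (containing-cell) assignment, which is exact for nested
grids and introduces no new legend codes.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .grid import AnalysisGrid
from .reclass import FOLLOWUP_CODES, UNASSIGNED, ReclassMap

__all__ = [
    "PERIODS",
    "ANALYSIS_YEARS",
    "build_forest_mask",
    "establishment_filter",
    "loss_period",
    "resample_landcover",
    "assign_followup",
]

#: period name -> (first loss year, last loss year, follow-up epoch or None)
PERIODS = {
    "P2001_2004": (2001, 2004, 2005),
    "P2005_2009": (2005, 2009, 2010),
    "P2010_2014": (2010, 2014, 2015),
    "P2015_2018": (2015, 2018, None),
}

ANALYSIS_YEARS = (2001, 2018)

UNASSIGNED_CODE = FOLLOWUP_CODES[UNASSIGNED]


def build_forest_mask(canopy: np.ndarray, threshold: float = 50.0) -> np.ndarray:
    """Year-2000 forest mask: canopy percent >= threshold.

    The 50% default makes a pixel with exactly 50% canopy forest and one
    with 49% non-forest.
    """
    canopy = np.asarray(canopy)
    if canopy.size and (canopy.min() < 0 or canopy.max() > 100):
        raise ValueError(
            f"canopy percent outside [0, 100]: range "
            f"[{canopy.min()}, {canopy.max()}]"
        )
    if not 0 <= threshold <= 100:
        raise ValueError(f"canopy threshold outside [0, 100]: {threshold}")
    return canopy >= threshold


def establishment_filter(loss_year: int, establishment_year: Optional[int]) -> bool:
    """Whether a loss event counts against a PA established in a given year.

    Loss is tallied from the year after formal designation: counted iff
    loss_year > establishment_year. A missing year means the PA is assumed
    established before 2001, so every analysis-period loss counts.
    """
    if establishment_year is None:
        return True
    return loss_year > establishment_year


def loss_period(loss_year: int) -> tuple[str, Optional[int]]:
    """(period name, follow-up epoch) for a loss year; epoch is None for
    2015-2018 loss, which cannot be assigned a follow-up land cover."""
    for name, (lo, hi, epoch) in PERIODS.items():
        if lo <= loss_year <= hi:
            return name, epoch
    raise ValueError(
        f"loss year {loss_year} outside the analysis window "
        f"{ANALYSIS_YEARS[0]}-{ANALYSIS_YEARS[1]}"
    )


def resample_landcover(
    coarse: np.ndarray, coarse_grid: AnalysisGrid, target: AnalysisGrid
) -> np.ndarray:
    """Nearest-neighbor resampling of a categorical raster onto ``target``.

    Each fine pixel takes the code of the coarse cell containing its center;
    for exactly nested grids this reduces to block replication. Raises when
    any fine-pixel center falls outside the coarse footprint.
    """
    coarse = np.asarray(coarse)
    if coarse.shape != coarse_grid.shape:
        raise ValueError(
            f"coarse array shape {coarse.shape} != grid shape {coarse_grid.shape}"
        )
    cols = np.floor(
        (target.lon_centers() - coarse_grid.origin_lon) / coarse_grid.cell_size
    ).astype(np.int64)
    rows = np.floor(
        (coarse_grid.origin_lat - target.lat_centers()) / coarse_grid.cell_size
    ).astype(np.int64)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() >= coarse_grid.n_rows
        or cols.max() >= coarse_grid.n_cols
    ):
        raise ValueError("target grid extends outside the land-cover raster extent")
    return coarse[np.ix_(rows, cols)]


def assign_followup(
    loss_year_raster: np.ndarray,
    landcover_stack: Mapping[int, np.ndarray],
    forest_mask: np.ndarray,
    reclass: ReclassMap,
) -> np.ndarray:
    """Per-pixel follow-up class raster (uint8).

    ``loss_year_raster`` holds 0 for no loss and k for loss in year 2000+k.
    ``landcover_stack`` maps epoch year -> legend-code raster already on the
    analysis grid. Output codes: 0 where no follow-up is defined (no loss or
    outside the forest mask), 1..7 the follow-up classes, 8 unassigned
    (2015-2018 loss).
    """
    loss = np.asarray(loss_year_raster)
    forest = np.asarray(forest_mask, dtype=bool)
    if loss.shape != forest.shape:
        raise ValueError("loss raster and forest mask shapes differ")

    needed = {epoch for _, (_, _, epoch) in PERIODS.items() if epoch is not None}
    missing = sorted(needed - set(landcover_stack))
    if missing:
        raise ValueError(f"land-cover stack missing epoch(s): {missing}")

    out = np.zeros(loss.shape, dtype=np.uint8)
    eligible = forest & (loss > 0)
    for _, (lo, hi, epoch) in PERIODS.items():
        sel = eligible & (loss >= lo - 2000) & (loss <= hi - 2000)
        if not sel.any():
            continue
        if epoch is None:
            out[sel] = UNASSIGNED_CODE
        else:
            lc = np.asarray(landcover_stack[epoch])
            if lc.shape != loss.shape:
                raise ValueError(f"epoch {epoch} raster not on the analysis grid")
            out[sel] = reclass.apply(lc)[sel]
    return out
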