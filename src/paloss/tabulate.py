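"""Area-correct stratified tabulation of forest loss.

Converts the per-pixel layers into tidy stratum tables: loss area in
hectares cross-classified by PA, IUCN category, country, region, loss year,
period and follow-up class, together with year-2000 forest-area denominators
inside and outside PAs. Each counted loss pixel contributes its exact
spherical (geodesic) pixel area to exactly one row per stratification, so
sums are conserved across stratifications by construction.

Conventions: unprotected pixels carry ``pa_id = 0`` and the placeholder
label "none" for category, country and region; they appear in the tables so
global totals and global/PA comparisons can be formed, and are excluded from
PA-level reporting by filtering on ``pa_id > 0``. Establishment-year
filtering applies to loss numerators only, never to forest-area denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .area import PixelAreaModel
from .overlay import PERIODS
from .pa import CATEGORY_LABELS, PAGrid
from .reclass import FOLLOWUP_LABELS, UNASSIGNED
from .regions import NO_REGION, RegionMap

__all__ = [
    "SummaryTable",
    "tabulate_loss",
    "proportions",
    "followup_shares",
    "country_summary",
    "annual_series",
]

logger = logging.getLogger(__name__)

LOSS_KEYS = [
    "pa_id",
    "iucn_category",
    "iso3",
    "region",
    "loss_year",
    "period",
    "followup_class",
]
FOREST_KEYS = ["pa_id", "iucn_category", "iso3", "region"]

HA_PER_MHA = 1e6


@dataclass(frozen=True)
class SummaryTable:
    """Stratified loss areas and year-2000 forest denominators (hectares).

    loss : one row per occupied (pa_id, iucn_category, iso3, region,
        loss_year, period, followup_class) stratum with its area_ha.
    forest : one row per occupied (pa_id, iucn_category, iso3, region)
        stratum with its year-2000 forest area_ha.
    """

    loss: pd.DataFrame
    forest: pd.DataFrame

    def loss_area_ha(self, pa_only: bool = True) -> float:
        df = self.loss
        if pa_only:
            df = df[df["pa_id"] > 0]
        return float(df["area_ha"].sum())

    def forest_area_ha(self, pa_only: bool = True) -> float:
        df = self.forest
        if pa_only:
            df = df[df["pa_id"] > 0]
        return float(df["area_ha"].sum())

    def by(self, keys: list[str], pa_only: bool = True) -> pd.DataFrame:
        """Loss area summed over ``keys`` (PA strata only by default)."""
        df = self.loss
        if pa_only:
            df = df[df["pa_id"] > 0]
        return df.groupby(keys, sort=True)["area_ha"].sum().reset_index()


def _label_arrays(pa_ids: np.ndarray, cat_codes: np.ndarray, pa_grid: PAGrid,
                  region_map: RegionMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iso_lookup = pa_grid.iso3_lookup()
    cats = np.array(["none"] + [CATEGORY_LABELS[c] for c in range(1, 11)], dtype=object)
    cat = cats[cat_codes]
    iso = np.array(
        ["none" if p == 0 else iso_lookup[int(p)] for p in pa_ids], dtype=object
    )
    reg = np.array([NO_REGION if i == "none" else region_map(i) for i in iso],
                   dtype=object)
    return cat, iso, reg


def tabulate_loss(
    pa_grid: PAGrid,
    forest_mask: np.ndarray,
    loss_year_raster: np.ndarray,
    followup_raster: np.ndarray,
    region_map: RegionMap,
    establishment: dict[int, int] | None = None,
    model: PixelAreaModel = PixelAreaModel(),
) -> SummaryTable:
    """One pass over the aligned pixel layers, producing the stratum tables.

    ``loss_year_raster`` holds 0 / k (= loss in year 2000+k); loss recorded
    outside the forest mask is ignored entirely. A PA pixel's loss is counted
    only when the loss year is strictly after the winning PA's establishment
    year; unprotected loss is always counted.
    """
    grid = pa_grid.grid
    shapes = {
        "pa_id_raster": pa_grid.pa_id_raster.shape,
        "forest_mask": np.asarray(forest_mask).shape,
        "loss_year_raster": np.asarray(loss_year_raster).shape,
        "followup_raster": np.asarray(followup_raster).shape,
    }
    bad = {k: s for k, s in shapes.items() if s != grid.shape}
    if bad:
        raise ValueError(f"layers not aligned to the analysis grid {grid.shape}: {bad}")

    if establishment is None:
        establishment = pa_grid.establishment_years()
    forest = np.asarray(forest_mask, dtype=bool)
    loss = np.asarray(loss_year_raster)
    fup = np.asarray(followup_raster)
    area_ha = model.row_areas_ha(grid)

    # ---- forest-area denominators (year 2000; no establishment filter) ----
    frows, fcols = np.nonzero(forest)
    fdf = pd.DataFrame(
        {
            "pa_id": pa_grid.pa_id_raster[frows, fcols].astype(np.int64),
            "area_ha": area_ha[frows],
        }
    )
    cat, iso, reg = _label_arrays(
        fdf["pa_id"].to_numpy(), pa_grid.category_raster[frows, fcols], pa_grid,
        region_map,
    )
    fdf["iucn_category"], fdf["iso3"], fdf["region"] = cat, iso, reg
    forest_table = (
        fdf.groupby(FOREST_KEYS, sort=True)["area_ha"].sum().reset_index()
    )

    # ---- counted loss pixels ----
    sel = forest & (loss > 0)
    rows, cols = np.nonzero(sel)
    pa_ids = pa_grid.pa_id_raster[rows, cols].astype(np.int64)
    years = loss[rows, cols].astype(np.int64) + 2000
    max_id = int(pa_ids.max(initial=0))
    est_lut = np.full(max_id + 1, -(10**6), dtype=np.int64)
    for pid, yr in establishment.items():
        if pid <= max_id:
            est_lut[pid] = yr
    counted = (pa_ids == 0) | (years > est_lut[pa_ids])
    rows, cols = rows[counted], cols[counted]
    pa_ids, years = pa_ids[counted], years[counted]

    period_lut = np.empty(19, dtype=object)
    for name, (lo, hi, _) in PERIODS.items():
        period_lut[lo - 2000 : hi - 2000 + 1] = name
    fup_codes = fup[rows, cols]
    if (fup_codes == 0).any():
        raise ValueError("counted loss pixel without a follow-up assignment")
    fup_labels = np.array(
        [FOLLOWUP_LABELS[c] for c in range(1, 9)], dtype=object
    )[fup_codes - 1]

    cat, iso, reg = _label_arrays(
        pa_ids, pa_grid.category_raster[rows, cols], pa_grid, region_map
    )
    ldf = pd.DataFrame(
        {
            "pa_id": pa_ids,
            "iucn_category": cat,
            "iso3": iso,
            "region": reg,
            "loss_year": years,
            "period": period_lut[years - 2000],
            "followup_class": fup_labels,
            "area_ha": area_ha[rows],
        }
    )
    loss_table = ldf.groupby(LOSS_KEYS, sort=True)["area_ha"].sum().reset_index()
    return SummaryTable(loss=loss_table, forest=forest_table)


def proportions(numerator, denominator, decimals: int = 1):
    """Percentages 100 * numerator / denominator.

    Scalars give a scalar; aligned pandas Series give a Series. Strata with a
    non-positive denominator are omitted from the output (and logged), never
    emitted as NaN. Rounding to ``decimals`` happens only here, at reporting.
    """
    if np.isscalar(numerator) and np.isscalar(denominator):
        if denominator <= 0:
            raise ValueError("proportion requested with non-positive denominator")
        return round(100.0 * numerator / denominator, decimals)
    num, den = pd.Series(numerator), pd.Series(denominator)
    num, den = num.align(den, join="outer", fill_value=0.0)
    ok = den > 0
    if (~ok).any():
        logger.warning(
            "omitting %d stratum rows with zero denominator: %s",
            (~ok).sum(),
            list(den.index[~ok]),
        )
    return (100.0 * num[ok] / den[ok]).round(decimals)


def followup_shares(
    table: SummaryTable, pa_only: bool = True, include_unassigned: bool = False
) -> pd.Series:
    """Fraction of counted loss area followed by each land-cover class.

    By default restricted to PA loss with an assigned follow-up (2001-2014
    loss), the quantity behind the global follow-up mix.
    """
    df = table.loss
    if pa_only:
        df = df[df["pa_id"] > 0]
    if not include_unassigned:
        df = df[df["followup_class"] != UNASSIGNED]
    shares = df.groupby("followup_class", sort=True)["area_ha"].sum()
    total = shares.sum()
    if total <= 0:
        return shares * 0.0
    return shares / total


def country_summary(table: SummaryTable, min_pa_forest_ha: float = 1000.0) -> pd.DataFrame:
    """Per-country PA forest, PA loss and percent lost.

    Countries with less than ``min_pa_forest_ha`` (strictly less; default
    1000 ha) of PA forest are omitted from country-level reporting; they
    still contribute to regional and global totals elsewhere.
    """
    forest = (
        table.forest[table.forest["pa_id"] > 0]
        .groupby("iso3", sort=True)["area_ha"]
        .sum()
    )
    loss = (
        table.loss[table.loss["pa_id"] > 0].groupby("iso3", sort=True)["area_ha"].sum()
    )
    out = pd.DataFrame({"pa_forest_ha": forest}).fillna(0.0)
    out["pa_loss_ha"] = loss.reindex(out.index).fillna(0.0)
    out = out[out["pa_forest_ha"] >= min_pa_forest_ha]
    out["pct_lost"] = proportions(out["pa_loss_ha"], out["pa_forest_ha"])
    return out.reset_index()


def annual_series(
    table: SummaryTable, pa_only: bool = True, years: tuple[int, int] = (2001, 2018)
) -> pd.DataFrame:
    """Per-year loss area, percent of year-2000 forest, and cumulative area.

    Years with zero loss appear as explicit 0 rows; the cumulative column is
    monotone non-decreasing and its last entry equals the total loss area.
    """
    df = table.loss
    if pa_only:
        df = df[df["pa_id"] > 0]
    per_year = df.groupby("loss_year", sort=True)["area_ha"].sum()
    idx = pd.RangeIndex(years[0], years[1] + 1, name="loss_year")
    per_year = per_year.reindex(idx, fill_value=0.0)
    denom = table.forest_area_ha(pa_only=pa_only)
    out = per_year.reset_index().rename(columns={"area_ha": "loss_ha"})
    out["pct_of_forest"] = (
        100.0 * out["loss_ha"] / denom if denom > 0 else np.zeros(len(out))
    )
    out["cumulative_ha"] = out["loss_ha"].cumsum()
    return out
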