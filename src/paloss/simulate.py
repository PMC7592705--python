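"""Synthetic landscape generator with known per-pixel ground truth.

Emulates the three input layers of the screening analysis — a WDPA-style
protected-area polygon layer, a year-2000 percent-canopy raster plus an
annual loss-year raster on the fine (~30 m analog) grid, and land-cover
epoch rasters for 2005/2010/2015 on a coarser (300 m analog) grid — with a
known generative process, so the whole pipeline can be verified at desk
scale against exact truth tables.

The stated world: protected pixels lose forest at a lower annual rate than
unprotected pixels (defaults calibrated to the reported 18-year loss
fractions of 4.1% inside and 12.2% outside protection), and the land cover
following loss is drawn from a categorical distribution whose default is the
reported global follow-up mix (shrubland 0.47, cropland 0.22,
mosaic vegetation 0.14, grassland 0.06, other 0.11). Follow-up classes are
drawn once per coarse land-cover cell and epoch, mirroring the 300 m / 30 m
resolution mismatch of the real products; loss in 2015-2018 has no
follow-up epoch and is truth-labelled "unassigned".

PA polygons are random axis-aligned rectangles (guaranteed valid geometry);
overlaps are created by centering a new rectangle inside an existing one.
Configured fractions of records are made fully marine, proposed-only,
point-only, or missing their establishment year, to exercise the screening
filters. No attempt is made to emulate spatial autocorrelation of
deforestation fronts; noise is class-conditional only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, box

from .area import PixelAreaModel
from .grid import AnalysisGrid
from .overlay import PERIODS
from .pa import IUCN_CATEGORIES, strictness_rank
from .raster_io import write_raster
from .reclass import FOLLOWUP_CLASSES, UNASSIGNED
from .regions import RegionMap
from .tabulate import FOREST_KEYS, LOSS_KEYS, SummaryTable
from .vector_io import PARecord, write_pa_layer

__all__ = ["LandscapeConfig", "SceneBundle", "generate_scene"]

#: Default follow-up mix: the reported global proportions of land cover
#: following protected forest loss (agriculture bucket carried by cropland).
DEFAULT_FOLLOWUP = {
    "forest": 0.0,
    "shrubland": 0.47,
    "grassland": 0.06,
    "cropland": 0.22,
    "mosaic_cropland": 0.0,
    "mosaic_vegetation": 0.14,
    "other": 0.11,
}

#: Representative legend code emitted for each drawn follow-up class.
CLASS_TO_CODE = {
    "forest": 50,
    "shrubland": 120,
    "grassland": 130,
    "cropland": 10,
    "mosaic_cropland": 30,
    "mosaic_vegetation": 40,
    "other": 190,
}

# Static background land cover (cells without loss), spanning the legend.
_BG_CODES = np.array(
    [50, 60, 71, 90, 100, 110, 120, 130, 10, 11, 30, 40, 150, 180, 190, 210]
)
_BG_PROBS = np.array(
    [0.20, 0.10, 0.05, 0.05, 0.07, 0.05, 0.08, 0.10, 0.06, 0.02, 0.04, 0.05,
     0.03, 0.04, 0.03, 0.03]
)

_COUNTRIES = (
    "BRA", "IDN", "COD", "USA", "CAN", "RUS", "AUS", "DEU", "GHA", "PER",
    "MMR", "UKR",
)

_N_YEARS = 18  # loss years 2001..2018 encoded 1..18


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"LandscapeConfig.{fieldname}: {msg}")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the stated synthetic world (all rates per the defaults
    described in the module docstring)."""

    grid_rows: int = 128
    grid_cols: int = 128
    origin_lon: float = -55.0
    origin_lat: float = -5.0
    cell_size: float = 0.00025
    seed: int = 0
    n_pas: int = 5
    p_overlap: float = 0.3
    frac_marine: float = 0.1
    frac_proposed: float = 0.1
    frac_point: float = 0.05
    frac_missing_year: float = 0.1
    canopy_mean: float = 70.0
    canopy_sd: float = 25.0
    #: Annual per-pixel loss probabilities; defaults solve
    #: 1-(1-p)^18 = 0.041 (inside) and 0.122 (outside).
    loss_rate_inside: float = 0.00233
    loss_rate_outside: float = 0.00720
    followup_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FOLLOWUP)
    )
    establishment_year_range: tuple[int, int] = (1990, 2015)
    coarse_factor: int = 12

    def __post_init__(self) -> None:
        _check(self.grid_rows >= 8 and self.grid_cols >= 8, "grid_rows",
               f"grid dimensions must be >= 8, got {self.grid_rows}x{self.grid_cols}")
        _check(self.cell_size > 0, "cell_size", f"must be > 0, got {self.cell_size}")
        _check(self.n_pas >= 0, "n_pas", f"must be >= 0, got {self.n_pas}")
        for name in ("p_overlap", "frac_marine", "frac_proposed", "frac_point",
                     "frac_missing_year", "loss_rate_inside", "loss_rate_outside"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"probability outside [0, 1]: {v}")
        _check(
            self.frac_marine + self.frac_proposed + self.frac_point <= 1.0 + 1e-12,
            "frac_marine",
            "frac_marine + frac_proposed + frac_point must not exceed 1",
        )
        _check(0.0 <= self.canopy_mean <= 100.0, "canopy_mean",
               f"percent outside [0, 100]: {self.canopy_mean}")
        _check(self.canopy_sd >= 0.0, "canopy_sd", "must be >= 0")
        dist = self.followup_distribution
        unknown = sorted(set(dist) - set(FOLLOWUP_CLASSES))
        _check(not unknown, "followup_distribution", f"unknown classes {unknown}")
        _check(all(p >= 0 for p in dist.values()), "followup_distribution",
               "negative probability")
        _check(abs(sum(dist.values()) - 1.0) <= 1e-9, "followup_distribution",
               f"probabilities sum to {sum(dist.values())}, not 1")
        y0, y1 = self.establishment_year_range
        _check(y0 <= y1, "establishment_year_range", f"empty range {y0}..{y1}")
        _check(self.coarse_factor >= 1, "coarse_factor", "must be >= 1")

    @property
    def grid(self) -> AnalysisGrid:
        return AnalysisGrid(
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
            n_rows=self.grid_rows,
            n_cols=self.grid_cols,
        )


@dataclass(frozen=True)
class SceneBundle:
    """A generated landscape: file paths plus exact truth tables."""

    out_dir: Path
    pa_vector_path: Path
    canopy_raster_path: Path
    loss_year_raster_path: Path
    landcover_raster_paths: dict[int, Path]
    truth_pixel_table: pd.DataFrame
    truth_summary: SummaryTable
    config: LandscapeConfig
    canopy_threshold: float = 50.0


def _make_records(cfg: LandscapeConfig, rng: np.random.Generator) -> list[PARecord]:
    w, s, e, n = cfg.grid.extent
    ext_w, ext_h = e - w, n - s
    rects: list[tuple[float, float, float, float]] = []
    records: list[PARecord] = []
    for i in range(cfg.n_pas):
        pw = rng.uniform(0.10, 0.35) * ext_w
        ph = rng.uniform(0.10, 0.35) * ext_h
        if rects and rng.random() < cfg.p_overlap:
            bx0, by0, bx1, by1 = rects[rng.integers(len(rects))]
            cx = rng.uniform(bx0, bx1)
            cy = rng.uniform(by0, by1)
        else:
            cx = rng.uniform(w, e)
            cy = rng.uniform(s, n)
        x0, x1 = max(w, cx - pw / 2), min(e, cx + pw / 2)
        y0, y1 = max(s, cy - ph / 2), min(n, cy + ph / 2)
        if x1 - x0 < cfg.cell_size or y1 - y0 < cfg.cell_size:
            # clipped to a sliver at the grid edge: re-center inside the extent
            cx = min(max(cx, w + pw / 2), e - pw / 2)
            cy = min(max(cy, s + ph / 2), n - ph / 2)
            x0, x1 = cx - pw / 2, cx + pw / 2
            y0, y1 = cy - ph / 2, cy + ph / 2

        u = rng.random()
        kind = "ok"
        if u < cfg.frac_marine:
            kind = "marine"
        elif u < cfg.frac_marine + cfg.frac_proposed:
            kind = "proposed"
        elif u < cfg.frac_marine + cfg.frac_proposed + cfg.frac_point:
            kind = "point"

        category = IUCN_CATEGORIES[rng.integers(len(IUCN_CATEGORIES))]
        year: Optional[int]
        if rng.random() < cfg.frac_missing_year:
            year = None
        else:
            y0r, y1r = cfg.establishment_year_range
            year = int(rng.integers(y0r, y1r + 1))
        iso3 = _COUNTRIES[rng.integers(len(_COUNTRIES))]
        marine_flag = 2 if kind == "marine" else (1 if rng.random() < 0.1 else 0)
        status = "Proposed" if kind == "proposed" else "Designated"
        geometry = Point(cx, cy) if kind == "point" else box(x0, y0, x1, y1)
        if kind != "point":
            rects.append((x0, y0, x1, y1))
        records.append(
            PARecord(
                pa_id=i + 1,
                iucn_category=category,
                status=status,
                status_year=year,
                marine_flag=marine_flag,
                iso3=iso3,
                geometry=geometry,
            )
        )
    return records


def _valid(rec: PARecord) -> bool:
    """A record that survives the screening filters (generator's view)."""
    return rec.marine_flag != 2 and rec.status == "Designated" and rec.is_polygonal


def _winner_rasters(
    records: list[PARecord], grid: AnalysisGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Winning pa_id per pixel (strictest category, then lowest id) and the
    count of valid polygons covering each pixel center."""
    pa = np.zeros(grid.shape, dtype=np.int32)
    ncov = np.zeros(grid.shape, dtype=np.int16)
    xx, yy = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    valid = [r for r in records if _valid(r)]
    for rec in valid:
        ncov += shapely.contains_xy(rec.geometry, xx, yy).astype(np.int16)
    for rec in sorted(valid, key=lambda r: (strictness_rank(r.iucn_category), r.pa_id)):
        free = pa == 0
        inside = shapely.contains_xy(rec.geometry, xx[free], yy[free])
        rows, cols = np.nonzero(free)
        pa[rows[inside], cols[inside]] = rec.pa_id
    return pa, ncov


def _draw_loss_years(
    cfg: LandscapeConfig, inside: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Loss-year raster (0 none, k = year 2000+k): per pixel, first success
    of independent annual Bernoulli trials at the inside/outside rate."""
    p = np.where(inside, cfg.loss_rate_inside, cfg.loss_rate_outside)
    u = rng.random((_N_YEARS,) + inside.shape)
    hits = u < p[None, :, :]
    any_hit = hits.any(axis=0)
    first = hits.argmax(axis=0).astype(np.uint8) + 1
    return np.where(any_hit, first, 0).astype(np.uint8)


def generate_scene(cfg: LandscapeConfig, out_dir: str | Path) -> SceneBundle:
    """Generate a scene, write its layers and truth tables under ``out_dir``.

    Deterministic for a fixed config (one seed stream split into per-layer
    substreams, so adding a layer does not perturb the others).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = cfg.grid
    ss = np.random.SeedSequence(cfg.seed)
    pa_rng, canopy_rng, loss_rng, lc_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- vector layer -----------------------------------------------------
    records = _make_records(cfg, pa_rng)
    pa_path = write_pa_layer(out_dir / "pa.geojson", records)
    pa_raster, ncov = _winner_rasters(records, grid)

    # --- canopy and loss --------------------------------------------------
    canopy = np.clip(
        np.rint(canopy_rng.normal(cfg.canopy_mean, cfg.canopy_sd, grid.shape)),
        0, 100,
    ).astype(np.uint8)
    forest = canopy >= 50
    loss = _draw_loss_years(cfg, pa_raster > 0, loss_rng)
    canopy_path = write_raster(out_dir / "canopy2000.tif", canopy, grid)
    loss_path = write_raster(out_dir / "lossyear.tif", loss, grid)

    # --- land-cover epochs (coarse grid) ----------------------------------
    coarse = grid.coarsen(cfg.coarse_factor)
    bg = _BG_CODES[
        lc_rng.choice(len(_BG_CODES), size=coarse.shape, p=_BG_PROBS)
    ].astype(np.uint8)
    fu_classes = np.array(FOLLOWUP_CLASSES, dtype=object)
    fu_probs = np.array([cfg.followup_distribution.get(c, 0.0) for c in FOLLOWUP_CLASSES])
    rr, cc = np.nonzero(forest & (loss > 0))
    years = loss[rr, cc].astype(int) + 2000
    cell_r, cell_c = rr // cfg.coarse_factor, cc // cfg.coarse_factor

    lc_paths: dict[int, Path] = {}
    drawn: dict[tuple[int, int, int], str] = {}  # (epoch, cell_r, cell_c) -> class
    for name in ("P2001_2004", "P2005_2009", "P2010_2014"):
        lo, hi, epoch = PERIODS[name]
        arr = bg.copy()
        in_period = (years >= lo) & (years <= hi)
        cells = sorted(set(zip(cell_r[in_period].tolist(), cell_c[in_period].tolist())))
        for r, c in cells:
            cls = fu_classes[lc_rng.choice(len(fu_classes), p=fu_probs)]
            drawn[(epoch, r, c)] = cls
            arr[r, c] = CLASS_TO_CODE[cls]
        lc_paths[epoch] = write_raster(out_dir / f"landcover{epoch}.tif", arr, coarse)

    # --- truth pixel table ------------------------------------------------
    region_map = RegionMap.default()
    attrs = {r.pa_id: r for r in records if _valid(r)}
    n = grid.n_rows * grid.n_cols
    rows_all, cols_all = np.divmod(np.arange(n), grid.n_cols)
    pid = pa_raster.ravel()
    truth = pd.DataFrame(
        {
            "row": rows_all,
            "col": cols_all,
            "pa_id": pid.astype(np.int64),
            "n_covering": ncov.ravel().astype(np.int64),
            "canopy": canopy.ravel().astype(np.int64),
            "forest": forest.ravel(),
            "loss_year": np.where(loss.ravel() > 0, loss.ravel().astype(np.int64) + 2000, 0),
        }
    )
    truth["iucn_category"] = [
        attrs[p].iucn_category if p else "none" for p in truth["pa_id"]
    ]
    truth["iso3"] = [attrs[p].iso3 if p else "none" for p in truth["pa_id"]]
    truth["region"] = [
        region_map(i) if i != "none" else "none" for i in truth["iso3"]
    ]
    est = {p: a.effective_establishment_year for p, a in attrs.items()}
    truth["establishment_year"] = [est.get(p, 0) for p in truth["pa_id"]]
    truth["counted"] = (
        truth["forest"]
        & (truth["loss_year"] > 0)
        & ((truth["pa_id"] == 0) | (truth["loss_year"] > truth["establishment_year"]))
    )

    # period and follow-up truth only for forest pixels with loss (rr, cc)
    period_arr = np.full(n, "", dtype=object)
    fu_arr = np.full(n, "", dtype=object)
    flat = rr * grid.n_cols + cc
    for j in range(len(rr)):
        yr = int(years[j])
        pname = next(nm for nm, (lo, hi, _) in PERIODS.items() if lo <= yr <= hi)
        period_arr[flat[j]] = pname
        epoch = PERIODS[pname][2]
        fu_arr[flat[j]] = (
            UNASSIGNED
            if epoch is None
            else drawn[(epoch, int(cell_r[j]), int(cell_c[j]))]
        )
    truth["period"] = period_arr
    truth["followup_class"] = fu_arr

    truth_summary = _aggregate_truth(truth, grid)
    truth.to_csv(out_dir / "truth_pixels.csv", index=False)
    truth_summary.loss.to_csv(out_dir / "truth_loss.csv", index=False)
    truth_summary.forest.to_csv(out_dir / "truth_forest.csv", index=False)

    return SceneBundle(
        out_dir=out_dir,
        pa_vector_path=pa_path,
        canopy_raster_path=canopy_path,
        loss_year_raster_path=loss_path,
        landcover_raster_paths=lc_paths,
        truth_pixel_table=truth,
        truth_summary=truth_summary,
        config=cfg,
    )


def _aggregate_truth(truth: pd.DataFrame, grid: AnalysisGrid) -> SummaryTable:
    """Direct aggregation of the truth pixel table into the stratum schema."""
    area_ha = PixelAreaModel().row_areas_ha(grid)
    t = truth.copy()
    t["area_ha"] = area_ha[t["row"].to_numpy()]
    forest = (
        t[t["forest"]]
        .groupby(FOREST_KEYS, sort=True)["area_ha"]
        .sum()
        .reset_index()
    )
    counted = t[t["counted"]]
    loss = (
        counted.groupby(LOSS_KEYS, sort=True)["area_ha"].sum().reset_index()
    )
    return SummaryTable(loss=loss, forest=forest)
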