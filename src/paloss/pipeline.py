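"""End-to-end pipeline: configuration, staging, outputs and manifest.

A run is described by one YAML/dict configuration naming either real input
layers (PA vector, canopy, loss-year, land-cover epochs) or a ``simulate``
block (a :class:`~paloss.simulate.LandscapeConfig`), plus the analysis
parameters. Outputs are tidy CSV tables with deterministic row ordering and
a manifest recording the configuration hash, input checksums and package
version, so identical configuration and inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .overlay import assign_followup, build_forest_mask, resample_landcover
from .pa import filter_pas, rasterize_pas
from .raster_io import read_raster, write_raster
from .reclass import ReclassMap
from .regions import RegionMap
from .simulate import LandscapeConfig, generate_scene
from .tabulate import (
    SummaryTable,
    annual_series,
    country_summary,
    followup_shares,
    tabulate_loss,
)
from .vector_io import read_pa_layer

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

logger = logging.getLogger(__name__)

EPOCHS = (2005, 2010, 2015)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any I/O)."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    Exactly one of ``inputs`` (paths to existing layers) or ``simulate``
    (synthetic-scene parameters) must be present.
    """

    inputs: Optional[dict[str, Any]] = None
    simulate: Optional[LandscapeConfig] = None
    canopy_threshold: float = 50.0
    reclass_map: Optional[str] = None
    region_map: Optional[str] = None
    min_country_pa_forest_ha: float = 1000.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ConfigError(
                "exactly one of 'inputs' or 'simulate' must be configured"
            )
        if not 0 <= self.canopy_threshold <= 100:
            raise ConfigError(
                f"canopy_threshold outside [0, 100]: {self.canopy_threshold}"
            )
        if self.min_country_pa_forest_ha < 0:
            raise ConfigError(
                f"min_country_pa_forest_ha must be >= 0: "
                f"{self.min_country_pa_forest_ha}"
            )
        if self.inputs is not None:
            required = {"pa_vector", "canopy", "loss_year", "landcover"}
            missing = sorted(required - set(self.inputs))
            if missing:
                raise ConfigError(f"inputs block missing keys: {missing}")
            lc = self.inputs["landcover"]
            absent = sorted(e for e in EPOCHS if e not in {int(k) for k in lc})
            if absent:
                raise ConfigError(f"inputs.landcover missing epochs: {absent}")

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        known = {
            "inputs", "simulate", "canopy_threshold", "reclass_map",
            "region_map", "min_country_pa_forest_ha", "seed",
        }
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        sim = raw.get("simulate")
        if sim is not None:
            if raw.get("seed") is not None:
                sim = {**sim, "seed": int(raw["seed"])}
            try:
                sim = LandscapeConfig(**sim)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"simulate block invalid: {exc}") from exc
        return cls(
            inputs=raw.get("inputs"),
            simulate=sim,
            canopy_threshold=float(raw.get("canopy_threshold", 50.0)),
            reclass_map=raw.get("reclass_map"),
            region_map=raw.get("region_map"),
            min_country_pa_forest_ha=float(
                raw.get("min_country_pa_forest_ha", 1000.0)
            ),
            seed=raw.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def canonical(self) -> dict[str, Any]:
        sim = None
        if self.simulate is not None:
            sim = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.simulate).items()
            }
        return {
            "inputs": self.inputs,
            "simulate": sim,
            "canopy_threshold": self.canopy_threshold,
            "reclass_map": self.reclass_map,
            "region_map": self.region_map,
            "min_country_pa_forest_ha": self.min_country_pa_forest_ha,
            "seed": self.seed,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-10s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig, out_dir: str | Path) -> SummaryTable:
    """Execute simulate/ingest/overlay/tabulate and write outputs.

    Writes the stratum tables and report CSVs plus ``manifest.json`` under
    ``out_dir`` and returns the :class:`SummaryTable`. Any stage failure
    propagates with the stage named in the log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- gather inputs ----------------------------------------------------
    if config.simulate is not None:
        bundle = generate_scene(config.simulate, out_dir / "inputs")
        pa_path = bundle.pa_vector_path
        canopy_path = bundle.canopy_raster_path
        loss_path = bundle.loss_year_raster_path
        lc_paths = {int(k): Path(v) for k, v in bundle.landcover_raster_paths.items()}
        t0 = _stage("simulate", t0)
    else:
        pa_path = Path(config.inputs["pa_vector"])
        canopy_path = Path(config.inputs["canopy"])
        loss_path = Path(config.inputs["loss_year"])
        lc_paths = {int(k): Path(v) for k, v in config.inputs["landcover"].items()}

    reclass = (
        ReclassMap.from_csv(config.reclass_map)
        if config.reclass_map
        else ReclassMap.default()
    )
    region_map = (
        RegionMap.from_csv(config.region_map)
        if config.region_map
        else RegionMap.default()
    )

    # --- ingest -----------------------------------------------------------
    canopy, grid = read_raster(canopy_path)
    loss, loss_grid = read_raster(loss_path)
    if not grid.same_grid(loss_grid):
        raise ValueError("ingest: canopy and loss-year rasters not on one grid")
    records = filter_pas(read_pa_layer(pa_path))
    pa_grid = rasterize_pas(records, grid)
    write_raster(out_dir / "pa_id.tif", pa_grid.pa_id_raster, grid)
    write_raster(out_dir / "pa_category.tif", pa_grid.category_raster, grid)
    t0 = _stage("ingest", t0)

    # --- overlay ----------------------------------------------------------
    forest = build_forest_mask(canopy, config.canopy_threshold)
    stack = {}
    for epoch, p in lc_paths.items():
        arr, cgrid = read_raster(p)
        stack[epoch] = resample_landcover(arr, cgrid, grid)
    followup = assign_followup(loss, stack, forest, reclass)
    write_raster(out_dir / "forest_mask.tif", forest.astype("uint8"), grid)
    write_raster(out_dir / "followup.tif", followup, grid)
    t0 = _stage("overlay", t0)

    # --- tabulate ---------------------------------------------------------
    table = tabulate_loss(pa_grid, forest, loss, followup, region_map)
    table.loss.to_csv(out_dir / "loss.csv", index=False)
    table.forest.to_csv(out_dir / "forest.csv", index=False)
    country_summary(table, config.min_country_pa_forest_ha).to_csv(
        out_dir / "by_country.csv", index=False
    )
    table.by(["region"]).to_csv(out_dir / "by_region.csv", index=False)
    table.by(["iucn_category"]).to_csv(out_dir / "by_category.csv", index=False)
    annual_series(table).to_csv(out_dir / "by_year.csv", index=False)
    followup_shares(table).rename("share").reset_index().to_csv(
        out_dir / "by_followup.csv", index=False
    )
    table.by(["pa_id", "iucn_category", "iso3", "region"]).to_csv(
        out_dir / "pa_table.csv", index=False
    )
    t0 = _stage("tabulate", t0)

    # --- manifest ---------------------------------------------------------
    cfg_json = json.dumps(config.canonical(), sort_keys=True)
    manifest = {
        "package": "paloss",
        "version": __version__,
        "config": config.canonical(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "inputs": {
            "pa_vector": _sha256(pa_path),
            "canopy": _sha256(canopy_path),
            "loss_year": _sha256(loss_path),
            "landcover": {str(e): _sha256(p) for e, p in sorted(lc_paths.items())},
        },
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return table
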