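"""Synthetic-landscape generator: determinism, truth consistency, recovery."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from paloss.area import PixelAreaModel
from paloss.simulate import LandscapeConfig, generate_scene
from paloss.tabulate import FOREST_KEYS, LOSS_KEYS
from paloss.vector_io import read_pa_layer


def _files(bundle):
    return [
        bundle.pa_vector_path,
        bundle.canopy_raster_path,
        bundle.loss_year_raster_path,
        *sorted(bundle.landcover_raster_paths.values()),
    ]


class TestConfigValidation:
    def test_offending_field_named(self):
        with pytest.raises(ValueError, match="loss_rate_inside"):
            LandscapeConfig(loss_rate_inside=1.5)
        with pytest.raises(ValueError, match="grid_rows"):
            LandscapeConfig(grid_rows=4)
        with pytest.raises(ValueError, match="followup_distribution"):
            LandscapeConfig(followup_distribution={"shrubland": 0.5})
        with pytest.raises(ValueError, match="cell_size"):
            LandscapeConfig(cell_size=0.0)
        with pytest.raises(ValueError, match="establishment_year_range"):
            LandscapeConfig(establishment_year_range=(2010, 2001))


class TestGenerate:
    def test_fixed_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = LandscapeConfig(grid_rows=32, grid_cols=32, seed=5)
        b1 = generate_scene(cfg, tmp_path / "a")
        b2 = generate_scene(cfg, tmp_path / "b")
        for f1, f2 in zip(_files(b1), _files(b2)):
            assert f1.read_bytes() == f2.read_bytes(), f1.name
        pd.testing.assert_frame_equal(b1.truth_pixel_table, b2.truth_pixel_table)

    def test_zero_inside_rate_gives_zero_pa_loss(self, tmp_path):
        cfg = LandscapeConfig(
            grid_rows=48, grid_cols=48, seed=2, loss_rate_inside=0.0,
            loss_rate_outside=0.05,
        )
        b = generate_scene(cfg, tmp_path)
        loss = b.truth_summary.loss
        assert loss[loss["pa_id"] > 0]["area_ha"].sum() == 0.0
        assert loss[loss["pa_id"] == 0]["area_ha"].sum() > 0.0

    def test_forced_overlap_covers_pixels_multiply(self, tmp_path):
        """n_pas=3, p_overlap=1 on 64x64: some pixel center lies in >= 2
        polygons; verified independently by per-pixel point-in-polygon."""
        cfg = LandscapeConfig(
            grid_rows=64, grid_cols=64, seed=9, n_pas=3, p_overlap=1.0,
            frac_marine=0.0, frac_proposed=0.0, frac_point=0.0,
        )
        b = generate_scene(cfg, tmp_path)
        assert (b.truth_pixel_table["n_covering"] >= 2).any()

        records = read_pa_layer(b.pa_vector_path)
        grid = cfg.grid
        multi = 0
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                pt = Point(*grid.center(i, j))
                if sum(pt.within(r.geometry) for r in records) >= 2:
                    multi += 1
        assert multi >= 1
        assert multi == int((b.truth_pixel_table["n_covering"] >= 2).sum())

    def test_configured_special_record_fractions_appear(self, tmp_path):
        cfg = LandscapeConfig(
            grid_rows=32, grid_cols=32, seed=13, n_pas=40,
            frac_marine=0.25, frac_proposed=0.25, frac_point=0.25,
            frac_missing_year=0.3,
        )
        b = generate_scene(cfg, tmp_path)
        records = read_pa_layer(b.pa_vector_path)
        assert any(r.marine_flag == 2 for r in records)
        assert any(r.status == "Proposed" for r in records)
        assert any(not r.is_polygonal for r in records)
        assert any(r.status_year is None for r in records)

    def test_missing_years_never_trigger_establishment_exclusion(self, tmp_path):
        """With every establishment year missing, no forest loss pixel is
        excluded by the establishment filter anywhere."""
        cfg = LandscapeConfig(
            grid_rows=48, grid_cols=48, seed=4, frac_missing_year=1.0,
            frac_marine=0.0, frac_proposed=0.0, frac_point=0.0,
            loss_rate_inside=0.02,
        )
        b = generate_scene(cfg, tmp_path)
        t = b.truth_pixel_table
        eligible = t["forest"] & (t["loss_year"] > 0)
        assert (t.loc[eligible, "counted"]).all()


class TestTruthSelfConsistency:
    def test_summary_equals_direct_pixel_aggregation(self, small_scene):
        t = small_scene.truth_pixel_table.copy()
        area = PixelAreaModel().row_areas_ha(small_scene.config.grid)
        t["area_ha"] = area[t["row"].to_numpy()]
        loss = (
            t[t["counted"]].groupby(LOSS_KEYS, sort=True)["area_ha"].sum()
            .reset_index()
        )
        forest = (
            t[t["forest"]].groupby(FOREST_KEYS, sort=True)["area_ha"].sum()
            .reset_index()
        )
        pd.testing.assert_frame_equal(loss, small_scene.truth_summary.loss)
        pd.testing.assert_frame_equal(forest, small_scene.truth_summary.forest)


class TestStatisticalRecovery:
    def test_inside_loss_fraction_converges(self, tmp_path):
        """Empirical 18-year loss fraction among protected pixels matches
        1 - (1-p)^18 within 3 binomial standard errors on a 256x256 scene."""
        p = 0.00233
        cfg = LandscapeConfig(
            grid_rows=256, grid_cols=256, seed=21, n_pas=8,
            frac_marine=0.0, frac_proposed=0.0, frac_point=0.0,
            loss_rate_inside=p,
        )
        b = generate_scene(cfg, tmp_path)
        t = b.truth_pixel_table
        inside = t["pa_id"] > 0
        n = int(inside.sum())
        assert n > 2000, "scene should contain a sizeable protected area"
        frac = (t.loc[inside, "loss_year"] > 0).mean()
        expected = 1 - (1 - p) ** 18
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) <= 3 * se

    def test_followup_distribution_recovered(self, tmp_path):
        """Follow-up class shares among lost forest pixels match the
        configured categorical distribution within 3 Monte-Carlo SE, with the
        effective sample size of the per-coarse-cell draws."""
        dist = {
            "forest": 0.0, "shrubland": 0.47, "grassland": 0.06,
            "cropland": 0.22, "mosaic_cropland": 0.0,
            "mosaic_vegetation": 0.14, "other": 0.11,
        }
        cfg = LandscapeConfig(
            grid_rows=256, grid_cols=256, seed=33, n_pas=6,
            frac_marine=0.0, frac_proposed=0.0, frac_point=0.0,
            followup_distribution=dist, loss_rate_inside=0.01,
            loss_rate_outside=0.01,
        )
        b = generate_scene(cfg, tmp_path)
        t = b.truth_pixel_table
        sel = t["forest"] & (t["loss_year"] > 0) & (t["followup_class"] != "unassigned")
        sub = t[sel]
        assert len(sub) > 500
        # one categorical draw per (epoch, coarse cell): weight = pixel count
        f = cfg.coarse_factor
        clusters = sub.groupby(
            [sub["period"], sub["row"] // f, sub["col"] // f]
        ).size()
        n_eff = clusters.sum() ** 2 / (clusters**2).sum()
        shares = sub["followup_class"].value_counts(normalize=True)
        for cls, p in dist.items():
            phat = shares.get(cls, 0.0)
            if p == 0.0:
                assert phat == 0.0
            else:
                se = np.sqrt(p * (1 - p) / n_eff)
                assert abs(phat - p) <= 3 * se, (cls, phat, p, 3 * se)
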