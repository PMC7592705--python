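"""Forest definition, period binning, resampling, reclassification, follow-up."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paloss.grid import AnalysisGrid
from paloss.overlay import (
    assign_followup,
    build_forest_mask,
    establishment_filter,
    loss_period,
    resample_landcover,
)
from paloss.reclass import FOLLOWUP_CLASSES, FOLLOWUP_CODES, ReclassMap


class TestForestMask:
    def test_canopy_threshold_boundary(self):
        canopy = np.array([[49, 50, 51, 0, 100]])
        assert build_forest_mask(canopy).tolist() == [[False, True, True, False, True]]

    def test_all_zero_canopy_gives_empty_mask(self):
        assert not build_forest_mask(np.zeros((4, 4))).any()

    def test_out_of_range_canopy_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            build_forest_mask(np.array([[101]]))
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            build_forest_mask(np.array([[50]]), threshold=-1)

    @given(st.integers(0, 100), st.integers(0, 100))
    def test_raising_threshold_never_adds_forest(self, t1, t2):
        lo, hi = sorted((t1, t2))
        canopy = np.arange(101).reshape(1, -1)
        m_lo, m_hi = build_forest_mask(canopy, lo), build_forest_mask(canopy, hi)
        assert (m_hi <= m_lo).all()


class TestEstablishment:
    @pytest.mark.parametrize(
        "loss_year,est,counted",
        [
            (2008, 2010, False),  # loss before establishment excluded
            (2011, 2010, True),   # counted from the year after designation
            (2010, 2010, False),  # the establishment year itself is excluded
            (2001, None, True),   # missing year: established before 2001
            (2001, 1990, True),
        ],
    )
    def test_rule(self, loss_year, est, counted):
        assert establishment_filter(loss_year, est) is counted

    @given(st.integers(2001, 2018), st.integers(1980, 2018))
    def test_counted_iff_strictly_after(self, loss_year, est):
        assert establishment_filter(loss_year, est) == (loss_year > est)


class TestLossPeriod:
    @pytest.mark.parametrize(
        "year,period,epoch",
        [
            (2001, "P2001_2004", 2005),
            (2003, "P2001_2004", 2005),
            (2004, "P2001_2004", 2005),
            (2005, "P2005_2009", 2010),
            (2009, "P2005_2009", 2010),
            (2010, "P2010_2014", 2015),
            (2014, "P2010_2014", 2015),
            (2015, "P2015_2018", None),
            (2016, "P2015_2018", None),
            (2018, "P2015_2018", None),
        ],
    )
    def test_mapping(self, year, period, epoch):
        assert loss_period(year) == (period, epoch)

    @pytest.mark.parametrize("year", [2000, 2019, 1999])
    def test_out_of_window_rejected(self, year):
        with pytest.raises(ValueError, match=str(year)):
            loss_period(year)

    @given(st.integers(2001, 2018))
    def test_every_year_gets_exactly_one_period(self, year):
        period, epoch = loss_period(year)
        assert period in {"P2001_2004", "P2005_2009", "P2010_2014", "P2015_2018"}
        assert (epoch is None) == (year >= 2015)


class TestReclass:
    def test_representative_codes(self):
        m = ReclassMap.default()
        assert m(50) == "forest"           # broadleaf evergreen tree cover
        assert m(30) == "mosaic_cropland"  # >50% cropland mosaic
        assert m(40) == "mosaic_vegetation"
        assert m(190) == "other"           # urban
        assert m(130) == "grassland"
        assert m(10) == "cropland"
        assert m(120) == "shrubland"

    def test_default_map_total_over_legend_with_seven_classes(self):
        m = ReclassMap.default()
        legend = [10, 11, 12, 20, 30, 40, 50, 60, 61, 62, 70, 71, 72, 80, 81,
                  82, 90, 100, 110, 120, 121, 122, 130, 140, 150, 151, 152,
                  153, 160, 170, 180, 190, 200, 201, 202, 210, 220]
        assert set(m.mapping) == set(legend)
        assert set(m.mapping.values()) == set(FOLLOWUP_CLASSES)

    def test_unmapped_code_rejected_with_code(self):
        m = ReclassMap.default()
        with pytest.raises(KeyError, match="999"):
            m(999)
        with pytest.raises(KeyError, match="255"):
            m.apply(np.array([[50, 255]]))

    def test_bad_class_name_rejected(self):
        with pytest.raises(ValueError, match="woodland"):
            ReclassMap({50: "woodland"})

    def test_csv_errors_carry_line_numbers(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("code,class\n50,forest\nxx,forest\n")
        with pytest.raises(ValueError, match=":3"):
            ReclassMap.from_csv(p)


class TestResample:
    def test_nested_grids_replicate_blocks_exactly(self, rng):
        fine = AnalysisGrid(10.0, 1.0, 0.01, 24, 36)
        coarse = fine.coarsen(12)
        arr = rng.integers(0, 200, coarse.shape).astype(np.uint8)
        out = resample_landcover(arr, coarse, fine)
        assert out.shape == fine.shape
        assert (out == np.kron(arr, np.ones((12, 12), dtype=np.uint8))[:24, :36]).all()

    def test_uniform_coarse_gives_uniform_fine(self):
        fine = AnalysisGrid(0.0, 1.0, 0.005, 20, 20)
        coarse = fine.coarsen(7)
        out = resample_landcover(np.full(coarse.shape, 130, np.uint8), coarse, fine)
        assert (out == 130).all()

    def test_matches_containing_cell_brute_force(self, rng):
        """Non-nested offsets: each fine pixel takes the code of the coarse
        cell containing its center, found by direct search."""
        fine = AnalysisGrid(5.0, 2.0, 0.003, 30, 40)
        coarse = AnalysisGrid(4.99, 2.01, 0.0113, 30, 30)
        arr = rng.integers(0, 255, coarse.shape).astype(np.uint8)
        out = resample_landcover(arr, coarse, fine)
        for i in range(fine.n_rows):
            for j in range(fine.n_cols):
                lon, lat = fine.center(i, j)
                ci = int((coarse.origin_lat - lat) // coarse.cell_size)
                cj = int((lon - coarse.origin_lon) // coarse.cell_size)
                assert out[i, j] == arr[ci, cj]

    def test_non_overlapping_extents_rejected(self):
        fine = AnalysisGrid(0.0, 1.0, 0.01, 10, 10)
        coarse = AnalysisGrid(50.0, 1.0, 0.1, 10, 10)
        with pytest.raises(ValueError, match="outside"):
            resample_landcover(np.zeros(coarse.shape, np.uint8), coarse, fine)


class TestAssignFollowup:
    def _stack(self, shape, codes):
        return {e: np.full(shape, c, np.uint8) for e, c in codes.items()}

    def test_epoch_selection_and_unassigned(self):
        m = ReclassMap.default()
        loss = np.array([[7, 16, 0, 3]], dtype=np.uint8)  # 2007, 2016, none, 2003
        forest = np.ones((1, 4), bool)
        stack = self._stack((1, 4), {2005: 120, 2010: 10, 2015: 130})
        out = assign_followup(loss, stack, forest, m)
        assert out[0, 0] == FOLLOWUP_CODES["cropland"]     # 2007 -> 2010 epoch
        assert out[0, 1] == FOLLOWUP_CODES["unassigned"]   # 2016: no epoch
        assert out[0, 2] == 0                              # no loss
        assert out[0, 3] == FOLLOWUP_CODES["shrubland"]    # 2003 -> 2005 epoch

    def test_non_forest_loss_gets_no_followup(self):
        m = ReclassMap.default()
        loss = np.array([[7]], dtype=np.uint8)
        out = assign_followup(
            loss, self._stack((1, 1), {2005: 10, 2010: 10, 2015: 10}),
            np.array([[False]]), m,
        )
        assert out[0, 0] == 0

    def test_missing_epoch_rejected(self):
        m = ReclassMap.default()
        with pytest.raises(ValueError, match="2015"):
            assign_followup(
                np.array([[7]], np.uint8),
                self._stack((1, 1), {2005: 10, 2010: 10}),
                np.ones((1, 1), bool), m,
            )

    def test_partition_every_counted_pixel_one_class(self, clean_scene, rng):
        """Every forest loss pixel receives exactly one of the 7 classes or
        'unassigned'; everything else stays 0."""
        from paloss.raster_io import read_raster
        from paloss.overlay import resample_landcover

        canopy, grid = read_raster(clean_scene.canopy_raster_path)
        loss, _ = read_raster(clean_scene.loss_year_raster_path)
        m = ReclassMap.default()
        stack = {}
        for epoch, p in clean_scene.landcover_raster_paths.items():
            arr, cgrid = read_raster(p)
            stack[epoch] = resample_landcover(arr, cgrid, grid)
        forest = build_forest_mask(canopy)
        out = assign_followup(loss, stack, forest, m)
        eligible = forest & (loss > 0)
        assert ((out > 0) == eligible).all()
        assert out.max() <= 8
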