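"""Design matrix, pixel geometry and sample-selection filters."""

import numpy as np
import pandas as pd
import pytest

import fracland as fl
from fracland.grid import EARTH_RADIUS_KM

from conftest import make_pixels


class TestBuildDesign:
    def test_hinge_pair_below_pivot(self):
        px = make_pixels(n=1, covs={"ph": 5.2})
        spec = fl.DesignSpec(
            terms=[fl.hinge_below("ph", 6.5), fl.hinge_above("ph", 6.5)], intercept=False
        )
        W = fl.build_design(px, spec)
        assert W.iloc[0].tolist() == pytest.approx([1.3, 0.0])

    def test_hinge_pair_at_pivot_is_zero(self):
        px = make_pixels(n=1, covs={"ph": 6.5})
        spec = fl.DesignSpec(
            terms=[fl.hinge_below("ph", 6.5), fl.hinge_above("ph", 6.5)], intercept=False
        )
        assert fl.build_design(px, spec).iloc[0].tolist() == [0.0, 0.0]

    def test_quadratic_interaction_column_order(self):
        px = make_pixels(n=1, covs={"temp": 10.0, "precip": 2.0})
        spec = fl.DesignSpec(
            terms=[
                fl.linear("temp"),
                fl.square("temp"),
                fl.linear("precip"),
                fl.square("precip"),
                fl.interaction("temp", "precip"),
            ],
            intercept=False,
        )
        W = fl.build_design(px, spec)
        assert W.iloc[0].tolist() == [10.0, 100.0, 2.0, 4.0, 20.0]

    def test_intercept_column_first(self):
        px = make_pixels(n=3, covs={"x": [1.0, 2.0, 3.0]})
        W = fl.build_design(px, fl.DesignSpec(terms=[fl.linear("x")]))
        assert list(W.columns) == ["intercept", "x"]
        assert (W["intercept"] == 1.0).all()

    def test_deterministic_and_pure(self):
        px = make_pixels(n=5, covs={"x": np.arange(5.0), "z": np.ones(5)})
        spec = fl.DesignSpec(terms=[fl.linear("z"), fl.square("x")], intercept=False)
        W1, W2 = fl.build_design(px, spec), fl.build_design(px, spec)
        pd.testing.assert_frame_equal(W1, W2)
        assert list(W1.columns) == ["z", "x^2"]

    def test_unknown_variable_raises(self):
        px = make_pixels(n=2, covs={"x": 1.0})
        with pytest.raises(fl.DesignError, match="nope"):
            fl.build_design(px, fl.DesignSpec(terms=[fl.linear("nope")]))

    def test_nonfinite_covariate_names_pixel(self):
        px = make_pixels(n=3, covs={"x": [1.0, np.nan, 2.0]})
        with pytest.raises(fl.DataError, match="p1"):
            fl.build_design(px, fl.DesignSpec(terms=[fl.linear("x")]))

    def test_indicator_expands_per_level_dropping_base(self):
        px = make_pixels(n=4, covs={"country": [0, 0, 1, 2]})
        # covariate columns are numeric here; indicator treats them as labels
        px.frame["country"] = ["AR", "AR", "BR", "US"]
        W = fl.build_design(
            px, fl.DesignSpec(terms=[fl.indicator("country")], intercept=True)
        )
        assert list(W.columns) == ["intercept", "country[BR]", "country[US]"]
        assert W["country[BR]"].tolist() == [0.0, 0.0, 1.0, 0.0]


class TestPixelArea:
    def test_equator_five_arcmin_matches_spherical_oracle(self):
        # independent spherical-quadrilateral computation
        dlam = np.deg2rad(5.0 / 60.0)
        phi = np.deg2rad(2.5 / 60.0)
        expected = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi) - np.sin(-phi))
        got = fl.pixel_area(0.0, 5.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(85.9, abs=0.05)

    def test_roughly_100_km2_at_equator(self):
        # 5' cells are "about 100 km^2" at the equator, within 20%
        assert abs(fl.pixel_area(0.0, 5.0) - 100.0) / 100.0 < 0.20

    def test_symmetric_in_hemisphere(self):
        assert fl.pixel_area(45.0) == pytest.approx(fl.pixel_area(-45.0), rel=1e-14)

    def test_strictly_decreasing_in_abs_latitude(self):
        lats = np.linspace(0, 89, 60)
        areas = fl.pixel_area(lats, 5.0)
        assert np.all(np.diff(areas) < 0)
        assert np.all(areas > 0)

    def test_pole_crossing_raises(self):
        with pytest.raises(fl.GridError, match="pole"):
            fl.pixel_area(89.999, 5.0)

    def test_fine_cells_partition_coarse_cell_area(self):
        # 36 five-minute cells tile one 30-minute cell exactly
        lat0 = 42.0  # bottom edge of a 30' cell
        fine_lats = lat0 + (np.arange(6) + 0.5) * (5.0 / 60.0)
        fine_total = 6 * np.sum(fl.pixel_area(fine_lats, 5.0))
        dlam = np.deg2rad(0.5)
        coarse = EARTH_RADIUS_KM**2 * dlam * (
            np.sin(np.deg2rad(lat0 + 0.5)) - np.sin(np.deg2rad(lat0))
        )
        assert fine_total == pytest.approx(coarse, rel=1e-12)


class TestBlockDownscale:
    def test_constant_coarse_grid(self):
        coarse = np.full((4, 4), 7.5)
        lat = np.array([0.1, 0.4, 1.2])
        lon = np.array([0.1, 0.7, 1.9])
        out = fl.block_downscale(coarse, lat, lon, origin=(0.0, 0.0))
        assert np.all(out == 7.5)

    def test_adjacent_cells_no_mixing(self):
        coarse = np.array([[1.0, 2.0]])  # two 30' cells side by side
        lons = np.linspace(0.0 + 1 / 24, 1.0 - 1 / 24, 12)  # 5' centres
        lats = np.full(12, 0.25)
        out = fl.block_downscale(coarse, lats, lons, origin=(0.0, 0.0))
        assert out[:6].tolist() == [1.0] * 6
        assert out[6:].tolist() == [2.0] * 6

    def test_half_open_boundary_goes_to_upper_cell(self):
        coarse = np.array([[1.0, 2.0]])
        out = fl.block_downscale(coarse, np.array([0.25]), np.array([0.5]), origin=(0.0, 0.0))
        assert out[0] == 2.0

    def test_missing_coarse_value_raises(self):
        coarse = np.array([[1.0, np.nan]])
        with pytest.raises(fl.GridError, match="missing"):
            fl.block_downscale(coarse, np.array([0.25]), np.array([0.75]), origin=(0.0, 0.0))

    def test_outside_coverage_names_pixels(self):
        coarse = np.ones((2, 2))
        with pytest.raises(fl.GridError, match="px9"):
            fl.block_downscale(
                coarse, np.array([5.0]), np.array([0.2]),
                origin=(0.0, 0.0), pixel_ids=np.array(["px9"]),
            )


class TestFilters:
    def test_no_flags_identity(self):
        px = make_pixels(n=4)
        assert fl.apply_exclusions(px) is px

    def test_drops_flagged_pixels(self):
        px = make_pixels(n=10, excluded=[True] * 3 + [False] * 7)
        out = fl.apply_exclusions(px)
        assert out.n_pixels == 7
        assert not out.frame["excluded"].any()

    def test_unit_losing_all_pixels_raises(self):
        px = make_pixels(n=4, units=["A", "A", "B", "B"],
                         excluded=[False, False, True, True])
        with pytest.raises(fl.EmptyUnitError, match="B"):
            fl.apply_exclusions(px)

    def _shares(self, rows):
        return fl.AggregateShares(
            pd.DataFrame(rows, columns=["other", "maize"],
                         index=[f"u{i}" for i in range(len(rows))])
        )

    def test_threshold_is_inclusive(self):
        shares = self._shares([[0.996, 0.004], [0.995, 0.005], [0.9, 0.1]])
        kept = fl.select_units(shares, 0.005)
        assert list(kept.units) == ["u1", "u2"]

    def test_multi_crop_sum_cap_on_raw_shares(self):
        # raw reported crop shares can exceed 1 jointly (multiple cropping);
        # such units are dropped before the composition is formed
        raw = pd.DataFrame(
            {"maize": [0.5, 0.3], "soy": [0.4, 0.3], "wheat": [0.2, 0.2]},
            index=["double_cropped", "ok"],
        )
        kept = fl.select_units(raw, 0.005)
        assert list(kept.index) == ["ok"]

    def test_idempotent(self):
        shares = self._shares([[0.996, 0.004], [0.9, 0.1], [0.5, 0.5]])
        once = fl.select_units(shares, 0.005)
        twice = fl.select_units(once, 0.005)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_empty_selection_raises(self):
        shares = self._shares([[0.999, 0.001], [0.998, 0.002]])
        with pytest.raises(fl.SelectionError):
            fl.select_units(shares, 0.005)


class TestContainers:
    def test_duplicate_pixel_id_rejected(self):
        df = make_pixels(n=3).frame
        df.loc[2, "pixel_id"] = "p0"
        with pytest.raises(fl.DataError, match="duplicate"):
            fl.PixelTable(df)

    def test_nonpositive_area_rejected(self):
        df = make_pixels(n=2).frame
        df.loc[0, "area"] = 0.0
        with pytest.raises(fl.DataError, match="area"):
            fl.PixelTable(df)

    def test_level2_must_nest(self):
        df = make_pixels(n=2, units=["A", "B"]).frame
        df["unit_l2"] = ["d1", "d1"]  # one district claiming two states
        with pytest.raises(fl.DataError, match="crossing"):
            fl.PixelTable(df)

    def test_shares_must_sum_to_one(self):
        df = pd.DataFrame({"other": [0.7], "maize": [0.2]}, index=["u0"])
        with pytest.raises(fl.DataError, match="sum"):
            fl.AggregateShares(df)

    def test_shares_long_roundtrip_with_residual_base(self):
        long = pd.DataFrame(
            {"unit_l1": ["a", "a", "b", "b"], "crop": ["maize", "soy"] * 2,
             "share": [0.2, 0.3, 0.1, 0.4]}
        )
        shares = fl.AggregateShares.from_long(long)
        assert shares.crops[0] == "other"
        assert shares.frame.loc["a", "other"] == pytest.approx(0.5)
        back = shares.to_long()
        assert set(back["crop"]) == {"other", "maize", "soy"}
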