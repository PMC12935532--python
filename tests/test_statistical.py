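import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defocarb.io_registry import AgStatsTable, ConfigBundle
from defocarb.statistical import (
    allocate_commodities,
    allocate_landuse,
    crop_expansions,
    landuse_expansions,
)


def _stats(rows):
    return AgStatsTable(pd.DataFrame(
        rows, columns=["region", "year", "variable", "value", "flag"]
    ))


@pytest.fixture()
def simple_stats():
    rows = []
    for y, v in [(2008, 1000), (2009, 1100), (2010, 1050)]:
        rows.append(("R1", y, "cropland_area", v, "official"))
    for y, v in [(2008, 500), (2009, 520), (2010, 560)]:
        rows.append(("R1", y, "pasture_area", v, "official"))
    for y in (2008, 2009, 2010):
        rows.append(("R1", y, "forest_plantation_area", 200, "official"))
    return _stats(rows)


class TestExpansions:
    def test_gross_sums_positive_increments(self, simple_stats):
        exp = landuse_expansions(simple_stats, "R1", 2010, 2, mode="gross")
        assert exp["cropland"] == pytest.approx(100.0)

    def test_net_is_endpoint_difference(self, simple_stats):
        exp = landuse_expansions(simple_stats, "R1", 2010, 2, mode="net")
        assert exp["cropland"] == pytest.approx(50.0)

    def test_constant_series_zero_expansion(self, simple_stats):
        exp = landuse_expansions(simple_stats, "R1", 2010, 2)
        assert exp["forest_plantation"] == 0.0

    def test_no_data_returns_none(self, simple_stats):
        assert landuse_expansions(simple_stats, "R9", 2010, 2) is None


class TestAllocateLanduse:
    def test_cropland_first_hand_case(self, config):
        out = allocate_landuse(
            {"unresolved_agriculture": 100.0},
            {"cropland": 60.0, "pasture": 40.0, "forest_plantation": 0.0},
            config,
        )
        got = out.groupby("target")["area_ha"].sum().to_dict()
        assert got == pytest.approx({"cropland": 60.0, "pasture": 40.0})

    def test_proportional_when_cropland_first_off(self):
        cfg = ConfigBundle(cropland_first=False)
        out = allocate_landuse(
            {"unresolved_agriculture": 100.0},
            {"cropland": 60.0, "pasture": 40.0, "forest_plantation": 0.0},
            cfg,
        )
        got = out.groupby("target")["area_ha"].sum().to_dict()
        assert got == pytest.approx({"cropland": 60.0, "pasture": 40.0})

    def test_restriction_produces_without_production_residual(self, config):
        out = allocate_landuse(
            {"unresolved_agriculture": 100.0},
            {"cropland": 60.0, "pasture": 10.0, "forest_plantation": 0.0},
            config,
        )
        got = out.groupby("target")["area_ha"].sum().to_dict()
        assert got.pop("without_production") == pytest.approx(30.0)
        assert sum(got.values()) == pytest.approx(70.0)

    def test_no_restriction_allocates_everything(self):
        cfg = ConfigBundle(restrict_by_stats="none", cropland_first=False)
        out = allocate_landuse(
            {"unresolved_agriculture": 100.0},
            {"cropland": 60.0, "pasture": 10.0, "forest_plantation": 0.0},
            cfg,
        )
        assert "without_production" not in set(out["target"])
        assert out["area_ha"].sum() == pytest.approx(100.0)

    def test_mosaic_splits_cropland_pasture_only(self, config):
        out = allocate_landuse(
            {"cropland_pasture_mosaic": 50.0},
            {"cropland": 30.0, "pasture": 60.0, "forest_plantation": 500.0},
            config,
        )
        targets = set(out["target"])
        assert "forest_plantation" not in targets
        got = out.groupby("target")["area_ha"].sum()
        assert got["cropland"] == pytest.approx(50 * 30 / 90)

    def test_zero_expansions_leave_pool_unallocated(self, config):
        out = allocate_landuse(
            {"unresolved_agriculture": 80.0},
            {"cropland": 0.0, "pasture": 0.0, "forest_plantation": 0.0},
            config,
        )
        assert out.iloc[0]["target"] == "unallocated"
        assert out["area_ha"].sum() == pytest.approx(80.0)

    def test_negative_pool_rejected(self, config):
        with pytest.raises(ValueError):
            allocate_landuse({"cropland_only": -1.0}, None, config)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        pools=st.fixed_dictionaries({
            "unresolved_agriculture": st.floats(0, 1000),
            "cropland_only": st.floats(0, 1000),
            "pasture_only": st.floats(0, 1000),
            "cropland_pasture_mosaic": st.floats(0, 1000),
        }),
        exps=st.tuples(st.floats(0, 500), st.floats(0, 500), st.floats(0, 500)),
        cropland_first=st.booleans(),
        restrict=st.sampled_from(["pools", "all", "none"]),
    )
    def test_conservation_property(self, pools, exps, cropland_first, restrict):
        """Allocations plus residuals always equal the input pools."""
        cfg = ConfigBundle(cropland_first=cropland_first,
                           restrict_by_stats=restrict)
        expansions = dict(zip(
            ("cropland", "pasture", "forest_plantation"), exps
        ))
        out = allocate_landuse(pools, expansions, cfg)
        assert out["area_ha"].sum() == pytest.approx(sum(pools.values()),
                                                     rel=1e-9, abs=1e-9)
        assert (out["area_ha"] >= -1e-12).all()


class TestAllocateCommodities:
    @pytest.fixture()
    def crop_stats(self):
        rows = []
        for y, soy, maize, area in [(2007, 100, 300, 1000),
                                    (2010, 400, 400, 1000)]:
            rows.append(("R1", y, "harvested_soy", soy, "official"))
            rows.append(("R1", y, "harvested_maize", maize, "official"))
            rows.append(("R1", y, "cropland_area", area, "official"))
        return _stats(rows)

    def test_proportional_hand_case(self, crop_stats):
        out = allocate_commodities(90.0, crop_stats, "R1", 2010, 3,
                                   multicropping=False)
        assert out == pytest.approx({"soy": 67.5, "maize": 22.5})

    def test_single_expanding_crop_takes_all(self):
        stats = _stats([
            ("R1", 2007, "harvested_soy", 100, "official"),
            ("R1", 2010, "harvested_soy", 150, "official"),
            ("R1", 2007, "harvested_maize", 300, "official"),
            ("R1", 2010, "harvested_maize", 300, "official"),
        ])
        out = allocate_commodities(10.0, stats, "R1", 2010, 3,
                                   multicropping=False)
        assert out == pytest.approx({"soy": 10.0})

    def test_no_expanding_crop_returns_none(self):
        stats = _stats([
            ("R1", 2007, "harvested_soy", 100, "official"),
            ("R1", 2010, "harvested_soy", 90, "official"),
        ])
        assert allocate_commodities(10.0, stats, "R1", 2010, 3) is None

    def test_scale_invariance_of_shares(self, crop_stats):
        base = allocate_commodities(90.0, crop_stats, "R1", 2010, 3,
                                    multicropping=False)
        scaled_rows = crop_stats.values.copy()
        scaled_rows.loc[
            scaled_rows["variable"].str.startswith("harvested"), "value"
        ] *= 7.0
        scaled = allocate_commodities(
            90.0, AgStatsTable(scaled_rows), "R1", 2010, 3,
            multicropping=False,
        )
        for crop in base:
            assert scaled[crop] == pytest.approx(base[crop])

    def test_uniform_cropping_intensity_cancels(self):
        """Doubling every harvested area doubles CI (already above 1), so the
        adjusted series — and hence the shares — are unchanged."""
        rows, rows2 = [], []
        for y, soy, maize in [(2007, 400, 800), (2010, 900, 900)]:
            for tgt, mult in ((rows, 1), (rows2, 2)):
                tgt.append(("R1", y, "harvested_soy", soy * mult, "official"))
                tgt.append(("R1", y, "harvested_maize", maize * mult,
                            "official"))
                tgt.append(("R1", y, "cropland_area", 1000, "official"))
        a = allocate_commodities(90.0, _stats(rows), "R1", 2010, 3,
                                 multicropping=True)
        b = allocate_commodities(90.0, _stats(rows2), "R1", 2010, 3,
                                 multicropping=True)
        assert set(a) == set(b)
        for crop in a:
            assert b[crop] == pytest.approx(a[crop])

    def test_multicropping_off_favours_largest_harvested_crop(self):
        """Turning the cropping-intensity correction off inflates the claim
        of a crop whose harvested-area boom comes from double cropping (the
        safrinha-maize pattern: maize jumps in a year when total harvested
        area far exceeds physical cropland)."""
        rows = []
        for y, soy, maize in [(2007, 400, 400), (2008, 600, 400),
                              (2009, 600, 400), (2010, 600, 900)]:
            rows.append(("R1", y, "harvested_soy", soy, "official"))
            rows.append(("R1", y, "harvested_maize", maize, "official"))
            rows.append(("R1", y, "cropland_area", 1000, "official"))
        stats = _stats(rows)
        with_ci = allocate_commodities(90.0, stats, "R1", 2010, 3,
                                       multicropping=True)
        without = allocate_commodities(90.0, stats, "R1", 2010, 3,
                                       multicropping=False)
        assert without["maize"] > with_ci["maize"]
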