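import numpy as np
import pandas as pd
import pytest

from defocarb.io_registry import (
    ConfigBundle,
    DatasetDescriptor,
    GridSpec,
    Layer,
    LayerStack,
)
from defocarb.spatial import (
    attribute_pixels,
    build_forest_mask,
    summarize_attribution,
)
from defocarb.synthetic import LandscapeParams, generate_landscape

from .reference import brute_force_attribution


class TestForestMask:
    @pytest.mark.parametrize(
        "density,plantation,expected",
        [
            (30.0, 0.0, 1.0),   # above threshold, natural
            (30.0, 1.0, 0.0),   # managed plantation is not natural forest
            (24.9, 0.0, 0.0),   # strictly below the >= 25 rule
            (25.0, 0.0, 1.0),   # boundary included
        ],
    )
    def test_threshold_and_plantation_logic(self, density, plantation, expected):
        d = Layer("density", "continuous", np.array([[density]]))
        p = Layer("plantation", "mask", np.array([[plantation]]))
        mask = build_forest_mask(d, p, 25.0)
        assert mask.values[0, 0] == expected

    def test_nodata_propagates(self):
        d = Layer("density", "continuous", np.array([[-9999.0, 50.0]]))
        mask = build_forest_mask(d, None, 25.0)
        assert not mask.valid[0, 0] and mask.values[0, 1] == 1.0

    def test_threshold_out_of_range(self):
        d = Layer("density", "continuous", np.array([[50.0]]))
        with pytest.raises(ValueError):
            build_forest_mask(d, None, 150.0)


def _tiny_stack(**layers):
    """1x1 world with density 80, loss in 2010, plus the given class layers."""
    grid = GridSpec(1, 1)
    base = {
        "density": Layer("density", "continuous", np.array([[80.0]])),
        "loss_year": Layer("loss_year", "year", np.array([[2010.0]])),
        "plantation": Layer("plantation", "mask", np.array([[0.0]])),
        "region": Layer("region", "categorical", np.array([[1.0]])),
    }
    base.update(layers)
    return LayerStack(grid, base.values())


SOY = DatasetDescriptor("soy_map", "commodity", {1: "soy"},
                        overall_accuracy=0.9, last_valid_year=2022)
CROPLAND = DatasetDescriptor("lu_map", "land_use", {1: "cropland"},
                             overall_accuracy=0.8, spatial_score=0.5,
                             last_valid_year=2022)
FIRE = DatasetDescriptor("fire", "fire", {1: "fire"})
PASTURE = DatasetDescriptor("pasture_map", "land_use", {2: "pasture"},
                            overall_accuracy=0.8, last_valid_year=2022)


class TestHierarchy:
    def test_commodity_beats_land_use(self, config):
        stack = _tiny_stack(
            soy_map=Layer("soy_map", "categorical", np.array([[1.0]])),
            lu_map=Layer("lu_map", "categorical", np.array([[1.0]])),
        )
        attr = attribute_pixels(stack, [CROPLAND, SOY], config)
        cls = attr.classes[attr.codes[0, 0]]
        assert (cls.label, cls.level) == ("soy", "commodity")

    def test_static_map_not_used_beyond_last_valid_year(self, config):
        cocoa = DatasetDescriptor("cocoa_map", "commodity", {1: "cocoa"},
                                  last_valid_year=2020)
        stack = _tiny_stack(
            loss_year=Layer("loss_year", "year", np.array([[2021.0]])),
            cocoa_map=Layer("cocoa_map", "categorical", np.array([[1.0]])),
        )
        attr = attribute_pixels(stack, [cocoa], config)
        assert attr.classes[attr.codes[0, 0]].label == "unattributed"

    def test_static_map_valid_for_earlier_losses(self, config):
        cocoa = DatasetDescriptor("cocoa_map", "commodity", {1: "cocoa"},
                                  last_valid_year=2020)
        stack = _tiny_stack(
            cocoa_map=Layer("cocoa_map", "categorical", np.array([[1.0]])),
        )
        attr = attribute_pixels(stack, [cocoa], config)
        assert attr.classes[attr.codes[0, 0]].label == "cocoa"

    def test_agriculture_wins_over_fire(self, config):
        stack = _tiny_stack(
            fire_year=Layer("fire_year", "year", np.array([[2010.0]])),
            pasture_map=Layer("pasture_map", "categorical", np.array([[2.0]])),
        )
        attr = attribute_pixels(stack, [PASTURE, FIRE], config)
        assert attr.classes[attr.codes[0, 0]].label == "pasture"

    def test_fire_only_excluded_from_deforestation(self, config):
        stack = _tiny_stack(
            fire_year=Layer("fire_year", "year", np.array([[2010.0]])),
        )
        attr = attribute_pixels(stack, [FIRE], config)
        assert attr.classes[attr.codes[0, 0]].label == "fire_non_commodity"
        summary = summarize_attribution(
            attr, stack["region"], stack["loss_year"], stack.grid
        )
        assert summary.totals["deforestation_ha"].sum() == 0.0
        assert summary.totals["fire_ha"].sum() == pytest.approx(0.09)

    def test_annual_map_lag_window(self):
        """An annual commodity observation is usable only within
        [t, t + spatial_lag_years]."""
        soy = DatasetDescriptor("soy_map", "commodity", {1: "soy"},
                                annual=True, last_valid_year=2022)
        for obs_year, lag, expected in [
            (2012, 3, "soy"), (2014, 3, "unattributed"),
            (2012, 1, "unattributed"), (2009, 3, "unattributed"),
        ]:
            stack = _tiny_stack(
                soy_map=Layer("soy_map", "categorical", np.array([[1.0]])),
                soy_map__year=Layer("soy_map__year", "continuous",
                                    np.array([[float(obs_year)]])),
            )
            cfg = ConfigBundle(spatial_lag_years=lag)
            attr = attribute_pixels(stack, [soy], cfg)
            assert attr.classes[attr.codes[0, 0]].label == expected, \
                (obs_year, lag)


class TestSummaries:
    def test_count_times_area(self, config):
        grid = GridSpec(10, 10)
        soy_vals = np.zeros((10, 10))
        soy_vals[:5, :] = 1.0  # 50 soy pixels
        stack = LayerStack(grid, [
            Layer("density", "continuous", np.full((10, 10), 80.0)),
            Layer("loss_year", "year", np.full((10, 10), 2010.0)),
            Layer("region", "categorical", np.ones((10, 10))),
            Layer("soy_map", "categorical", soy_vals),
        ])
        attr = attribute_pixels(stack, [SOY], config)
        summary = summarize_attribution(attr, stack["region"],
                                        stack["loss_year"], grid)
        soy_row = summary.rows[summary.rows["label"] == "soy"]
        assert soy_row["area_ha"].sum() == pytest.approx(50 * 0.09)
        summary.check_invariants()

    def test_empty_loss_layer(self, config):
        stack = _tiny_stack(
            loss_year=Layer("loss_year", "year", np.array([[0.0]])),
        )
        attr = attribute_pixels(stack, [], config)
        summary = summarize_attribution(attr, stack["region"],
                                        stack["loss_year"], stack.grid)
        assert summary.rows.empty and summary.totals.empty


class TestProperties:
    def test_exclusivity_every_loss_pixel_in_one_class(self, default_landscape):
        ls = default_landscape
        attr = attribute_pixels(ls.stack, ls.registry, ConfigBundle())
        loss = ls.stack["loss_year"].values > 0
        assert ((attr.codes >= 0) == loss).all()

    def test_threshold_monotonicity(self, default_landscape):
        ls = default_landscape
        areas = []
        for thr in (10.0, 25.0, 75.0):
            attr = attribute_pixels(ls.stack, ls.registry,
                                    ConfigBundle(tcd_threshold=thr))
            s = summarize_attribution(attr, ls.stack["region"],
                                      ls.stack["loss_year"], ls.stack.grid)
            areas.append(s.totals["deforestation_ha"].sum())
        assert areas[0] >= areas[1] >= areas[2]
        assert areas[2] < areas[1]  # strict on this landscape

    def test_lag_monotonicity_in_commodity_area(self):
        ls = generate_landscape(LandscapeParams(seed=31, obs_delay_max=5))
        areas = []
        for lag in (1, 3, 5):
            attr = attribute_pixels(ls.stack, ls.registry,
                                    ConfigBundle(spatial_lag_years=lag))
            s = summarize_attribution(attr, ls.stack["region"],
                                      ls.stack["loss_year"], ls.stack.grid)
            areas.append(
                s.rows.loc[s.rows["level"] == "commodity", "area_ha"].sum()
            )
        assert areas[0] <= areas[1] <= areas[2]
        assert areas[0] < areas[2]

    def test_noiseless_full_coverage_matches_truth_exactly(
        self, noiseless_landscape
    ):
        ls = noiseless_landscape
        attr = attribute_pixels(ls.stack, ls.registry, ConfigBundle())
        s = summarize_attribution(attr, ls.stack["region"],
                                  ls.stack["loss_year"], ls.stack.grid)
        got = (
            s.rows[s.rows["level"] == "commodity"]
            .groupby("label")["area_ha"].sum()
        )
        want = ls.truth.table.groupby("commodity")["area_ha"].sum()
        pd.testing.assert_series_equal(
            got.sort_index(), want.sort_index(),
            check_names=False, check_exact=False, rtol=1e-12,
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_matches_brute_force(self, seed):
        ls = generate_landscape(
            LandscapeParams(grid=GridSpec(30, 30), seed=seed,
                            spatial_coverage=0.7, noise=0.1,
                            obs_delay_max=4)
        )
        cfg = ConfigBundle()
        attr = attribute_pixels(ls.stack, ls.registry, cfg)
        ref_labels, ref_levels, _ = brute_force_attribution(
            ls.stack, ls.registry, cfg
        )
        got = attr.label_grid()
        assert (got == ref_labels).all()
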