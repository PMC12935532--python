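import numpy as np
import pytest

from defocarb.carbon import (
    C_TO_CO2,
    CarbonParams,
    apportion_statistical_emissions,
    landuse_group_of,
    net_emissions,
    pixel_gross_carbon,
)


@pytest.fixture()
def params():
    # biome fractions chosen to reproduce the hand-checked worked numbers
    return CarbonParams(
        deadwood_frac={"tropical": 0.1},
        litter_frac={"tropical": 0.04},
        soc_loss_frac={("cropland", "tropical"): 0.25},
    )


class TestGrossCarbon:
    def test_hand_arithmetic(self, params):
        """AGB 100, rs 0.2, deadwood 0.1, litter 0.04 -> vegetation
        100*(1.34)*0.47 = 62.98 MgC/ha; SOC 120 * 0.25 = 30 MgC/ha."""
        comp = pixel_gross_carbon(100.0, 0.2, "tropical", 120.0, False,
                                  params, "cropland")
        veg = (comp["agb"] + comp["bgb"] + comp["deadwood"] + comp["litter"])
        assert float(veg) == pytest.approx(62.98)
        assert float(comp["soc"]) == pytest.approx(30.0)

    def test_peat_pixels_carry_no_soc_component(self, params):
        comp = pixel_gross_carbon(100.0, 0.2, "tropical", 500.0, True,
                                  params, "cropland")
        assert float(comp["soc"]) == 0.0

    def test_zero_inputs_zero_components(self, params):
        comp = pixel_gross_carbon(0.0, 0.2, "tropical", 0.0, False,
                                  params, "cropland")
        assert all(float(v) == 0.0 for v in comp.values())

    def test_unknown_biome_rejected(self, params):
        with pytest.raises(KeyError):
            pixel_gross_carbon(10.0, 0.2, "lunar", 10.0, False, params,
                               "cropland")

    def test_agb_only_closed_form_limit(self):
        """All fractions and rs zero reduce the model to AGB carbon alone."""
        p = CarbonParams(
            deadwood_frac={"tropical": 0.0}, litter_frac={"tropical": 0.0},
            soc_loss_frac={("cropland", "tropical"): 0.0},
        )
        comp = pixel_gross_carbon(200.0, 0.0, "tropical", 99.0, False, p,
                                  "cropland")
        total = sum(float(v) for v in comp.values())
        assert total == pytest.approx(200.0 * 0.47)


class TestNetEmissions:
    def test_hand_case(self, params):
        """92.98 MgC gross on 1 ha, 40 MgC/ha replacing stock:
        gross 340.93, net (92.98-40)*44/12 = 194.26 MgCO2."""
        p = CarbonParams(plant_stock={"testcrop": 40.0})
        rec = net_emissions({"veg": 62.98, "soc": 30.0}, "testcrop", 1.0, p)
        assert rec["gross_MgCO2"] == pytest.approx(340.93, abs=0.005)
        assert rec["net_MgCO2"] == pytest.approx(194.26, abs=0.005)

    def test_mgc_to_mgco2_identity(self):
        p = CarbonParams(plant_stock={"x": 0.0})
        rec = net_emissions({"veg": 12.0}, "x", 1.0, p)
        assert rec["gross_MgCO2"] == pytest.approx(44.0)

    def test_reduced_plant_stock_scale_raises_net(self):
        p1 = CarbonParams(plant_stock={"x": 40.0}, plant_stock_scale=1.0)
        p2 = CarbonParams(plant_stock={"x": 40.0}, plant_stock_scale=0.75)
        n1 = net_emissions({"veg": 90.0}, "x", 1.0, p1)["net_MgCO2"]
        n2 = net_emissions({"veg": 90.0}, "x", 1.0, p2)["net_MgCO2"]
        assert n2 > n1

    def test_net_never_exceeds_gross(self):
        p = CarbonParams()
        for commodity in ("soy", "oil_palm", "cattle_meat_leather"):
            rec = net_emissions({"veg": 50.0}, commodity, 2.0, p)
            assert rec["net_MgCO2"] <= rec["gross_MgCO2"]

    def test_group_fallback_resolves_unknown_commodity(self):
        p = CarbonParams()
        # wheat has no direct stock entry; group annual_crop applies
        assert p.plant_stock_for("wheat") == p.plant_stock["annual_crop"]
        with pytest.raises(KeyError, match="group"):
            CarbonParams(plant_stock={}, commodity_group={}).plant_stock_for(
                "mystery_crop"
            )


class TestApportionment:
    def test_fifty_percent_share(self):
        out = apportion_statistical_emissions(1000.0, {"maize": 5.0, "soy": 5.0})
        assert out["maize"] == pytest.approx(500.0)

    def test_single_commodity_pool(self):
        out = apportion_statistical_emissions(123.0, {"soy": 2.0})
        assert out == {"soy": 123.0}

    def test_conservation_on_random_splits(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            areas = {f"c{i}": float(a) for i, a in
                     enumerate(rng.uniform(0.1, 10, size=5))}
            total = float(rng.uniform(1, 1e4))
            out = apportion_statistical_emissions(total, areas)
            assert sum(out.values()) == pytest.approx(total, rel=1e-12)

    def test_zero_pool_with_emissions_rejected(self):
        with pytest.raises(ValueError):
            apportion_statistical_emissions(10.0, {"soy": 0.0})


class TestGroups:
    @pytest.mark.parametrize("commodity,group", [
        ("soy", "cropland"), ("oil_palm", "cropland"),
        ("cattle_meat_leather", "pasture"),
        ("forestry_products", "forest_plantation"),
    ])
    def test_landuse_group_mapping(self, commodity, group):
        assert landuse_group_of(commodity) == group
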