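"""Committed carbon-emission bookkeeping for deforested area.

Deforestation commits five carbon stocks to the atmosphere: above-ground
biomass (AGB), below-ground biomass (BGB, via a root-to-shoot ratio),
deadwood, litter (both as biome-specific proportions of AGB) and a fraction
of the 0-100 cm soil organic carbon (SOC) stock.  The committed carbon
sequestration of the replacing commodity (its mature plant carbon stock) is
deducted to obtain net emissions:

    net = AGB + BGB + deadwood + litter + SOC_loss - plant_stock

All losses are booked once ("committed") in the deforestation year; peat
soils are excluded from the SOC term because drained-peat fluxes are
accounted separately and would otherwise be double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

C_TO_CO2 = 44.0 / 12.0
BIOMASS_TO_CARBON = 0.47

BIOMES = ("tropical", "temperate", "boreal")

#: raster biome codes -> biome names
BIOME_CODES = {1: "tropical", 2: "temperate", 3: "boreal"}

# Residual classes of the land balance: deforested area that could not be
# tied to any produced commodity.  No replacing vegetation is credited.
RESIDUAL_CLASSES = ("without_production", "unallocated")


def landuse_group_of(commodity: str) -> str:
    """Map a commodity label to its replacing land-use group.

    The group selects the SOC-loss fraction and (for peat) the drainage
    emission factor.  Pasture output is the combined cattle class; forestry
    output maps to plantations; everything else is a crop.
    """
    if commodity in ("cattle_meat_leather", "pasture"):
        return "pasture"
    if commodity in ("forestry_products", "forest_plantation"):
        return "forest_plantation"
    return "cropland"


def _default_plant_stocks() -> dict[str, float]:
    # Mature plant carbon stocks, MgC/ha.  Commodity-specific entries first,
    # group-level fallbacks below (annual crops are low, tree crops high).
    return {
        "soy": 2.0,
        "maize": 2.5,
        "rice": 2.5,
        "cocoa": 33.0,
        "coffee": 21.0,
        "oil_palm": 36.0,
        "rubber": 38.0,
        "cattle_meat_leather": 3.4,
        "forestry_products": 55.0,
        # group fallbacks
        "annual_crop": 2.2,
        "tree_crop": 30.0,
        "pasture": 3.4,
        "forest_plantation": 55.0,
        "cropland": 2.2,
    }


def _default_commodity_groups() -> dict[str, str]:
    return {
        "soy": "annual_crop",
        "maize": "annual_crop",
        "rice": "annual_crop",
        "wheat": "annual_crop",
        "cassava": "annual_crop",
        "cocoa": "tree_crop",
        "coffee": "tree_crop",
        "oil_palm": "tree_crop",
        "rubber": "tree_crop",
        "cattle_meat_leather": "pasture",
        "forestry_products": "forest_plantation",
    }


@dataclass
class CarbonParams:
    """Parameters of the committed-emission calculation.

    biomass_to_carbon : dry biomass -> carbon ratio (IPCC forest default 0.47)
    deadwood_frac, litter_frac : proportion of AGB, by biome
    soc_loss_frac : fraction of the 0-100 cm SOC stock lost on conversion,
        by (replacing land-use group, biome)
    plant_stock : mature plant carbon stock, MgC/ha, by commodity; groups
        act as fallback via ``commodity_group``
    plant_stock_scale : fraction of the mature stock credited (1.0 default;
        0.75 models average pre-harvest accumulation)
    """

    biomass_to_carbon: float = BIOMASS_TO_CARBON
    soc_depth_cm: int = 100  # the SOC layer must hold the 0-100 cm stock
    deadwood_frac: dict[str, float] = field(
        default_factory=lambda: {"tropical": 0.08, "temperate": 0.12, "boreal": 0.16}
    )
    litter_frac: dict[str, float] = field(
        default_factory=lambda: {"tropical": 0.04, "temperate": 0.08, "boreal": 0.12}
    )
    soc_loss_frac: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("cropland", "tropical"): 0.25,
            ("cropland", "temperate"): 0.30,
            ("cropland", "boreal"): 0.30,
            ("pasture", "tropical"): 0.12,
            ("pasture", "temperate"): 0.10,
            ("pasture", "boreal"): 0.10,
            ("forest_plantation", "tropical"): 0.10,
            ("forest_plantation", "temperate"): 0.08,
            ("forest_plantation", "boreal"): 0.08,
        }
    )
    plant_stock: dict[str, float] = field(default_factory=_default_plant_stocks)
    commodity_group: dict[str, str] = field(default_factory=_default_commodity_groups)
    plant_stock_scale: float = 1.0
    c_to_co2: float = C_TO_CO2

    def biome_name(self, biome) -> str:
        if isinstance(biome, str):
            if biome not in BIOMES:
                raise KeyError(f"unknown biome {biome!r}")
            return biome
        try:
            return BIOME_CODES[int(biome)]
        except (KeyError, ValueError):
            raise KeyError(f"unknown biome code {biome!r}") from None

    def plant_stock_for(self, commodity: str) -> float:
        """MgC/ha stock of the replacing commodity, falling back to its group.

        Residual classes carry no replacing vegetation and return 0.
        """
        if commodity in RESIDUAL_CLASSES:
            return 0.0
        if commodity in self.plant_stock:
            return self.plant_stock[commodity]
        group = self.commodity_group.get(commodity, landuse_group_of(commodity))
        if group in self.plant_stock:
            return self.plant_stock[group]
        raise KeyError(
            f"no plant carbon stock for commodity {commodity!r} or its group {group!r}"
        )

    def soc_fraction(self, landuse_group: str, biome) -> float:
        name = self.biome_name(biome)
        if landuse_group == "mixed":
            # provenance-free residual pools: mean over the three groups
            return float(
                np.mean([self.soc_loss_frac[(g, name)] for g in
                         ("cropland", "pasture", "forest_plantation")])
            )
        try:
            return self.soc_loss_frac[(landuse_group, name)]
        except KeyError:
            raise KeyError(
                f"no SOC loss fraction for ({landuse_group!r}, {name!r})"
            ) from None


def pixel_gross_carbon(
    agb,
    rs_ratio,
    biome,
    soc,
    on_peat,
    params: CarbonParams,
    landuse_group: str = "cropland",
) -> dict[str, np.ndarray]:
    """Per-hectare gross carbon components (MgC/ha) for deforested pixels.

    Accepts scalars or aligned arrays.  Vegetation pools are AGB times
    (1, root-to-shoot, deadwood and litter proportions) converted with the
    biomass-to-carbon ratio; the SOC component is a land-use- and
    biome-dependent fraction of the standing 0-100 cm stock, forced to zero
    on peat (drained-peat emissions are booked separately).
    """
    agb = np.asarray(agb, dtype=float)
    rs_ratio = np.asarray(rs_ratio, dtype=float)
    soc = np.asarray(soc, dtype=float)
    on_peat = np.asarray(on_peat, dtype=bool)
    biome_arr = np.asarray(biome)

    b2c = params.biomass_to_carbon
    dw = np.empty_like(agb)
    lit = np.empty_like(agb)
    socf = np.empty_like(agb)
    for code in np.unique(biome_arr):
        name = params.biome_name(code)
        sel = biome_arr == code
        dw[sel] = params.deadwood_frac[name]
        lit[sel] = params.litter_frac[name]
        socf[sel] = params.soc_fraction(landuse_group, name)

    components = {
        "agb": agb * b2c,
        "bgb": agb * rs_ratio * b2c,
        "deadwood": agb * dw * b2c,
        "litter": agb * lit * b2c,
        "soc": np.where(on_peat, 0.0, socf * soc),
    }
    return components


def net_emissions(
    gross_components_MgC: Mapping[str, float],
    commodity: str,
    area_ha: float,
    params: CarbonParams,
) -> dict[str, float]:
    """Build one emission record (MgCO2) from aggregated gross carbon.

    ``gross_components_MgC`` holds total MgC per component over ``area_ha``.
    The replacing commodity's mature plant stock (scaled by
    ``plant_stock_scale``) is deducted over the same area.  Net emissions may
    be negative when the replacing stock exceeds the forest carbon; they are
    reported as computed so that totals stay conservative.
    """
    comp_co2 = {k: float(v) * params.c_to_co2 for k, v in gross_components_MgC.items()}
    gross = sum(comp_co2.values())
    deduction = (
        params.plant_stock_for(commodity) * params.plant_stock_scale
        * float(area_ha) * params.c_to_co2
    )
    record = dict(comp_co2)
    record["gross_MgCO2"] = gross
    record["net_MgCO2"] = gross - deduction
    return record


def apportion_statistical_emissions(
    pool_emissions: float, allocations: Mapping[str, float]
) -> dict[str, float]:
    """Split a pool's emissions across commodities proportionally to area.

    Conserves the pool total exactly: each commodity bears the same share of
    emissions as of the pool's deforested area.
    """
    total_area = float(sum(allocations.values()))
    if total_area <= 0.0:
        if pool_emissions != 0.0:
            raise ValueError("zero pool area with nonzero pool emissions")
        return {k: 0.0 for k in allocations}
    return {
        k: float(pool_emissions) * float(a) / total_area for k, a in allocations.items()
    }
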