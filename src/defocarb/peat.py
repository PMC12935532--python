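"""Peatland drainage emissions.

Deforestation on peat soils triggers drainage, and the drained peat keeps
oxidizing: a fixed per-hectare annual CO2 flux (an emission factor specific
to the replacing land use and the biome) accrues every year from the
deforestation event until the accounting horizon.  Only post-2000
deforestation cohorts are tracked; peat converted earlier is outside the
accounting boundary.  The deforestation year itself accrues a full year, so
a hectare drained in 2010 and accounted until 2022 accrues 13 annual
charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import BIOME_CODES, landuse_group_of

PEAT_GROUPS = ("cropland", "pasture", "forest_plantation", "oil_palm")

#: Default drainage emission factors, MgCO2/ha/yr, by (land-use group, biome).
#: Tropical oil palm carries the canonical 54.41 value; the remaining cells
#: follow wetland-supplement-style magnitudes and are configuration inputs.
DEFAULT_EMISSION_FACTORS: dict[tuple[str, str], float] = {
    ("oil_palm", "tropical"): 54.41,
    ("cropland", "tropical"): 51.33,
    ("pasture", "tropical"): 29.33,
    ("forest_plantation", "tropical"): 44.0,
    ("oil_palm", "temperate"): 28.93,
    ("cropland", "temperate"): 28.93,
    ("pasture", "temperate"): 21.27,
    ("forest_plantation", "temperate"): 9.53,
    ("oil_palm", "boreal"): 28.93,
    ("cropland", "boreal"): 28.93,
    ("pasture", "boreal"): 20.9,
    ("forest_plantation", "boreal"): 2.57,
}


@dataclass
class EmissionFactorTable:
    factors: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EMISSION_FACTORS)
    )

    def __post_init__(self):
        for (group, biome), ef in self.factors.items():
            if ef < 0:
                raise ValueError(f"negative emission factor for ({group}, {biome})")

    def lookup(self, commodity: str, biome) -> float:
        """Factor for a commodity: oil palm has its own row, other crops use
        the cropland row of their biome."""
        name = biome if isinstance(biome, str) else BIOME_CODES[int(biome)]
        group = "oil_palm" if commodity == "oil_palm" else landuse_group_of(commodity)
        try:
            return self.factors[(group, name)]
        except KeyError:
            raise KeyError(f"no emission factor for ({group!r}, {name!r})") from None


def allocate_peat_area(area_ha: float, commodities) -> dict[str, float]:
    """Evenly split spatially unresolved peat deforestation across the
    commodities identified as expanding in that region-year.

    An empty set leaves the area under the residual class.
    """
    commodities = sorted(set(commodities))
    if area_ha < 0:
        raise ValueError("negative peat area")
    if not commodities:
        return {"unallocated": float(area_ha)}
    share = float(area_ha) / len(commodities)
    return {c: share for c in commodities}


def accrual_years(defo_year: int, horizon, year_end: int) -> int:
    """Number of annual drainage charges for a deforestation cohort.

    ``horizon`` is ``"until_end"`` (accrue to the end of the study window),
    ``"none"`` (no accumulation), or an integer number of years from the
    deforestation event.  The deforestation year counts as a full year.
    """
    if defo_year > year_end:
        return 0
    if horizon == "none":
        return 0
    if horizon == "until_end":
        return year_end - defo_year + 1
    try:
        h = int(horizon)
    except (TypeError, ValueError):
        raise ValueError(f"unknown accumulation horizon {horizon!r}") from None
    if h < 0:
        raise ValueError("horizon must be non-negative")
    return min(year_end, defo_year + h - 1) - defo_year + 1 if h > 0 else 0


def accumulate_emissions(
    records: pd.DataFrame,
    ef_table: EmissionFactorTable,
    horizon,
    year_end: int,
) -> pd.DataFrame:
    """Attach annual and accumulated drainage emissions to peat cohorts.

    ``records`` needs columns region, commodity, year (deforestation year),
    biome and peat_area_ha; one row per cohort.  Output adds the emission
    factor, annual flux, accrual years and the accumulated total
    (area x factor x accrual years — linear in both area and years).
    """
    out = records.copy()
    if out.empty:
        for col in ("ef_MgCO2_ha_yr", "annual_MgCO2", "accrual_years",
                    "accumulated_MgCO2"):
            out[col] = pd.Series(dtype=float)
        return out
    out["ef_MgCO2_ha_yr"] = [
        ef_table.lookup(c, b) for c, b in zip(out["commodity"], out["biome"])
    ]
    out["annual_MgCO2"] = out["peat_area_ha"] * out["ef_MgCO2_ha_yr"]
    out["accrual_years"] = [
        accrual_years(int(y), horizon, int(year_end)) for y in out["year"]
    ]
    out["accumulated_MgCO2"] = out["annual_MgCO2"] * out["accrual_years"]
    return out
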