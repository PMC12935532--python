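"""Synthetic landscapes with embedded, recoverable ground truth.

The generator builds the full input bundle — aligned raster stack, dataset
registry and a self-consistent agricultural-statistics table — for a world
in which every commodity conversion is known exactly.  Conversion events
are clustered rectangles (frontier-like patches) placed on natural forest;
each cluster carries one loss year and one replacing commodity.  Spatial
evidence degrades controllably: a commodity map covers converted pixels
with probability ``spatial_coverage`` (observed with a detection delay),
uncovered pixels may fall to a static land-use map, to a cropland/pasture
mosaic label, or only to the dominant-driver map; commodity labels can be
swapped (classification noise) without ever breaking area conservation.
Statistics tables are built from the true conversions, so land-use and
harvested-area expansions equal the truth and the statistical land balance
can recover commodity totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import CarbonParams, landuse_group_of, pixel_gross_carbon
from .io_registry import AgStatsTable, DatasetDescriptor, GridSpec, Layer, LayerStack

DRIVER_CODES = {1: "commodity_driven", 2: "forestry", 3: "shifting_agriculture",
                4: "other"}
LANDUSE_CODES = {1: "cropland", 2: "pasture", 3: "forest_plantation"}
MOSAIC_CODES = {1: "cropland_pasture_mosaic"}


def _default_mix() -> dict[str, float]:
    return {
        "soy": 0.25,
        "maize": 0.15,
        "oil_palm": 0.20,
        "cocoa": 0.10,
        "cattle_meat_leather": 0.20,
        "forestry_products": 0.10,
    }


@dataclass
class LandscapeParams:
    """Knobs of the synthetic world; the defaults are the study conditions
    used throughout the test suite."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(64, 64))
    regions: int = 2
    commodity_mix: dict[str, float] = field(default_factory=_default_mix)
    spatial_coverage: float = 0.9
    landuse_coverage: float = 0.8
    mosaic_fraction: float = 0.1
    fire_fraction: float = 0.05
    peat_fraction: float = 0.1
    noise: float = 0.0
    forest_fraction: float = 0.7
    loss_fraction: float = 0.25
    rotational_fraction: float = 0.15
    plantation_fraction: float = 0.05
    cluster_size: int = 4
    obs_delay_max: int = 2
    biome_by_region: dict[int, int] | None = None  # region code -> biome code
    stats_flag: str = "official"
    stats_lead_years: int = 5  # statistics start this many years before the window
    seed: int = 0

    def __post_init__(self):
        for name in ("spatial_coverage", "landuse_coverage", "mosaic_fraction",
                     "fire_fraction", "peat_fraction", "noise",
                     "forest_fraction", "loss_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        total = sum(self.commodity_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"commodity shares must sum to 1 (got {total})")

    @property
    def crops(self) -> list[str]:
        return [c for c in self.commodity_mix
                if landuse_group_of(c) == "cropland"]


@dataclass
class GroundTruth:
    """Exact per-(region, commodity, year) outcomes recorded at generation.

    ``table`` columns: region, commodity, year, area_ha, gross_MgCO2,
    net_MgCO2, peat_area_ha.  ``n_converted_pixels`` ties the totals to the
    raster: sum(area_ha) = n_converted_pixels * pixel_area_ha exactly.
    """

    table: pd.DataFrame
    n_converted_pixels: int

    def commodity_shares(self) -> pd.Series:
        per = self.table.groupby("commodity")["area_ha"].sum()
        return per / per.sum()


@dataclass
class Landscape:
    stack: LayerStack
    registry: list[DatasetDescriptor]
    stats: AgStatsTable
    truth: GroundTruth
    params: LandscapeParams


def _place_clusters(rng, eligible: np.ndarray, target: int, cluster_size: int
                    ) -> list[np.ndarray]:
    """Greedily place random rectangles on eligible cells until ``target``
    pixels are covered; returns one flat-index array per cluster."""
    n_rows, n_cols = eligible.shape
    taken = np.zeros_like(eligible, dtype=bool)
    clusters: list[np.ndarray] = []
    covered = 0
    attempts = 0
    max_attempts = 50 * max(1, target)
    while covered < target and attempts < max_attempts:
        attempts += 1
        h = int(rng.integers(1, 2 * cluster_size + 1))
        w = int(rng.integers(1, 2 * cluster_size + 1))
        r0 = int(rng.integers(0, max(1, n_rows - h + 1)))
        c0 = int(rng.integers(0, max(1, n_cols - w + 1)))
        block = np.zeros_like(eligible, dtype=bool)
        block[r0:r0 + h, c0:c0 + w] = True
        block &= eligible & ~taken
        idx = np.flatnonzero(block)
        if idx.size == 0:
            continue
        if covered + idx.size > target:
            idx = idx[: target - covered]
        taken.flat[idx] = True
        clusters.append(idx)
        covered += idx.size
    return clusters


def generate_landscape(
    params: LandscapeParams, carbon_params: CarbonParams | None = None
) -> Landscape:
    """Build one landscape; identical parameters and seed give bit-identical
    outputs."""
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    shape = grid.shape
    n_pix = grid.n_rows * grid.n_cols
    carbon_params = carbon_params or CarbonParams()

    # --- structural layers -------------------------------------------------
    region = np.ones(shape, dtype=float)
    bounds = np.linspace(0, grid.n_cols, params.regions + 1).astype(int)
    for r in range(params.regions):
        region[:, bounds[r]:bounds[r + 1]] = r + 1

    biome_map = params.biome_by_region or {r + 1: 1 for r in range(params.regions)}
    biome = np.vectorize(lambda r: biome_map.get(int(r), 1))(region).astype(float)

    plantation = (rng.random(shape) < params.plantation_fraction).astype(float)
    forest_core = (rng.random(shape) < params.forest_fraction) & (plantation == 0)
    density = np.where(
        forest_core,
        rng.uniform(25.0, 100.0, shape),
        rng.uniform(0.0, 24.9, shape),
    )
    natural_forest = (density >= 25.0) & (plantation == 0)

    peat = (rng.random(shape) < params.peat_fraction).astype(float)

    agb_range = {1: (100.0, 400.0), 2: (50.0, 250.0), 3: (30.0, 150.0)}
    agb = np.empty(shape)
    for code, (lo, hi) in agb_range.items():
        sel = biome == code
        agb[sel] = rng.uniform(lo, hi, int(sel.sum()))
    rs_ratio = rng.uniform(0.18, 0.28, shape)
    soc = rng.uniform(80.0, 200.0, shape)

    # --- conversion, fire and rotational events ----------------------------
    years = np.array(list(grid.years))
    commodities = list(params.commodity_mix)
    mix = np.array([params.commodity_mix[c] for c in commodities])

    n_forest = int(natural_forest.sum())
    n_conv = int(round(params.loss_fraction * n_forest))
    conv_clusters = _place_clusters(rng, natural_forest, n_conv,
                                    params.cluster_size)
    conv_idx = (np.concatenate(conv_clusters) if conv_clusters
                else np.array([], dtype=int))
    n_conv = conv_idx.size

    loss_year = np.zeros(shape)
    fire_year = np.zeros(shape)
    true_commodity = np.full(shape, "", dtype=object)
    for idx in conv_clusters:
        y = int(rng.choice(years))
        c = commodities[int(rng.choice(len(commodities), p=mix))]
        loss_year.flat[idx] = y
        for i in idx:
            true_commodity.flat[i] = c

    # non-commodity fire on natural forest, disjoint from conversions
    converted = np.zeros(shape, dtype=bool)
    converted.flat[conv_idx] = True
    if params.fire_fraction > 0:
        n_fire = int(round(params.fire_fraction / (1 - params.fire_fraction)
                           * n_conv))
        fire_clusters = _place_clusters(rng, natural_forest & ~converted,
                                        n_fire, params.cluster_size)
        for idx in fire_clusters:
            y = int(rng.choice(years))
            loss_year.flat[idx] = y
            fire_year.flat[idx] = y

    # rotational clearing / degradation: loss outside natural forest
    n_rot = int(round(params.rotational_fraction * n_conv))
    rot_clusters = _place_clusters(rng, ~natural_forest, n_rot,
                                   params.cluster_size)
    for idx in rot_clusters:
        loss_year.flat[idx] = int(rng.choice(years))

    # --- spatial evidence layers -------------------------------------------
    crop_codes = {c: i + 1 for i, c in enumerate(commodities)}
    commod = np.zeros(shape)
    commod_year = np.zeros(shape)
    landuse = np.zeros(shape)
    mosaic = np.zeros(shape)
    driver = np.zeros(shape)

    for i in conv_idx:
        c = true_commodity.flat[i]
        group = landuse_group_of(c)
        driver.flat[i] = 2 if group == "forest_plantation" else 1
        if rng.random() < params.spatial_coverage:
            label = c
            if params.noise > 0 and rng.random() < params.noise:
                others = [o for o in commodities if o != c]
                label = others[int(rng.choice(len(others)))]
            commod.flat[i] = crop_codes[label]
            delay = int(rng.integers(0, params.obs_delay_max + 1)) \
                if params.obs_delay_max > 0 else 0
            commod_year.flat[i] = loss_year.flat[i] + delay
        elif (group in ("cropland", "pasture")
              and rng.random() < params.mosaic_fraction):
            mosaic.flat[i] = 1
        elif rng.random() < params.landuse_coverage:
            landuse.flat[i] = {"cropland": 1, "pasture": 2,
                               "forest_plantation": 3}[group]
    # fire pixels also appear in the driver map: agriculture must still win
    driver[(fire_year > 0)] = 1

    stack = LayerStack(grid, [
        Layer("density", "continuous", density),
        Layer("loss_year", "year", loss_year),
        Layer("plantation", "mask", plantation),
        Layer("fire_year", "year", fire_year),
        Layer("peat", "mask", peat),
        Layer("region", "categorical", region),
        Layer("biome", "categorical", biome),
        Layer("agb", "continuous", agb),
        Layer("rs_ratio", "continuous", rs_ratio),
        Layer("soc", "continuous", soc),
        Layer("commod", "categorical", commod),
        Layer("commod__year", "year",
              np.clip(commod_year, 0, grid.year_end + params.obs_delay_max)),
        Layer("landuse", "categorical", landuse),
        Layer("mosaic", "categorical", mosaic),
        Layer("driver", "categorical", driver),
    ])
    # observation years may legitimately overrun the window; keep kind "year"
    # but bypass window validation by storing as continuous
    stack["commod__year"].kind = "continuous"

    registry = [
        DatasetDescriptor("commod", "commodity",
                          {v: k for k, v in crop_codes.items()},
                          overall_accuracy=0.92, spatial_score=1.0,
                          temporal_score=0.75, explicitness_score=1.0,
                          last_valid_year=grid.year_end + params.obs_delay_max,
                          annual=True),
        DatasetDescriptor("landuse", "land_use", dict(LANDUSE_CODES),
                          overall_accuracy=0.85, spatial_score=0.75,
                          temporal_score=0.75, explicitness_score=0.5,
                          last_valid_year=grid.year_end),
        DatasetDescriptor("mosaic", "mosaic", dict(MOSAIC_CODES),
                          overall_accuracy=0.80, spatial_score=0.75,
                          temporal_score=0.5, explicitness_score=0.25,
                          last_valid_year=grid.year_end),
        DatasetDescriptor("driver", "driver", dict(DRIVER_CODES),
                          overall_accuracy=0.80, spatial_score=0.25,
                          temporal_score=0.25, explicitness_score=0.25,
                          last_valid_year=grid.year_end),
        DatasetDescriptor("fire", "fire", {1: "fire"}, overall_accuracy=0.90,
                          spatial_score=0.75, temporal_score=1.0,
                          explicitness_score=0.5,
                          last_valid_year=grid.year_end),
        DatasetDescriptor("loss", "loss", {1: "loss"}, overall_accuracy=0.99,
                          spatial_score=1.0, temporal_score=1.0,
                          explicitness_score=0.25,
                          last_valid_year=grid.year_end),
    ]

    # --- ground truth -------------------------------------------------------
    flat_region = region.ravel().astype(int)
    flat_year = loss_year.ravel().astype(int)
    comps = pixel_gross_carbon(
        agb.ravel()[conv_idx], rs_ratio.ravel()[conv_idx],
        biome.ravel()[conv_idx], soc.ravel()[conv_idx],
        peat.ravel()[conv_idx].astype(bool), carbon_params, "cropland",
    )
    # SOC fraction depends on the true replacing land use: recompute per pixel
    veg_c = comps["agb"] + comps["bgb"] + comps["deadwood"] + comps["litter"]
    records = []
    pa = grid.pixel_area_ha
    for k, i in enumerate(conv_idx):
        c = true_commodity.flat[i]
        group = landuse_group_of(c)
        b = carbon_params.biome_name(biome.flat[i])
        on_peat = bool(peat.flat[i])
        soc_loss = 0.0 if on_peat else carbon_params.soc_fraction(group, b) \
            * soc.flat[i]
        gross_c_ha = veg_c[k] + soc_loss
        records.append({
            "region": str(flat_region[i]),
            "commodity": c,
            "year": flat_year[i],
            "area_ha": pa,
            "gross_MgC": gross_c_ha * pa,
            "peat_area_ha": pa if on_peat else 0.0,
        })
    if records:
        truth_df = (
            pd.DataFrame(records)
            .groupby(["region", "commodity", "year"], as_index=False)
            .sum()
        )
    else:
        truth_df = pd.DataFrame(
            columns=["region", "commodity", "year", "area_ha", "gross_MgC",
                     "peat_area_ha"]
        )
    truth_df["gross_MgCO2"] = truth_df["gross_MgC"] * carbon_params.c_to_co2
    truth_df["net_MgCO2"] = truth_df["gross_MgCO2"] - [
        carbon_params.plant_stock_for(c) * carbon_params.plant_stock_scale
        * a * carbon_params.c_to_co2
        for c, a in zip(truth_df["commodity"], truth_df["area_ha"])
    ]
    truth_df = truth_df.drop(columns=["gross_MgC"])
    truth = GroundTruth(table=truth_df, n_converted_pixels=int(n_conv))

    stats = _build_stats(params, truth_df)
    return Landscape(stack=stack, registry=registry, stats=stats, truth=truth,
                     params=params)


def _build_stats(params: LandscapeParams, truth_df: pd.DataFrame) -> AgStatsTable:
    """Statistics exactly consistent with the true conversions: land-use and
    harvested areas grow by each year's converted area on top of a constant
    base, so windowed gross expansions equal the truth."""
    grid = params.grid
    years = range(grid.year_start - params.stats_lead_years, grid.year_end + 1)
    base_landuse = {"cropland": 1000.0, "pasture": 1500.0,
                    "forest_plantation": 300.0}
    crops = params.crops
    base_crop = {c: 0.8 * base_landuse["cropland"] / max(1, len(crops))
                 for c in crops}

    rows = []
    for r in range(1, params.regions + 1):
        sub = truth_df[truth_df["region"] == str(r)]
        conv_lu = {lu: {} for lu in base_landuse}
        conv_crop = {c: {} for c in crops}
        for _, row in sub.iterrows():
            group = landuse_group_of(row["commodity"])
            y = int(row["year"])
            conv_lu[group][y] = conv_lu[group].get(y, 0.0) + row["area_ha"]
            if row["commodity"] in conv_crop:
                conv_crop[row["commodity"]][y] = (
                    conv_crop[row["commodity"]].get(y, 0.0) + row["area_ha"]
                )
        for y in years:
            for lu, base in base_landuse.items():
                cum = sum(a for yy, a in conv_lu[lu].items() if yy <= y)
                rows.append((str(r), y, f"{lu}_area", base + cum,
                             params.stats_flag))
            for c in crops:
                cum = sum(a for yy, a in conv_crop[c].items() if yy <= y)
                rows.append((str(r), y, f"harvested_{c}", base_crop[c] + cum,
                             params.stats_flag))
    return AgStatsTable(
        pd.DataFrame(rows, columns=["region", "year", "variable", "value",
                                    "flag"])
    )


def degrade_to_statistical(
    landscape: Landscape, truncate_year: int | None = None
) -> Landscape:
    """Remove (or truncate) commodity-level evidence so attribution must
    fall back to the statistical land balance."""
    stack = landscape.stack.copy()
    registry = []
    for desc in landscape.registry:
        if desc.level != "commodity":
            registry.append(desc)
            continue
        if truncate_year is None:
            stack.drop(desc.id)
            stack.drop(f"{desc.id}__year")
        else:
            from dataclasses import replace

            registry.append(replace(desc, last_valid_year=truncate_year))
    return Landscape(stack=stack, registry=registry, stats=landscape.stats,
                     truth=landscape.truth, params=landscape.params)
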