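"""End-to-end pipeline: attribution, land balance, emissions, peat, IQI.

The stages are pure functions over in-memory tables; `run_pipeline` wires
them together and enforces conservation at every hand-off (every loss pixel
lands in exactly one class; statistical allocation redistributes pool areas
and emissions without creating or destroying any; peat SOC is never
double-counted).  Residual classes — deforestation without matching
production, and pools that no statistic could allocate — are carried as
explicit rows, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import carbon as carbon_mod
from . import peat as peat_mod
from . import quality as quality_mod
from . import statistical as stat_mod
from .carbon import CarbonParams, landuse_group_of
from .io_registry import (
    AgStatsTable,
    ConfigBundle,
    DatasetDescriptor,
    GridSpec,
    LayerStack,
    validate_stack,
)
from .spatial import (
    AttributionSummary,
    PixelAttribution,
    attribute_pixels,
    summarize_attribution,
)

MG_TO_MT = 1e-6

#: AttributionSummary label/level -> statistical pool
_POOL_OF = {
    ("cropland", "land_use"): "cropland_only",
    ("pasture", "land_use"): "pasture_only",
    ("forest_plantation", "land_use"): "plantation_only",
    ("cropland_pasture_mosaic", "mosaic"): "cropland_pasture_mosaic",
    ("unresolved_agriculture", "driver"): "unresolved_agriculture",
    ("forest_plantation", "driver"): "plantation_only",
    ("unattributed", "none"): "unresolved_agriculture",
}

_LU_COMMODITY = {"pasture": "cattle_meat_leather",
                 "forest_plantation": "forestry_products"}


class _FifoBudget:
    """Expansion budget made of positive year-on-year increments, consumed
    oldest-first so overlapping backward lag windows never hand the same
    reported expansion to two deforestation cohorts."""

    def __init__(self, series: pd.Series):
        self.increments: dict[int, float] = {}
        if series is not None and len(series) > 1:
            diffs = series.sort_index().diff().dropna()
            for y, d in diffs.items():
                if d > 0:
                    self.increments[int(y)] = float(d)
        self.consumed: dict[int, float] = {}
        self.empty = not self.increments and (series is None or series.empty)

    def _window(self, year: int, lag: int) -> list[int]:
        return [y for y in sorted(self.increments)
                if year - lag + 1 <= y <= year]

    def available(self, year: int, lag: int) -> float:
        return sum(
            max(0.0, self.increments[y] - self.consumed.get(y, 0.0))
            for y in self._window(year, lag)
        )

    def consume(self, year: int, lag: int, amount: float) -> None:
        for y in self._window(year, lag):
            if amount <= 0:
                break
            free = self.increments[y] - self.consumed.get(y, 0.0)
            take = min(free, amount)
            if take > 0:
                self.consumed[y] = self.consumed.get(y, 0.0) + take
                amount -= take
        # any remainder exceeded the budget (restriction off); nothing to book


def _crop_budgets(stats: AgStatsTable, region: str, config: ConfigBundle
                  ) -> dict[str, _FifoBudget]:
    series = stat_mod.harvested_series(stats, region, config.multicropping)
    return {c: _FifoBudget(s) for c, s in series.items()}


def _crop_share_vector(
    crop_budgets: dict[str, _FifoBudget],
    stats: AgStatsTable,
    region: str,
    year: int,
    config: ConfigBundle,
) -> dict[str, float] | None:
    """Normalized crop shares for this region-year's cropland allocation;
    None when no crop shows remaining expansion."""
    lag = config.statistical_lag_years
    if config.expansion_mode == "gross":
        remaining = {c: b.available(year, lag) for c, b in crop_budgets.items()}
    else:
        remaining = stat_mod.crop_expansions(
            stats, region, year, lag, config.expansion_mode,
            config.multicropping,
        )
    total = sum(v for v in remaining.values() if v > 0)
    if total <= 0:
        return None
    return {c: v / total for c, v in remaining.items() if v > 0}


@dataclass
class PipelineResult:
    summary: AttributionSummary
    allocation: pd.DataFrame
    emissions: pd.DataFrame
    peat: pd.DataFrame
    footprint: pd.DataFrame
    config: ConfigBundle
    checks: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.rows.to_csv(out / "attribution.csv", index=False)
        self.summary.totals.to_csv(out / "attribution_totals.csv", index=False)
        self.allocation.to_csv(out / "allocation.csv", index=False)
        self.emissions.to_csv(out / "emissions.csv", index=False)
        self.peat.to_csv(out / "peat.csv", index=False)
        self.footprint.to_csv(out / "footprint.csv", index=False)


def _pixel_table(
    stack: LayerStack, attribution: PixelAttribution, params: CarbonParams
) -> pd.DataFrame:
    """Flat per-pixel table for all class-attributed loss pixels, with
    vegetation carbon and (non-peat) SOC stock per pixel."""
    grid = stack.grid
    has = attribution.codes >= 0
    if not has.any():
        return pd.DataFrame(
            columns=["region", "year", "code", "biome", "area_ha", "veg_MgC",
                     "soc_stock_MgC", "peat_area_ha"]
        )
    pa = grid.pixel_area_ha
    biome = stack["biome"].values[has]
    agb = stack["agb"].values[has] if "agb" in stack else np.zeros(has.sum())
    rs = stack["rs_ratio"].values[has] if "rs_ratio" in stack else np.zeros(has.sum())
    soc = stack["soc"].values[has] if "soc" in stack else np.zeros(has.sum())
    on_peat = (stack["peat"].values[has] == 1) if "peat" in stack \
        else np.zeros(has.sum(), dtype=bool)

    b2c = params.biomass_to_carbon
    dw = np.zeros_like(agb)
    lit = np.zeros_like(agb)
    for code in np.unique(biome):
        name = params.biome_name(code)
        sel = biome == code
        dw[sel] = params.deadwood_frac[name]
        lit[sel] = params.litter_frac[name]
    veg_c_ha = agb * (1.0 + rs + dw + lit) * b2c

    return pd.DataFrame({
        "region": [str(int(r)) for r in stack["region"].values[has]],
        "year": stack["loss_year"].values[has].astype(int),
        "code": attribution.codes[has],
        "biome": biome.astype(int),
        "area_ha": pa,
        "veg_MgC": veg_c_ha * pa,
        "soc_stock_MgC": np.where(on_peat, 0.0, soc * pa),
        "peat_area_ha": np.where(on_peat, pa, 0.0),
    })


def run_pipeline(
    stack: LayerStack,
    registry: list[DatasetDescriptor],
    stats: AgStatsTable,
    config: ConfigBundle | None = None,
) -> PipelineResult:
    """Execute attribution -> statistics -> carbon -> peat -> IQI -> report.

    Deterministic given inputs and configuration.  Raises on a failing
    validation report before touching any stage.
    """
    config = config or ConfigBundle()
    grid = stack.grid
    report = validate_stack(stack, registry, grid)
    if not report.ok:
        raise ValueError(f"input validation failed:\n{report}")
    params = config.carbon
    by_id = {d.id: d for d in registry}

    attribution = attribute_pixels(stack, registry, config)
    summary = summarize_attribution(attribution, stack["region"],
                                    stack["loss_year"], grid)
    summary.check_invariants()
    # region codes as strings, matching the statistics table
    summary.rows["region"] = summary.rows["region"].astype(int).astype(str)
    summary.totals["region"] = summary.totals["region"].astype(int).astype(str)

    px = _pixel_table(stack, attribution, params)
    classes = attribution.classes
    px["label"] = [classes[c].label for c in px["code"]]
    px["level"] = [classes[c].level for c in px["code"]]
    px["source_id"] = [classes[c].source_id for c in px["code"]]

    defo = px[~px["label"].isin(
        ("degradation_rotation", "fire_non_commodity", "non_commodity_other")
    )].copy()

    # ------------------------------------------------------------------
    # spatial commodity estimates (dLUC)
    spatial = defo[defo["level"] == "commodity"]
    spatial_rows = []
    if not spatial.empty:
        grouped = spatial.groupby(
            ["region", "year", "label", "source_id", "biome"], as_index=False
        )[["area_ha", "veg_MgC", "soc_stock_MgC", "peat_area_ha"]].sum()
        for _, g in grouped.iterrows():
            group = landuse_group_of(g["label"])
            socf = params.soc_fraction(group, int(g["biome"]))
            spatial_rows.append({
                "region": g["region"], "year": int(g["year"]),
                "commodity": g["label"], "source_id": g["source_id"],
                "biome": int(g["biome"]), "mode": "spatial",
                "area_ha": g["area_ha"], "veg_MgC": g["veg_MgC"],
                "soc_loss_MgC": socf * g["soc_stock_MgC"],
                "peat_area_ha": g["peat_area_ha"],
            })
    spatial_df = pd.DataFrame(spatial_rows)

    # ------------------------------------------------------------------
    # statistical land balance over the remaining pools.  Region-years are
    # processed chronologically with FIFO budget tracking: every positive
    # year-on-year expansion increment can absorb deforestation (spatial or
    # statistical) only once, even though backward lag windows overlap.
    pools_px = defo[defo["level"] != "commodity"].copy()
    if not pools_px.empty:
        pools_px["pool"] = [
            _POOL_OF[(lab, lev)] for lab, lev in
            zip(pools_px["label"], pools_px["level"])
        ]
    lag = config.statistical_lag_years
    budgets: dict[str, tuple] = {}

    def _region_budgets(region: str):
        if region not in budgets:
            lu_b = {
                lu: _FifoBudget(stats.series(region, f"{lu}_area"))
                for lu in ("cropland", "pasture", "forest_plantation")
            }
            crop_b = _crop_budgets(stats, region, config)
            budgets[region] = (lu_b, crop_b)
        return budgets[region]

    years_seen = sorted(
        set(pools_px["year"]) | (set(spatial_df["year"])
                                 if not spatial_df.empty else set())
    )
    regions_seen = sorted(
        set(pools_px["region"]) | (set(spatial_df["region"])
                                   if not spatial_df.empty else set())
    )
    allocation_rows = []
    for year in years_seen:
        year = int(year)
        for region in regions_seen:
            lu_b, crop_b = _region_budgets(region)
            # spatial commodity attributions consume their expansion first
            spatial_ry = spatial_df[
                (spatial_df["region"] == region) & (spatial_df["year"] == year)
            ] if not spatial_df.empty else pd.DataFrame(
                columns=["commodity", "area_ha"])
            for _, row in spatial_ry.iterrows():
                lu = landuse_group_of(row["commodity"])
                lu_b[lu].consume(year, lag, row["area_ha"])
                if lu == "cropland" and row["commodity"] in crop_b:
                    crop_b[row["commodity"]].consume(year, lag, row["area_ha"])

            sub = pools_px[(pools_px["region"] == region)
                           & (pools_px["year"] == year)] \
                if not pools_px.empty else pd.DataFrame()
            if sub.empty:
                continue
            pools = sub.groupby("pool")["area_ha"].sum().to_dict()
            if config.expansion_mode == "gross":
                if all(b.empty for b in lu_b.values()):
                    expansions = None
                else:
                    expansions = {lu: b.available(year, lag)
                                  for lu, b in lu_b.items()}
            else:
                expansions = stat_mod.landuse_expansions(
                    stats, region, year, lag, config.expansion_mode
                )
            lu_alloc = stat_mod.allocate_landuse(pools, expansions, config)
            crop_shares = "unset"
            for _, arow in lu_alloc.iterrows():
                target, pool, area = arow["target"], arow["pool"], arow["area_ha"]
                if target in (stat_mod.RESIDUAL_WITHOUT_PRODUCTION,
                              stat_mod.RESIDUAL_UNALLOCATED):
                    allocation_rows.append((region, year, pool, target, target,
                                            area))
                    continue
                lu_b[target].consume(year, lag, area)
                if target == "cropland":
                    if crop_shares == "unset":
                        crop_shares = _crop_share_vector(
                            crop_b, stats, region, year, config
                        )
                    if crop_shares is None:
                        allocation_rows.append((region, year, pool, "cropland",
                                                stat_mod.RESIDUAL_UNALLOCATED,
                                                area))
                    else:
                        for crop, share in crop_shares.items():
                            crop_amount = area * share
                            if crop in crop_b:
                                crop_b[crop].consume(year, lag, crop_amount)
                            allocation_rows.append((region, year, pool,
                                                    "cropland", crop,
                                                    crop_amount))
                else:
                    allocation_rows.append(
                        (region, year, pool, target, _LU_COMMODITY[target],
                         area)
                    )
    allocation = pd.DataFrame(
        allocation_rows,
        columns=["region", "year", "pool", "land_use", "commodity", "area_ha"],
    )

    # ------------------------------------------------------------------
    # emissions: pool aggregates by biome, shared proportionally
    pool_agg = (
        pools_px.groupby(["region", "year", "pool", "biome"], as_index=False)
        [["area_ha", "veg_MgC", "soc_stock_MgC", "peat_area_ha"]].sum()
        if not pools_px.empty else pd.DataFrame(
            columns=["region", "year", "pool", "biome", "area_ha", "veg_MgC",
                     "soc_stock_MgC", "peat_area_ha"])
    )
    pool_src = (
        pools_px.groupby(["region", "year", "pool", "source_id"], dropna=False,
                         as_index=False)["area_ha"].sum()
        if not pools_px.empty else pd.DataFrame(
            columns=["region", "year", "pool", "source_id", "area_ha"])
    )

    stat_rows = []
    for _, arow in allocation.iterrows():
        region, year, pool = arow["region"], int(arow["year"]), arow["pool"]
        commodity, area = arow["commodity"], arow["area_ha"]
        agg = pool_agg[
            (pool_agg["region"] == region) & (pool_agg["year"] == year)
            & (pool_agg["pool"] == pool)
        ]
        pool_area = agg["area_ha"].sum()
        frac = area / pool_area if pool_area > 0 else 0.0
        if commodity in carbon_mod.RESIDUAL_CLASSES:
            group = "mixed"
        else:
            group = landuse_group_of(commodity)
        veg = frac * agg["veg_MgC"].sum()
        soc_loss = frac * sum(
            params.soc_fraction(group, int(b)) * s
            for b, s in zip(agg["biome"], agg["soc_stock_MgC"])
        )
        stat_rows.append({
            "region": region, "year": year, "commodity": commodity,
            "source_id": pool, "mode": "statistical", "area_ha": area,
            "veg_MgC": veg, "soc_loss_MgC": soc_loss,
        })
    stat_df = pd.DataFrame(stat_rows)

    pieces = [df for df in (spatial_df, stat_df) if not df.empty]
    detail = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["region", "year", "commodity", "source_id", "mode", "area_ha",
                 "veg_MgC", "soc_loss_MgC"]
    )

    emissions = (
        detail.groupby(["region", "year", "commodity"], as_index=False)
        [["area_ha", "veg_MgC", "soc_loss_MgC"]].sum()
        if not detail.empty else pd.DataFrame(
            columns=["region", "year", "commodity", "area_ha", "veg_MgC",
                     "soc_loss_MgC"])
    )
    if not emissions.empty:
        emissions["gross_MgCO2"] = (
            (emissions["veg_MgC"] + emissions["soc_loss_MgC"]) * params.c_to_co2
        )
        emissions["plant_deduction_MgCO2"] = [
            params.plant_stock_for(c) * params.plant_stock_scale * a
            * params.c_to_co2
            for c, a in zip(emissions["commodity"], emissions["area_ha"])
        ]
        emissions["net_MgCO2"] = (
            emissions["gross_MgCO2"] - emissions["plant_deduction_MgCO2"]
        )
    else:
        for col in ("gross_MgCO2", "plant_deduction_MgCO2", "net_MgCO2"):
            emissions[col] = pd.Series(dtype=float)

    # ------------------------------------------------------------------
    # peatland drainage
    peat_rows = []
    if not spatial_df.empty:
        for _, g in spatial_df.iterrows():
            if g["peat_area_ha"] > 0:
                peat_rows.append({
                    "region": g["region"], "year": int(g["year"]),
                    "commodity": g["commodity"], "biome": int(g["biome"]),
                    "peat_area_ha": g["peat_area_ha"], "mode": "direct",
                })
    if not pools_px.empty:
        pool_peat = pool_agg[pool_agg["peat_area_ha"] > 0]
        for (region, year), sub in pool_peat.groupby(["region", "year"]):
            year = int(year)
            if config.peat_split == "proportional":
                ry = emissions[(emissions["region"] == region)
                               & (emissions["year"] == year)]
                ry = ry[~ry["commodity"].isin(carbon_mod.RESIDUAL_CLASSES)]
                weights = dict(zip(ry["commodity"], ry["area_ha"]))
                total_w = sum(weights.values())
            else:
                weights = None
                total_w = 0.0
            ry_all = emissions[(emissions["region"] == region)
                               & (emissions["year"] == year)]
            identified = sorted(
                c for c, a in zip(ry_all["commodity"], ry_all["area_ha"])
                if a > 0 and c not in carbon_mod.RESIDUAL_CLASSES
            )
            for _, g in sub.iterrows():
                if weights is not None and total_w > 0:
                    split = {c: g["peat_area_ha"] * w / total_w
                             for c, w in weights.items() if w > 0}
                else:
                    split = peat_mod.allocate_peat_area(
                        g["peat_area_ha"], identified
                    )
                for commodity, area in split.items():
                    if area > 0:
                        peat_rows.append({
                            "region": region, "year": year,
                            "commodity": commodity, "biome": int(g["biome"]),
                            "peat_area_ha": area, "mode": "statistical",
                        })
    peat_df = pd.DataFrame(
        peat_rows, columns=["region", "year", "commodity", "biome",
                            "peat_area_ha", "mode"]
    )
    if not peat_df.empty:
        peat_df = peat_df.groupby(
            ["region", "year", "commodity", "biome"], as_index=False
        ).agg({"peat_area_ha": "sum", "mode": "first"})
    peat_out = peat_mod.accumulate_emissions(
        peat_df, config.peat_factors, config.peat_horizon, grid.year_end
    )

    # ------------------------------------------------------------------
    # quality index
    iqi_rows = []
    if not detail.empty:
        for (region, year, commodity), sub in detail.groupby(
            ["region", "year", "commodity"]
        ):
            year = int(year)
            contribs = []
            for _, row in sub.iterrows():
                if row["mode"] == "spatial":
                    desc = by_id.get(row["source_id"])
                    if desc is None:
                        continue
                    contribs.append((
                        row["area_ha"],
                        quality_mod.adjusted_accuracy(
                            desc.overall_accuracy, None, None,
                            statistical=False,
                            flag_scores=config.flag_scores),
                        quality_mod.dataset_score(desc),
                    ))
                else:
                    pool = row["source_id"]
                    srcs = pool_src[
                        (pool_src["region"] == region)
                        & (pool_src["year"] == year)
                        & (pool_src["pool"] == pool)
                    ]
                    pool_area = srcs["area_ha"].sum()
                    flag_lu = stats.flag_land_use(region, year)
                    flag_prod = (
                        stats.flag_production(region, year, commodity)
                        if landuse_group_of(commodity) == "cropland" else None
                    )
                    for _, srow in srcs.iterrows():
                        desc = by_id.get(srow["source_id"])
                        if desc is None:
                            continue
                        fl = row["area_ha"] * srow["area_ha"] / pool_area \
                            if pool_area > 0 else 0.0
                        contribs.append((
                            fl,
                            quality_mod.adjusted_accuracy(
                                desc.overall_accuracy, flag_lu, flag_prod,
                                statistical=True,
                                flag_scores=config.flag_scores),
                            quality_mod.dataset_score(desc),
                        ))
            rec = quality_mod.compute_iqi(contribs)
            iqi_rows.append({
                "region": region, "year": year, "commodity": commodity,
                "IQI": rec.iqi, "band": rec.band,
            })
    iqi_df = pd.DataFrame(
        iqi_rows, columns=["region", "year", "commodity", "IQI", "band"]
    )

    # ------------------------------------------------------------------
    # footprint assembly
    footprint = emissions.copy()
    if not footprint.empty:
        peat_per = (
            peat_out.groupby(["region", "year", "commodity"])
            ["accumulated_MgCO2"].sum()
            if not peat_out.empty else pd.Series(dtype=float)
        )
        footprint["peat_MgCO2"] = [
            float(peat_per.get((r, y, c), 0.0))
            for r, y, c in zip(footprint["region"], footprint["year"],
                               footprint["commodity"])
        ]
        footprint = footprint.merge(iqi_df, on=["region", "year", "commodity"],
                                    how="left")
        footprint["deforestation_ha"] = footprint["area_ha"]
        footprint["gross_MtCO2"] = footprint["gross_MgCO2"] * MG_TO_MT
        footprint["net_MtCO2"] = footprint["net_MgCO2"] * MG_TO_MT
        footprint["peat_MtCO2"] = footprint["peat_MgCO2"] * MG_TO_MT
        footprint["amortized"] = False
        footprint = footprint[
            ["region", "commodity", "year", "deforestation_ha", "gross_MtCO2",
             "net_MtCO2", "peat_MtCO2", "IQI", "band", "amortized"]
        ]
    else:
        footprint = pd.DataFrame(
            columns=["region", "commodity", "year", "deforestation_ha",
                     "gross_MtCO2", "net_MtCO2", "peat_MtCO2", "IQI", "band",
                     "amortized"]
        )

    checks = _conservation_checks(summary, allocation, emissions, detail,
                                  footprint)
    return PipelineResult(summary=summary, allocation=allocation,
                          emissions=emissions, peat=peat_out,
                          footprint=footprint, config=config, checks=checks)


def _conservation_checks(summary, allocation, emissions, detail, footprint
                         ) -> dict:
    defo_total = summary.totals["deforestation_ha"].sum() \
        if not summary.totals.empty else 0.0
    footprint_total = footprint["deforestation_ha"].sum() \
        if not footprint.empty else 0.0
    gross_detail = (
        (detail["veg_MgC"] + detail["soc_loss_MgC"]).sum()
        * carbon_mod.C_TO_CO2 if not detail.empty else 0.0
    )
    gross_out = emissions["gross_MgCO2"].sum() if not emissions.empty else 0.0
    return {
        "deforestation_ha_summary": float(defo_total),
        "deforestation_ha_footprint": float(footprint_total),
        "area_residual": float(footprint_total - defo_total),
        "gross_MgCO2_detail": float(gross_detail),
        "gross_MgCO2_out": float(gross_out),
        "gross_residual": float(gross_out - gross_detail),
    }


# ---------------------------------------------------------------------------
# amortization

AMORTIZED_COLUMNS = ("deforestation_ha", "gross_MtCO2", "net_MtCO2")


def amortize(footprint: pd.DataFrame, window: int) -> pd.DataFrame:
    """Spread each event-year estimate evenly over ``window`` years.

    Committed columns are divided by the window and booked in
    [year, year + window - 1]; peat drainage columns pass through on the
    event year only (their temporal profile is already explicit).  Totals
    are conserved exactly.
    """
    if window < 1:
        raise ValueError("amortization window must be >= 1")
    if footprint.empty or window == 1:
        out = footprint.copy()
        out["amortized"] = True
        return out
    rows = []
    for _, row in footprint.iterrows():
        for k in range(window):
            new = row.copy()
            new["year"] = int(row["year"]) + k
            for col in AMORTIZED_COLUMNS:
                new[col] = row[col] / window
            if k > 0:
                new["peat_MtCO2"] = 0.0
            new["amortized"] = True
            rows.append(new)
    out = pd.DataFrame(rows)
    num_cols = list(AMORTIZED_COLUMNS) + ["peat_MtCO2"]
    agg = {c: "sum" for c in num_cols}
    agg.update({"IQI": "first", "band": "first", "amortized": "first"})
    out = out.groupby(["region", "commodity", "year"], as_index=False).agg(agg)
    return out


# ---------------------------------------------------------------------------
# sensitivity harness

SENSITIVITY_SWITCHES: dict[str, dict] = {
    "tcd_threshold_10": {"tcd_threshold": 10.0},
    "tcd_threshold_75": {"tcd_threshold": 75.0},
    "spatial_lag_1": {"spatial_lag_years": 1},
    "spatial_lag_5": {"spatial_lag_years": 5},
    "statistical_lag_1": {"statistical_lag_years": 1},
    "statistical_lag_5": {"statistical_lag_years": 5},
    "partial_statistical": {"attribution_mode": "partial_statistical"},
    "full_statistical": {"attribution_mode": "full_statistical"},
    "cropland_first_off": {"cropland_first": False},
    "net_expansion": {"expansion_mode": "net"},
    "restrict_all": {"restrict_by_stats": "all"},
    "restrict_none": {"restrict_by_stats": "none"},
    "multicropping_off": {"multicropping": False},
    "peat_horizon_none": {"peat_horizon": "none"},
    "peat_horizon_5": {"peat_horizon": 5},
    "peat_horizon_10": {"peat_horizon": 10},
    "peat_horizon_15": {"peat_horizon": 15},
    "plant_stock_75": {"plant_stock_scale": 0.75},
}


def _metrics(result: PipelineResult) -> dict[str, float]:
    fp = result.footprint
    produced = fp[~fp["commodity"].isin(carbon_mod.RESIDUAL_CLASSES)] \
        if not fp.empty else fp
    rows = result.summary.rows
    dluc = rows.loc[rows["level"] == "commodity", "area_ha"].sum() \
        if not rows.empty else 0.0
    return {
        "deforestation_ha": float(fp["deforestation_ha"].sum())
        if not fp.empty else 0.0,
        "commodity_deforestation_ha": float(produced["deforestation_ha"].sum())
        if not fp.empty else 0.0,
        "dluc_area_ha": float(dluc),
        "gross_MtCO2": float(fp["gross_MtCO2"].sum()) if not fp.empty else 0.0,
        "net_MtCO2": float(fp["net_MtCO2"].sum()) if not fp.empty else 0.0,
        "peat_MtCO2": float(fp["peat_MtCO2"].sum()) if not fp.empty else 0.0,
    }


def sensitivity_run(
    stack: LayerStack,
    registry: list[DatasetDescriptor],
    stats: AgStatsTable,
    baseline: ConfigBundle | None = None,
    switches: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Re-run the pipeline under each named switch and report % change from
    the baseline for every headline metric (two decimals, sign =
    (variant - reference) / reference * 100)."""
    baseline = baseline or ConfigBundle()
    switches = switches if switches is not None else SENSITIVITY_SWITCHES
    unknown = [k for k in switches if not isinstance(switches[k], dict)]
    if unknown:
        raise ValueError(f"malformed switches {unknown}")
    ref = _metrics(run_pipeline(stack, registry, stats, baseline))
    rows = []
    for name, overrides in switches.items():
        overrides = dict(overrides)
        plant = overrides.pop("plant_stock_scale", None)
        cfg = baseline.replace(**overrides) if overrides else baseline
        if plant is not None:
            from dataclasses import replace as dc_replace

            cfg = cfg.replace(carbon=dc_replace(baseline.carbon,
                                                plant_stock_scale=plant))
        var = _metrics(run_pipeline(stack, registry, stats, cfg))
        row = {"switch": name}
        for metric, ref_val in ref.items():
            if ref_val == 0:
                row[metric] = float("nan") if var[metric] != 0 else 0.0
            else:
                row[metric] = round(
                    (var[metric] - ref_val) / ref_val * 100.0, 2
                )
        rows.append(row)
    return pd.DataFrame(rows)
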