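"""Two-step statistical land balance for spatially unresolved deforestation.

Step 1 allocates each region-year's unresolved pools to land uses
(cropland, pasture, forest plantation) in proportion to — and optionally
capped by — their statistical expansion over a backward lag window.  Under
the default displacement rule, cropland expansion is satisfied first from
the mixed-agriculture pool (cropland tends to displace pasture, which in
turn expands into forest), with the remainder split between pasture and
plantation proportionally to their expansions.

Step 2 splits cropland-driven deforestation across crops in proportion to
their harvested-area increases over the same kind of window, optionally
deflated by the region-year cropping intensity so multiple cropping does
not inflate a crop's claim.  Pasture maps to the combined cattle
meat-and-leather class, plantations to forestry products.

Expansions may be computed gross (sum of positive year-on-year increments,
so abandonment elsewhere in the window does not cancel expansion) or net
(endpoint difference).  When the pipeline provides spatially attributed
areas, they are netted off the expansions first so spatial and statistical
attribution draw on one shared land budget.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io_registry import AgStatsTable, ConfigBundle, LAND_USES

POOL_KEYS = (
    "unresolved_agriculture",
    "cropland_only",
    "pasture_only",
    "plantation_only",
    "cropland_pasture_mosaic",
)

RESIDUAL_WITHOUT_PRODUCTION = "without_production"
RESIDUAL_UNALLOCATED = "unallocated"


def _window_expansion(series: pd.Series, year: int, lag: int, mode: str) -> float | None:
    """Expansion of one statistic over [year - lag, year]; None if the
    window has no data."""
    if series.empty:
        return None
    y0, y1 = year - lag, year
    window = series.loc[[y for y in range(y0, y1 + 1) if y in series.index]]
    if window.empty or len(window) < 2:
        # a single observation carries no expansion signal
        return None if window.empty else 0.0
    if mode == "net":
        return max(0.0, float(window.iloc[-1] - window.iloc[0]))
    if mode == "gross":
        diffs = window.diff().dropna()
        return float(diffs[diffs > 0].sum())
    raise ValueError(f"unknown expansion mode {mode!r}")


def landuse_expansions(
    stats: AgStatsTable, region: str, year: int, lag: int, mode: str = "gross"
) -> dict[str, float] | None:
    """Land-use area expansion (ha) over the lag window, by land use.

    Returns None when no land-use statistic covers the window, which leaves
    the region-year's pools unallocated.
    """
    out = {}
    any_data = False
    for lu in LAND_USES:
        exp = _window_expansion(stats.series(region, f"{lu}_area"), year, lag, mode)
        if exp is None:
            out[lu] = 0.0
        else:
            out[lu] = exp
            any_data = True
    return out if any_data else None


def harvested_series(
    stats: AgStatsTable, region: str, multicropping: bool = True
) -> dict[str, pd.Series]:
    """Per-crop harvested-area series, optionally deflated by the region-year
    cropping intensity CI = max(1, total harvested / cropland area) so that
    double-cropped land does not claim expansion twice."""
    crops = stats.crops()
    series = {c: stats.series(region, f"harvested_{c}") for c in crops}
    if multicropping:
        years = sorted({y for s in series.values() for y in s.index})
        cropland = stats.series(region, "cropland_area")
        ci = {}
        for y in years:
            total_h = sum(float(s.loc[y]) for s in series.values() if y in s.index)
            area = float(cropland.loc[y]) if y in cropland.index else 0.0
            ci[y] = max(1.0, total_h / area) if area > 0 else 1.0
        series = {
            c: pd.Series({y: float(v) / ci[y] for y, v in s.items()})
            for c, s in series.items()
        }
    return series


def crop_expansions(
    stats: AgStatsTable,
    region: str,
    year: int,
    lag: int,
    mode: str = "gross",
    multicropping: bool = True,
) -> dict[str, float]:
    """Harvested-area expansion by crop over the lag window (cropping-
    intensity-adjusted when ``multicropping`` is on)."""
    crops = stats.crops()
    series = harvested_series(stats, region, multicropping)
    out = {}
    for c in crops:
        exp = _window_expansion(series[c], year, lag, mode)
        out[c] = exp if exp is not None else 0.0
    return out


def _net_of(expansions: Mapping[str, float], attributed: Mapping[str, float] | None
            ) -> dict[str, float]:
    if not attributed:
        return dict(expansions)
    return {
        k: max(0.0, v - float(attributed.get(k, 0.0))) for k, v in expansions.items()
    }


def allocate_landuse(
    pools: Mapping[str, float],
    expansions: Mapping[str, float] | None,
    config: ConfigBundle,
    already_attributed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Step 1: allocate unresolved pools to land uses.

    Returns rows (pool, target, area_ha) where target is a land use or a
    residual class; per pool, targets sum exactly to the pool.  ``pools``
    uses the keys of :data:`POOL_KEYS`.  ``already_attributed`` (area by
    land use) is netted off the expansions before allocation so the land
    budget is shared with the spatial step.

    ``config.restrict_by_stats``: ``pools`` caps only statistically split
    pools at their land use's remaining expansion (single-land-use pools
    pass through on spatial evidence); ``all`` also caps the pass-through
    pools; ``none`` removes all caps.  Overflow is reported as
    deforestation without production.
    """
    for key, v in pools.items():
        if v < 0:
            raise ValueError(f"negative pool {key!r}")
        if key not in POOL_KEYS:
            raise ValueError(f"unknown pool {key!r}")
    rows: list[tuple[str, str, float]] = []

    if expansions is None:
        for key, v in pools.items():
            if v > 0:
                rows.append((key, RESIDUAL_UNALLOCATED, v))
        return pd.DataFrame(rows, columns=["pool", "target", "area_ha"])

    remaining = _net_of(expansions, already_attributed)
    restrict = config.restrict_by_stats

    def draw(lu: str, amount: float, capped: bool) -> float:
        """Allocate up to ``amount`` to land use ``lu``; returns allocation."""
        if not capped:
            remaining[lu] = max(0.0, remaining.get(lu, 0.0) - amount)
            return amount
        grant = min(amount, max(0.0, remaining.get(lu, 0.0)))
        remaining[lu] = max(0.0, remaining.get(lu, 0.0) - grant)
        return grant

    # pass-through pools (spatial land-use evidence)
    passthrough = {
        "cropland_only": "cropland",
        "pasture_only": "pasture",
        "plantation_only": "forest_plantation",
    }
    for key, lu in passthrough.items():
        pool = float(pools.get(key, 0.0))
        if pool <= 0:
            continue
        granted = draw(lu, pool, capped=(restrict == "all"))
        if granted > 0:
            rows.append((key, lu, granted))
        if pool - granted > 0:
            rows.append((key, RESIDUAL_WITHOUT_PRODUCTION, pool - granted))

    capped = restrict in ("pools", "all")

    def proportional(pool_key: str, pool: float, uses: list[str]) -> None:
        weights = {lu: max(0.0, remaining.get(lu, 0.0)) if capped
                   else max(0.0, _net_of(expansions, already_attributed).get(lu, 0.0))
                   for lu in uses}
        total_w = sum(weights.values())
        if total_w <= 0:
            rows.append((pool_key, RESIDUAL_UNALLOCATED, pool))
            return
        residual = pool
        for lu in uses:
            claim = pool * weights[lu] / total_w
            granted = draw(lu, claim, capped=capped)
            if granted > 0:
                rows.append((pool_key, lu, granted))
            residual -= granted
        if residual > 1e-12:
            rows.append((pool_key, RESIDUAL_WITHOUT_PRODUCTION, residual))

    # mosaic pool: cropland and pasture only
    mosaic = float(pools.get("cropland_pasture_mosaic", 0.0))
    if mosaic > 0:
        proportional("cropland_pasture_mosaic", mosaic, ["cropland", "pasture"])

    # mixed-agriculture pool
    pool = float(pools.get("unresolved_agriculture", 0.0))
    if pool > 0:
        if config.cropland_first:
            crop_cap = max(0.0, remaining.get("cropland", 0.0))
            crop_take = min(pool, crop_cap)
            if crop_take > 0:
                draw("cropland", crop_take, capped=True)
                rows.append(("unresolved_agriculture", "cropland", crop_take))
            rest = pool - crop_take
            if rest > 0:
                proportional("unresolved_agriculture", rest,
                             ["pasture", "forest_plantation"])
        else:
            proportional("unresolved_agriculture", pool, list(LAND_USES))

    return pd.DataFrame(rows, columns=["pool", "target", "area_ha"])


def allocate_commodities(
    cropland_ha: float,
    stats: AgStatsTable,
    region: str,
    year: int,
    lag: int,
    multicropping: bool = True,
    mode: str = "gross",
    already_attributed: Mapping[str, float] | None = None,
) -> dict[str, float] | None:
    """Step 2: split a cropland allocation across crops.

    Shares are positive harvested-area expansions normalized over the lag
    window; proportions are invariant to rescaling all harvested areas.
    Returns None (caller reports the pool unallocated) when no crop
    expanded.
    """
    if cropland_ha < 0:
        raise ValueError("negative cropland allocation")
    if cropland_ha == 0:
        return {}
    expansions = _net_of(
        crop_expansions(stats, region, year, lag, mode, multicropping),
        already_attributed,
    )
    total = sum(v for v in expansions.values() if v > 0)
    if total <= 0:
        return None
    return {
        crop: cropland_ha * exp / total
        for crop, exp in expansions.items()
        if exp > 0
    }
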