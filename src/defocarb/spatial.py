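"""Sequential per-pixel attribution of forest loss.

A tree-cover-loss pixel is deforestation only if it was natural forest in
the base year: canopy density at or above the threshold (default 25%) and
outside the plantation mask.  Loss that fails this criterion is degradation
or rotational clearing and never enters the commodity accounts.

Each deforestation pixel is then claimed by at most one dataset, scanned in
order of explicitness: commodity maps first, then broad land-use maps, then
land-use mosaics; ties within a level go to the higher rubric score, then
registry order.  A dataset may claim a pixel lost in year t only while its
information is valid — annual sources must observe the class within the lag
window [t, t + spatial_lag_years] (and not beyond their last valid year),
static maps must extend to t or later.  Pixels no dataset claims are
checked against the fire layer (agriculture beats fire; fire-only loss is
excluded from commodity deforestation), then against the dominant-driver
fallback, and otherwise remain unattributed and fall to the statistical
land balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_registry import ConfigBundle, DatasetDescriptor, GridSpec, Layer, LayerStack

LEVEL_RANK = {"commodity": 0, "land_use": 1, "mosaic": 2}

# driver-fallback classes and where they land
DRIVER_TO_POOL = {
    "commodity_driven": "unresolved_agriculture",
    "shifting_agriculture": "unresolved_agriculture",
    "forestry": "forest_plantation",
    "other": "non_commodity_other",
}

LABEL_DEGRADATION = "degradation_rotation"
LABEL_FIRE = "fire_non_commodity"
LABEL_UNATTRIBUTED = "unattributed"
LABEL_OTHER = "non_commodity_other"

#: labels counted outside deforestation_ha
NON_DEFORESTATION_LABELS = (LABEL_DEGRADATION, LABEL_FIRE, LABEL_OTHER)


@dataclass(frozen=True)
class AttributionClass:
    label: str
    level: str  # commodity | land_use | mosaic | driver | fire | none
    source_id: str | None = None


@dataclass
class PixelAttribution:
    """Per-pixel attribution result: an int grid of class codes (-1 where no
    loss occurred) plus the code table."""

    codes: np.ndarray
    classes: list[AttributionClass]

    def label_grid(self) -> np.ndarray:
        out = np.full(self.codes.shape, "", dtype=object)
        for i, cls in enumerate(self.classes):
            out[self.codes == i] = cls.label
        return out

    def mask_of(self, **selectors) -> np.ndarray:
        sel = np.zeros(self.codes.shape, dtype=bool)
        for i, cls in enumerate(self.classes):
            if all(getattr(cls, k) == v for k, v in selectors.items()):
                sel |= self.codes == i
        return sel


def build_forest_mask(
    density: Layer, plantation_mask: Layer | None, threshold: float
) -> Layer:
    """Natural-forest mask: density >= threshold and outside plantations.

    Nodata in either input propagates.
    """
    if not 0 <= threshold <= 100:
        raise ValueError("threshold must be in [0, 100]")
    dens = density.values
    forest = (dens >= threshold).astype(float)
    invalid = ~density.valid
    if plantation_mask is not None:
        forest = np.where(plantation_mask.values == 1, 0.0, forest)
        invalid |= ~plantation_mask.valid
    forest[invalid] = density.nodata
    return Layer("forest", "mask", forest, nodata=density.nodata)


def _scan_order(registry, levels) -> list[DatasetDescriptor]:
    from .quality import dataset_score

    indexed = [(d, i) for i, d in enumerate(registry) if d.level in levels]
    indexed.sort(key=lambda di: (LEVEL_RANK.get(di[0].level, 99),
                                 -dataset_score(di[0]), di[1]))
    return [d for d, _ in indexed]


class _ClassTable:
    def __init__(self):
        self.classes: list[AttributionClass] = []
        self._index: dict[AttributionClass, int] = {}

    def code(self, label, level, source_id=None) -> int:
        cls = AttributionClass(label, level, source_id)
        if cls not in self._index:
            self._index[cls] = len(self.classes)
            self.classes.append(cls)
        return self._index[cls]


def attribute_pixels(
    stack: LayerStack,
    registry: list[DatasetDescriptor],
    config: ConfigBundle,
) -> PixelAttribution:
    """Run the sequential attribution hierarchy over the whole grid.

    Every loss pixel receives exactly one class.  ``attribution_mode``
    restricts the evidence used: ``partial_statistical`` drops commodity,
    land-use and mosaic layers (keeping the driver fallback and fire);
    ``full_statistical`` uses the loss layer alone — no plantation mask, no
    fire exclusion — so all threshold-passing loss becomes an unattributed
    pool, emulating attribution from loss data and statistics only.
    """
    grid = stack.grid
    mode = config.attribution_mode
    loss_layer = stack["loss_year"]
    t = loss_layer.values
    loss = loss_layer.valid & (t >= grid.year_start) & (t <= grid.year_end)

    plantation = stack["plantation"] if ("plantation" in stack and
                                         mode != "full_statistical") else None
    forest_layer = build_forest_mask(stack["density"], plantation,
                                     config.tcd_threshold)
    forest = forest_layer.values == 1.0

    table = _ClassTable()
    codes = np.full(grid.shape, -1, dtype=np.int32)

    degradation = loss & ~forest
    codes[degradation] = table.code(LABEL_DEGRADATION, "none")
    candidates = loss & forest
    claimed = np.zeros(grid.shape, dtype=bool)

    # --- commodity / land-use / mosaic scan -------------------------------
    levels = () if mode in ("partial_statistical", "full_statistical") else (
        "commodity", "land_use", "mosaic")
    for desc in _scan_order(registry, levels):
        if desc.id not in stack:
            continue
        vals = stack[desc.id].values
        present = stack[desc.id].valid & (vals != 0)
        if desc.annual:
            obs_name = f"{desc.id}__year"
            if obs_name not in stack:
                raise ValueError(f"annual dataset {desc.id!r} lacks {obs_name!r}")
            obs = stack[obs_name].values
            eligible = (
                (obs >= t)
                & (obs <= t + config.spatial_lag_years)
                & (obs <= desc.last_valid_year)
            )
        else:
            eligible = t <= desc.last_valid_year
        claim = candidates & ~claimed & present & eligible
        if not claim.any():
            continue
        for code, label in desc.class_map.items():
            sel = claim & (vals == code)
            if sel.any():
                codes[sel] = table.code(label, desc.level, desc.id)
        claimed |= claim

    # --- fire exclusion (agriculture before fire) -------------------------
    if mode != "full_statistical" and "fire_year" in stack:
        fy = stack["fire_year"].values
        fire = (
            candidates
            & ~claimed
            & stack["fire_year"].valid
            & (fy > 0)
            & (np.abs(fy - t) <= config.fire_window_years)
        )
        fire_src = next((d.id for d in registry if d.level == "fire"), None)
        codes[fire] = table.code(LABEL_FIRE, "fire", fire_src)
        claimed |= fire

    # --- dominant-driver fallback -----------------------------------------
    if mode != "full_statistical":
        for desc in _scan_order(registry, ("driver",)):
            if desc.id not in stack:
                continue
            vals = stack[desc.id].values
            present = stack[desc.id].valid & (vals != 0)
            eligible = t <= desc.last_valid_year
            claim = candidates & ~claimed & present & eligible
            if not claim.any():
                continue
            for code, label in desc.class_map.items():
                pool = DRIVER_TO_POOL.get(label, LABEL_OTHER)
                level = "none" if pool == LABEL_OTHER else "driver"
                sel = claim & (vals == code)
                if sel.any():
                    codes[sel] = table.code(pool, level, desc.id)
            claimed |= claim

    # --- remainder ---------------------------------------------------------
    rest = candidates & ~claimed
    loss_src = next((d.id for d in registry if d.level == "loss"), None)
    codes[rest] = table.code(LABEL_UNATTRIBUTED, "none", loss_src)

    return PixelAttribution(codes=codes, classes=table.classes)


@dataclass
class AttributionSummary:
    """Region x year x class deforested areas plus loss-decomposition totals.

    ``rows`` columns: region, year, label, level, source_id, area_ha —
    deforestation classes only.  ``totals`` columns: region, year,
    total_loss_ha, deforestation_ha, degradation_rotation_ha, fire_ha, with
    deforestation_ha + degradation_rotation_ha + fire_ha = total_loss_ha.
    """

    rows: pd.DataFrame
    totals: pd.DataFrame

    def check_invariants(self, atol: float = 1e-9) -> None:
        if (self.rows["area_ha"] < 0).any():
            raise AssertionError("negative class area")
        per_ry = self.rows.groupby(["region", "year"])["area_ha"].sum()
        for _, row in self.totals.iterrows():
            key = (row["region"], row["year"])
            got = float(per_ry.get(key, 0.0))
            if abs(got - row["deforestation_ha"]) > atol:
                raise AssertionError(f"class areas != deforestation_ha at {key}")
            decomposed = (
                row["deforestation_ha"]
                + row["degradation_rotation_ha"]
                + row["fire_ha"]
            )
            if abs(decomposed - row["total_loss_ha"]) > atol:
                raise AssertionError(f"loss decomposition broken at {key}")


def summarize_attribution(
    attribution: PixelAttribution,
    region_layer: Layer,
    loss_layer: Layer,
    grid: GridSpec,
) -> AttributionSummary:
    """Aggregate the per-pixel grid to region-year class areas.

    Areas are pixel counts times the constant pixel area, so conservation
    holds to machine precision on integer counts.
    """
    has_class = attribution.codes >= 0
    if not has_class.any():
        rows = pd.DataFrame(
            columns=["region", "year", "label", "level", "source_id", "area_ha"]
        )
        totals = pd.DataFrame(
            columns=["region", "year", "total_loss_ha", "deforestation_ha",
                     "degradation_rotation_ha", "fire_ha"]
        )
        return AttributionSummary(rows, totals)

    region = region_layer.values[has_class].astype(int)
    year = loss_layer.values[has_class].astype(int)
    code = attribution.codes[has_class]
    df = pd.DataFrame({"region": region, "year": year, "code": code})
    counts = df.groupby(["region", "year", "code"]).size().reset_index(name="n")
    counts["area_ha"] = counts["n"] * grid.pixel_area_ha
    cls = counts["code"].map(lambda c: attribution.classes[c])
    counts["label"] = [c.label for c in cls]
    counts["level"] = [c.level for c in cls]
    counts["source_id"] = [c.source_id for c in cls]

    is_defo = ~counts["label"].isin(NON_DEFORESTATION_LABELS)
    rows = counts.loc[
        is_defo, ["region", "year", "label", "level", "source_id", "area_ha"]
    ].reset_index(drop=True)

    def bucket(label):
        if label == LABEL_FIRE:
            return "fire_ha"
        if label in (LABEL_DEGRADATION, LABEL_OTHER):
            return "degradation_rotation_ha"
        return "deforestation_ha"

    counts["bucket"] = counts["label"].map(bucket)
    totals = (
        counts.pivot_table(
            index=["region", "year"], columns="bucket", values="area_ha",
            aggfunc="sum", fill_value=0.0,
        )
        .reindex(columns=["deforestation_ha", "degradation_rotation_ha", "fire_ha"],
                 fill_value=0.0)
        .reset_index()
    )
    totals["total_loss_ha"] = (
        totals["deforestation_ha"]
        + totals["degradation_rotation_ha"]
        + totals["fire_ha"]
    )
    totals = totals[
        ["region", "year", "total_loss_ha", "deforestation_ha",
         "degradation_rotation_ha", "fire_ha"]
    ]
    return AttributionSummary(rows, totals)
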