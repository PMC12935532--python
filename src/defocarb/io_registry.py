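"""Raster stack, dataset registry, agricultural statistics and configuration.

Everything downstream operates on a :class:`LayerStack` of pre-aligned 2-D
grids sharing one :class:`GridSpec` (abstract planar grid — no projection or
resampling; pixel area is a constant in hectares, default 0.09 ha for the
30-m convention).  Rasters are read from single-band TIFF or a plain-text
grid; statistics come as a long CSV ``region,year,variable,value,flag``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .carbon import CarbonParams
from .peat import EmissionFactorTable, DEFAULT_EMISSION_FACTORS

#: internal nodata sentinel, applied uniformly at read time
NODATA = -9999.0

LAYER_KINDS = ("continuous", "categorical", "mask", "year")
LEVELS = ("commodity", "land_use", "mosaic", "driver", "fire", "loss")
FLAG_LABELS = ("official", "semi_official", "estimated", "imputed", "unofficial")

LAND_USES = ("cropland", "pasture", "forest_plantation")

#: layers that carry structural ids rather than attribution content
ANCILLARY_CATEGORICAL = ("region", "biome")


@dataclass(frozen=True)
class GridSpec:
    n_rows: int
    n_cols: int
    pixel_area_ha: float = 0.09
    year_start: int = 2001
    year_end: int = 2022

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_area_ha <= 0:
            raise ValueError("pixel_area_ha must be positive")
        if self.year_start > self.year_end:
            raise ValueError("year_start must not exceed year_end")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


@dataclass
class Layer:
    """One aligned 2-D grid (row-major, origin top-left).

    ``kind`` is continuous (densities, stocks), categorical (coded classes),
    mask (0/1) or year (0 = no event, otherwise a calendar year).
    """

    name: str
    kind: str
    values: np.ndarray
    nodata: float = NODATA

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"layer {self.name!r} must be 2-D")
        if self.kind == "mask":
            valid = np.isin(self.values, [0.0, 1.0, self.nodata])
            if not valid.all():
                raise ValueError(f"mask layer {self.name!r} must be binary")

    @property
    def valid(self) -> np.ndarray:
        return self.values != self.nodata


class LayerStack:
    """Dict-like bundle of aligned layers on one grid."""

    def __init__(self, grid: GridSpec, layers: Iterable[Layer] = ()):
        self.grid = grid
        self._layers: dict[str, Layer] = {}
        for layer in layers:
            self.add(layer)

    def add(self, layer: Layer) -> None:
        if layer.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {layer.name!r} shape {layer.values.shape} does not match "
                f"grid {self.grid.shape}"
            )
        self._layers[layer.name] = layer

    def __getitem__(self, name: str) -> Layer:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers.values())

    def names(self) -> list[str]:
        return list(self._layers)

    def copy(self) -> "LayerStack":
        return LayerStack(
            self.grid,
            [Layer(l.name, l.kind, l.values.copy(), l.nodata) for l in self],
        )

    def drop(self, name: str) -> None:
        self._layers.pop(name, None)


@dataclass
class DatasetDescriptor:
    """Metadata for one attribution source.

    ``overall_accuracy`` is the producer-reported OA; the three rubric
    sub-scores grade spatial granularity, temporal granularity and
    explicitness of the deforestation driver, each in [0, 1].  ``annual``
    sources carry a companion ``<id>__year`` observation-year layer.
    """

    id: str
    level: str
    class_map: dict[int, str] = field(default_factory=dict)
    overall_accuracy: float = 1.0
    spatial_score: float = 1.0
    temporal_score: float = 1.0
    explicitness_score: float = 1.0
    last_valid_year: int = 9999
    annual: bool = False

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown dataset level {self.level!r}")
        if not 0 < self.overall_accuracy <= 1:
            raise ValueError("overall_accuracy must be in (0, 1]")
        for s in (self.spatial_score, self.temporal_score, self.explicitness_score):
            if not 0 <= s <= 1:
                raise ValueError("rubric sub-scores must be in [0, 1]")


class AgStatsTable:
    """Region-year land-use areas, per-crop harvested areas and quality flags.

    Values are stored per (region, year, variable) with an FAO-style flag
    drawn from the closed label set; missing years are linearly interpolated
    on access so expansion windows can straddle reporting gaps.
    """

    def __init__(self, values: pd.DataFrame):
        required = {"region", "year", "variable", "value", "flag"}
        if not required.issubset(values.columns):
            raise ValueError(f"statistics table needs columns {sorted(required)}")
        bad = set(values["flag"]) - set(FLAG_LABELS)
        if bad:
            raise ValueError(f"unknown flag labels {sorted(bad)}")
        if values.duplicated(["region", "year", "variable"]).any():
            raise ValueError("duplicate key (region, year, variable) in statistics")
        if (values["value"] < 0).any():
            raise ValueError("negative areas in statistics")
        values = values.copy()
        values["region"] = values["region"].astype(str)
        values["year"] = values["year"].astype(int)
        self.values = values.reset_index(drop=True)
        self._series_cache: dict[tuple[str, str], pd.Series] = {}

    # -- accessors ---------------------------------------------------------
    def regions(self) -> list[str]:
        return sorted(self.values["region"].unique())

    def crops(self) -> list[str]:
        names = self.values["variable"]
        return sorted(
            {v[len("harvested_"):] for v in names if v.startswith("harvested_")}
        )

    def series(self, region: str, variable: str) -> pd.Series:
        """Yearly series for one variable, linearly interpolated inside the
        observed span; empty if the variable was never reported."""
        key = (region, variable)
        if key not in self._series_cache:
            sub = self.values[
                (self.values["region"] == region)
                & (self.values["variable"] == variable)
            ]
            if sub.empty:
                s = pd.Series(dtype=float)
            else:
                s = sub.set_index("year")["value"].sort_index().astype(float)
                full = pd.RangeIndex(s.index.min(), s.index.max() + 1)
                s = s.reindex(full).interpolate(method="linear")
            self._series_cache[key] = s
        return self._series_cache[key]

    def area(self, region: str, year: int, variable: str) -> float | None:
        s = self.series(region, variable)
        if year in s.index:
            return float(s.loc[year])
        return None

    def flag(self, region: str, year: int, variable: str) -> str | None:
        sub = self.values[
            (self.values["region"] == region)
            & (self.values["year"] == year)
            & (self.values["variable"] == variable)
        ]
        if sub.empty:
            return None
        return str(sub["flag"].iloc[0])

    def flag_land_use(self, region: str, year: int) -> str:
        """Worst (lowest-scoring) flag among reported land-use areas."""
        order = {label: i for i, label in enumerate(FLAG_LABELS)}
        flags = [
            f
            for lu in LAND_USES
            if (f := self.flag(region, year, f"{lu}_area")) is not None
        ]
        if not flags:
            return "unofficial"
        return max(flags, key=lambda f: order[f])

    def flag_production(self, region: str, year: int, crop: str) -> str | None:
        """Flag of the crop's harvested area; None when the source reports
        no production flag (scored as official downstream)."""
        return self.flag(region, year, f"harvested_{crop}")


def load_ag_stats(path) -> AgStatsTable:
    """Load a long-format statistics CSV.

    Missing flags default to ``unofficial``; negative-value rows are dropped
    with a warning; duplicate (region, year, variable) keys are an error.
    """
    df = pd.read_csv(path)
    missing = {"region", "year", "variable", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"statistics CSV missing columns {sorted(missing)}")
    if "flag" not in df.columns:
        df["flag"] = "unofficial"
    df["flag"] = df["flag"].fillna("unofficial").replace("", "unofficial")
    bad = set(df["flag"]) - set(FLAG_LABELS)
    if bad:
        raise ValueError(f"unknown flag labels {sorted(bad)}")
    neg = df["value"] < 0
    if neg.any():
        warnings.warn(f"dropping {int(neg.sum())} negative-area statistics rows")
        df = df[~neg]
    if df.duplicated(["region", "year", "variable"]).any():
        raise ValueError("duplicate key (region, year, variable) in statistics CSV")
    df["year"] = df["year"].astype(int)
    return AgStatsTable(df)


# ---------------------------------------------------------------------------
# raster I/O: single-band TIFF (via tifffile) or plain-text grid

def read_layer(path, kind: str, name: str | None = None,
               src_nodata: float | None = None) -> Layer:
    """Read a single-band raster or plain-text grid as a Layer.

    Values equal to ``src_nodata`` are normalized to the internal sentinel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(path))
        if values.ndim == 3 and values.shape[0] == 1:
            values = values[0]
        if values.ndim != 2:
            raise ValueError(f"{path.name}: multi-band rasters are not supported")
    else:
        values = np.loadtxt(path, ndmin=2)
    values = values.astype(float)
    if src_nodata is not None:
        values = np.where(values == src_nodata, NODATA, values)
    return Layer(name or path.stem, kind, values)


def write_layer(layer: Layer, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, layer.values.astype(np.float64))
    else:
        np.savetxt(path, layer.values, fmt="%.10g")


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "OK" if self.ok else "\n".join(self.violations)


REQUIRED_LAYERS = ("density", "loss_year")


def validate_stack(
    stack: LayerStack,
    registry: Iterable[DatasetDescriptor],
    grid: GridSpec | None = None,
) -> ValidationReport:
    """Check that the stack, registry and grid form a runnable input set.

    Collects all violations instead of failing fast; the pipeline refuses to
    run on a failing report.
    """
    grid = grid or stack.grid
    report = ValidationReport()
    registry = list(registry)
    by_id = {d.id: d for d in registry}

    for layer in stack:
        if layer.values.shape != grid.shape:
            report.violations.append(
                f"layer {layer.name!r}: shape {layer.values.shape} != grid {grid.shape}"
            )
        if layer.kind == "year":
            vals = layer.values[layer.valid]
            vals = vals[vals != 0]
            out = (vals < grid.year_start) | (vals > grid.year_end)
            if out.any():
                report.violations.append(
                    f"layer {layer.name!r}: year outside window "
                    f"[{grid.year_start}, {grid.year_end}]"
                )

    for required in REQUIRED_LAYERS:
        if required not in stack:
            report.violations.append(f"required layer {required!r} missing")

    for layer in stack:
        if layer.kind != "categorical" or layer.name in ANCILLARY_CATEGORICAL:
            continue
        desc = by_id.get(layer.name)
        if desc is None:
            report.violations.append(f"undescribed dataset: layer {layer.name!r}")
            continue
        codes = np.unique(layer.values[layer.valid])
        codes = codes[codes != 0]
        unknown = [int(c) for c in codes if int(c) not in desc.class_map]
        if unknown:
            report.violations.append(
                f"layer {layer.name!r}: codes {unknown} not in class_map of "
                f"descriptor {desc.id!r}"
            )

    for desc in registry:
        if desc.annual and desc.id in stack and f"{desc.id}__year" not in stack:
            report.violations.append(
                f"annual dataset {desc.id!r} lacks observation-year layer "
                f"{desc.id + '__year'!r}"
            )
    return report


# ---------------------------------------------------------------------------
# configuration bundle

@dataclass
class ConfigBundle:
    """All tunable parameters of the pipeline.

    The named sensitivity switches of the harness map one-to-one onto these
    fields; defaults are the baseline configuration.
    """

    tcd_threshold: float = 25.0
    spatial_lag_years: int = 3
    statistical_lag_years: int = 3
    amortize_years: int = 5
    fire_window_years: int = 0
    attribution_mode: str = "full"  # full | partial_statistical | full_statistical
    expansion_mode: str = "gross"  # gross | net
    cropland_first: bool = True
    restrict_by_stats: str = "pools"  # pools | all | none
    multicropping: bool = True
    peat_horizon: object = "until_end"  # until_end | none | int years
    peat_split: str = "even"  # even | proportional
    carbon: CarbonParams = field(default_factory=CarbonParams)
    peat_factors: EmissionFactorTable = field(default_factory=EmissionFactorTable)
    flag_scores: dict[str, float] = field(
        default_factory=lambda: {
            "official": 1.0,
            "semi_official": 0.75,
            "estimated": 0.5,
            "imputed": 0.25,
            "unofficial": 0.25,
        }
    )

    def __post_init__(self):
        if not 0 <= self.tcd_threshold <= 100:
            raise ValueError("tcd_threshold must be in [0, 100]")
        if self.spatial_lag_years < 0 or self.statistical_lag_years < 0:
            raise ValueError("lag years must be non-negative")
        if self.amortize_years < 1:
            raise ValueError("amortize_years must be at least 1")
        if self.attribution_mode not in ("full", "partial_statistical",
                                         "full_statistical"):
            raise ValueError(f"unknown attribution mode {self.attribution_mode!r}")
        if self.restrict_by_stats not in ("pools", "all", "none"):
            raise ValueError(f"unknown restrict_by_stats {self.restrict_by_stats!r}")

    def replace(self, **kwargs) -> "ConfigBundle":
        from dataclasses import replace

        return replace(self, **kwargs)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["carbon"]["soc_loss_frac"] = {
            f"{g}|{b}": v for (g, b), v in self.carbon.soc_loss_frac.items()
        }
        d["peat_factors"] = {
            f"{g}|{b}": v for (g, b), v in self.peat_factors.factors.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConfigBundle":
        d = dict(d)
        carbon = d.pop("carbon", None)
        peat = d.pop("peat_factors", None)
        if carbon is not None:
            carbon = dict(carbon)
            if "soc_loss_frac" in carbon:
                carbon["soc_loss_frac"] = {
                    tuple(k.split("|")): v for k, v in carbon["soc_loss_frac"].items()
                }
            carbon = CarbonParams(**carbon)
        if peat is not None:
            peat = EmissionFactorTable(
                {tuple(k.split("|")): v for k, v in peat.items()}
            )
        kwargs = dict(d)
        if carbon is not None:
            kwargs["carbon"] = carbon
        if peat is not None:
            kwargs["peat_factors"] = peat
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ConfigBundle":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# registry serialization

def registry_to_yaml(registry: Iterable[DatasetDescriptor], path) -> None:
    data = []
    for d in registry:
        row = asdict(d)
        row["class_map"] = {int(k): v for k, v in d.class_map.items()}
        data.append(row)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def registry_from_yaml(path) -> list[DatasetDescriptor]:
    raw = yaml.safe_load(Path(path).read_text()) or []
    out = []
    for row in raw:
        row = dict(row)
        row["class_map"] = {int(k): v for k, v in row.get("class_map", {}).items()}
        out.append(DatasetDescriptor(**row))
    return out
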