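"""Integrated Quality Index (IQI) for deforestation estimates.

Each estimate aggregates contributions from several input datasets.  The
IQI is the area-weighted mean of each contributing dataset's overall
accuracy times its rubric score,

    IQI = sum_j(FL_j * OA'_j * Score_j) / sum_j(FL_j),

where FL_j is the deforested area contributed by dataset j.  Score_j
averages three equally weighted rubric criteria (spatial granularity,
temporal granularity, explicitness).  For statistically attributed
contributions, OA_j is discounted by the mean of the two FAO-style quality
flag scores (land-use and production statistics); purely spatial commodity
contributions keep OA_j unchanged.  The IQI indicates confidence, not
accuracy, and is banded as dLUC-commodity (>= 0.6), dLUC-landuse
([0.55, 0.6)) or sLUC (< 0.55).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_registry import DatasetDescriptor

DEFAULT_FLAG_SCORES = {
    "official": 1.0,
    "semi_official": 0.75,
    "estimated": 0.5,
    "imputed": 0.25,
    "unofficial": 0.25,
}

BAND_DLUC_COMMODITY = "dLUC_commodity"
BAND_DLUC_LANDUSE = "dLUC_landuse"
BAND_SLUC = "sLUC"


def dataset_score(desc: DatasetDescriptor) -> float:
    """Mean of the three equally weighted rubric criteria."""
    scores = (desc.spatial_score, desc.temporal_score, desc.explicitness_score)
    for s in scores:
        if not 0 <= s <= 1:
            raise ValueError("rubric sub-scores must be in [0, 1]")
    return sum(scores) / 3.0


def adjusted_accuracy(
    overall_accuracy: float,
    flag_land_use: str | None,
    flag_production: str | None,
    statistical: bool,
    flag_scores: dict[str, float] | None = None,
) -> float:
    """Flag-adjusted overall accuracy OA'.

    Spatial-commodity contributions keep OA unchanged.  Statistical
    contributions multiply OA by the mean of the two flag scores; an absent
    flag (a source that reports values directly without flagging) scores 1.
    """
    if not statistical:
        return overall_accuracy
    scores = flag_scores or DEFAULT_FLAG_SCORES

    def score(flag):
        if flag is None:
            return 1.0
        try:
            return scores[flag]
        except KeyError:
            raise ValueError(f"unknown flag label {flag!r}") from None

    return overall_accuracy * (score(flag_land_use) + score(flag_production)) / 2.0


def classify_band(iqi: float) -> str:
    if iqi >= 0.6:
        return BAND_DLUC_COMMODITY
    if iqi >= 0.55:
        return BAND_DLUC_LANDUSE
    return BAND_SLUC


@dataclass
class IQIRecord:
    iqi: float | None
    band: str | None
    contributions: list[tuple[float, float, float]] = field(default_factory=list)
    flagged: bool = False  # True when the area total was zero


def compute_iqi(contributions: Sequence[tuple[float, float, float]]) -> IQIRecord:
    """Area-weighted IQI from (FL area, adjusted OA, Score) triples.

    Zero total area leaves the record flagged with no fabricated value.
    """
    contributions = [(float(fl), float(oa), float(sc)) for fl, oa, sc in contributions]
    for fl, _, _ in contributions:
        if fl < 0:
            raise ValueError("contribution areas must be non-negative")
    total = sum(fl for fl, _, _ in contributions)
    if total <= 0:
        return IQIRecord(iqi=None, band=None, contributions=contributions,
                         flagged=True)
    iqi = sum(fl * oa * sc for fl, oa, sc in contributions) / total
    return IQIRecord(iqi=iqi, band=classify_band(iqi), contributions=contributions)


def weighted_average_iqi(records: Iterable[IQIRecord]) -> IQIRecord:
    """Multi-year IQI: pool all contributions, weighting by area."""
    pooled: list[tuple[float, float, float]] = []
    for rec in records:
        pooled.extend(rec.contributions)
    return compute_iqi(pooled)
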