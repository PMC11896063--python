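"""Habitat-quality weights and the Natural Succession Index (NSI).

The NSI of a stratum (climate sub-area or region) is the habitat-quality
weighted fraction of its monitoring samples,

    P = (Q_grassland * n_grassland + Q_shrub * n_shrub + Q_forest * n_forest) / N,

where each quality Q is the reciprocal of the land-cover type's landscape
resistance (circuit-theory convention: forest conducts ecological flow,
grassland resists it). With the default resistances 30/5/1 the index lives
in [1/30, 1]; P = 1 means every sample reached forest.

All arithmetic uses exact reciprocals — rounding happens only at display
(4 decimals, round half up; the rounded display values are NOT suitable for
further computation, e.g. 1/30 and its display 0.0333 yield different
fourth decimals on real strata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import UndefinedIndexError
from .records_io import SeralStage, StageCounts

#: Literature resistance values per seral stage (dimensionless).
DEFAULT_RESISTANCE: Mapping[SeralStage, float] = {
    SeralStage.GRASSLAND: 30.0,
    SeralStage.SHRUB: 5.0,
    SeralStage.FOREST: 1.0,
}


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (table convention), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def habitat_quality(resistance: float) -> float:
    """Quality as the exact reciprocal of a positive resistance."""
    if not resistance > 0:
        raise ValueError(f"resistance must be positive, got {resistance!r}")
    return 1.0 / resistance


@dataclass(frozen=True)
class HabitatQuality:
    """Per-stage resistances and their reciprocal qualities."""

    resistance_by_stage: Mapping[SeralStage, float] = field(
        default_factory=lambda: dict(DEFAULT_RESISTANCE)
    )

    def __post_init__(self) -> None:
        missing = [s for s in SeralStage if s not in self.resistance_by_stage]
        if missing:
            raise ValueError(f"resistance missing for stages {missing}")
        for s, r in self.resistance_by_stage.items():
            if not r > 0:
                raise ValueError(f"resistance for {s.name} must be positive, got {r!r}")

    def quality(self, stage: SeralStage) -> float:
        return habitat_quality(self.resistance_by_stage[stage])

    @property
    def quality_by_stage(self) -> dict[SeralStage, float]:
        return {s: self.quality(s) for s in SeralStage}


def compute_nsi(counts: StageCounts, quality: HabitatQuality | None = None) -> float:
    """Exact (unrounded) NSI of one stratum.

    Undefined for an empty stratum (N = 0): raises rather than returning 0,
    since 0 is below the index's attainable minimum.
    """
    quality = quality or HabitatQuality()
    if counts.N == 0:
        raise UndefinedIndexError("NSI is undefined for an empty stratum (N = 0)")
    weighted = sum(quality.quality(s) * counts.count(s) for s in SeralStage)
    return weighted / counts.N


@dataclass(frozen=True)
class SubAreaIndex:
    """One stratum's NSI row: counts, percentages, exact and display P."""

    subarea_label: str
    counts: StageCounts
    P: float  # exact
    P_display: float  # 4 dp, round half up
    percent_by_stage: Mapping[SeralStage, float]  # 2 dp, round half up


def _index_row(label: str, counts: StageCounts, quality: HabitatQuality) -> SubAreaIndex:
    p = compute_nsi(counts, quality)
    percents = {
        s: round_half_up(100.0 * counts.count(s) / counts.N, 2) for s in SeralStage
    }
    return SubAreaIndex(label, counts, p, round_half_up(p, 4), percents)


def nsi_table(
    counts_by_subarea: Mapping[str, StageCounts],
    quality: HabitatQuality | None = None,
    region_counts: Mapping[str, StageCounts] | None = None,
) -> tuple[list[SubAreaIndex], list[str]]:
    """Index rows for every sub-area and primary region, plus the ordering.

    Region rows are aggregated from sub-area counts (the label prefix before
    the hyphen) unless explicit ``region_counts`` are supplied. The returned
    ordering ranks sub-areas by descending exact P, ties broken by label.
    """
    quality = quality or HabitatQuality()
    sub_rows = [
        _index_row(label, counts_by_subarea[label], quality)
        for label in sorted(counts_by_subarea)
    ]

    if region_counts is None:
        agg: dict[str, StageCounts] = {}
        for label, counts in counts_by_subarea.items():
            region = label.split("-")[0]
            agg[region] = agg.get(region, StageCounts(0, 0, 0)) + counts
        region_counts = agg
    region_rows = [
        _index_row(label, region_counts[label], quality) for label in sorted(region_counts)
    ]

    ordering = [r.subarea_label for r in sorted(sub_rows, key=lambda r: (-r.P, r.subarea_label))]
    return region_rows + sub_rows, ordering


def nsi_table_frame(rows: Sequence[SubAreaIndex]) -> pd.DataFrame:
    """Tabular view of index rows (counts, 2-dp percentages, 4-dp P)."""
    return pd.DataFrame(
        [
            {
                "stratum": r.subarea_label,
                "N": r.counts.N,
                "n_grassland": r.counts.n_grassland,
                "pct_grassland": r.percent_by_stage[SeralStage.GRASSLAND],
                "n_shrub": r.counts.n_shrub,
                "pct_shrub": r.percent_by_stage[SeralStage.SHRUB],
                "n_forest": r.counts.n_forest,
                "pct_forest": r.percent_by_stage[SeralStage.FOREST],
                "P": f"{r.P_display:.4f}",
            }
            for r in rows
        ]
    )


def write_nsi_table(rows: Sequence[SubAreaIndex], path: str | Path) -> None:
    nsi_table_frame(rows).to_csv(path, index=False)
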