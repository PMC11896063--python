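"""Shared fixtures: published index-table values and small hand-built series."""

from __future__ import annotations

import pytest
from hypothesis import settings

from nsikit.records_io import DEFAULT_YEARS, PlotSeries, SeralStage

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

G, S, F = SeralStage.GRASSLAND, SeralStage.SHRUB, SeralStage.FOREST

#: Published per-stratum succession indices (4-dp display values).
PRINTED_P: dict[str, float] = {
    "C": 0.3873, "M": 0.5144, "W": 0.6554, "H": 0.7859,
    "C-I": 0.2943, "C-II": 0.4778,
    "M-I": 0.3624, "M-II": 0.5735, "M-III": 0.6356,
    "W-I": 0.6498, "W-II": 0.3980, "W-III": 0.5644, "W-IV": 0.5571,
    "H-I": 0.7812, "H-II": 0.3375, "H-III": 0.6316, "H-IV": 0.7739,
}

#: Published stage percentages (grassland, shrub, forest) per stratum.
PRINTED_PERCENT: dict[str, tuple[float, float, float]] = {
    "C": (29.58, 40.84, 29.58),
    "M": (33.68, 20.00, 46.32),
    "W": (18.27, 21.00, 60.73),
    "H": (15.37, 8.20, 76.43),
    "C-I": (25.72, 57.14, 17.14),
    "C-II": (33.33, 25.00, 41.67),
    "M-I": (41.94, 29.03, 29.03),
    "M-II": (30.61, 16.33, 53.06),
    "M-III": (26.67, 13.33, 60.00),
    "W-I": (19.28, 20.48, 60.24),
    "W-II": (23.76, 46.54, 29.70),
    "W-III": (23.13, 26.49, 50.38),
    "W-IV": (14.29, 38.10, 47.61),
    "H-I": (13.83, 10.64, 75.53),
    "H-II": (37.50, 37.50, 25.00),
    "H-III": (18.95, 23.16, 57.89),
    "H-IV": (13.38, 12.10, 74.52),
}

#: Cells where the published table was hand-adjusted so each row sums to
#: 100.00; plain 2-dp half-up rounding of 100*n/N differs by one ulp there.
ADJUSTED_PERCENT_CELLS: set[tuple[str, int]] = {
    ("C", 1), ("W", 0), ("C-I", 0), ("W-II", 1), ("W-III", 2), ("W-IV", 2),
}

#: Published descending ordering of the 13 sub-area indices.
PRINTED_ORDER: list[str] = [
    "H-I", "H-IV", "W-I", "M-III", "H-III", "M-II",
    "W-III", "W-IV", "C-II", "W-II", "M-I", "H-II", "C-I",
]


def make_plot(stages, plot_id="P1", town_id="T1", years=DEFAULT_YEARS, **flags) -> PlotSeries:
    """Build a plot series from a stage list on the default census grid."""
    assert len(stages) == len(years)
    return PlotSeries(
        plot_id=plot_id,
        town_id=town_id,
        observations=tuple(zip(years, stages)),
        **flags,
    )


@pytest.fixture
def grass_to_forest_plot() -> PlotSeries:
    """[G, G, G, S, S, F, F]: leaves grassland in (10,15], forest in (20,25]."""
    return make_plot([G, G, G, S, S, F, F])


@pytest.fixture
def all_grass_plot() -> PlotSeries:
    return make_plot([G] * 7)
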