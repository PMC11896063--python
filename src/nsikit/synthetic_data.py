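"""Synthetic towns and monitoring-plot series for closed-loop testing.

The generator emulates the two inputs of the pipeline:

* **towns** — climate factors drawn uniformly within each sub-area's
  published factor box, so threshold-mode zonation recovers the generating
  region exactly (the accumulated-temperature boxes are disjoint across
  regions);
* **plot series** — a latent annual succession chain. Each plot starts as
  grassland; every year it moves grassland -> shrub with probability
  ``p_grass_to_shrub`` and shrub -> forest with probability
  ``p_shrub_to_forest``. The latent state is recorded only at the five-year
  census grid, which reproduces the interval-censoring structure the
  duration estimators must handle. Waiting times are drawn as geometric
  variates, which is exactly the annual-Bernoulli chain.

A scenario's ``favorability`` θ in (0, 1) sets both annual probabilities
through a fixed monotone map, so ordering scenarios by θ orders their
expected succession indices. The default 13 scenarios rank θ as the
published sub-area indices rank, making the generator a statistical stand-in
for the real monitoring system.

The closed-form outcome distribution of the chain after T years is
available in :func:`outcome_probabilities` as an independent check on the
simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .records_io import DEFAULT_YEARS, PlotSeries, SeralStage, StageCounts, TownClimateRecord

#: Published per-sub-area factor boxes: (low, high) per factor. The
#: accumulated-temperature box is the sub-area's region interval.
CLIMATE_BOXES: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "C-I": {"accumulated_temperature": (1489, 3215), "annual_precipitation": (636, 898),
            "relative_humidity": (65, 77), "mean_annual_temperature": (1, 10),
            "mean_altitude": (2614, 4069)},
    "C-II": {"accumulated_temperature": (1489, 3215), "annual_precipitation": (900, 1200),
             "relative_humidity": (65, 85), "mean_annual_temperature": (6, 10),
             "mean_altitude": (2582, 3328)},
    "M-I": {"accumulated_temperature": (3280, 4344), "annual_precipitation": (690, 932),
            "relative_humidity": (74, 84), "mean_annual_temperature": (6, 13),
            "mean_altitude": (1452, 2978)},
    "M-II": {"accumulated_temperature": (3280, 4344), "annual_precipitation": (874, 1135),
             "relative_humidity": (65, 76), "mean_annual_temperature": (8, 13),
             "mean_altitude": (2243, 3021)},
    "M-III": {"accumulated_temperature": (3280, 4344), "annual_precipitation": (1152, 1585),
              "relative_humidity": (73, 81), "mean_annual_temperature": (10, 13),
              "mean_altitude": (2066, 2634)},
    "W-I": {"accumulated_temperature": (4348, 6281), "annual_precipitation": (1166, 1594),
            "relative_humidity": (72, 85), "mean_annual_temperature": (13, 19),
            "mean_altitude": (1181, 2224)},
    "W-II": {"accumulated_temperature": (4348, 6281), "annual_precipitation": (713, 1015),
             "relative_humidity": (63, 76), "mean_annual_temperature": (11, 18),
             "mean_altitude": (1305, 2383)},
    "W-III": {"accumulated_temperature": (4348, 6281), "annual_precipitation": (920, 1240),
              "relative_humidity": (63, 82), "mean_annual_temperature": (11, 19),
              "mean_altitude": (1012, 2645)},
    "W-IV": {"accumulated_temperature": (4348, 6281), "annual_precipitation": (796, 1037),
             "relative_humidity": (75, 85), "mean_annual_temperature": (12, 16),
             "mean_altitude": (613, 1646)},
    "H-I": {"accumulated_temperature": (6302, 8287), "annual_precipitation": (1504, 2253),
            "relative_humidity": (77, 87), "mean_annual_temperature": (16, 23),
            "mean_altitude": (334, 1770)},
    "H-II": {"accumulated_temperature": (6302, 8287), "annual_precipitation": (716, 983),
             "relative_humidity": (63, 75), "mean_annual_temperature": (16, 19),
             "mean_altitude": (1231, 1740)},
    "H-III": {"accumulated_temperature": (6302, 8287), "annual_precipitation": (893, 1266),
              "relative_humidity": (72, 83), "mean_annual_temperature": (15, 22),
              "mean_altitude": (450, 1903)},
    "H-IV": {"accumulated_temperature": (6302, 8287), "annual_precipitation": (1090, 1708),
             "relative_humidity": (71, 86), "mean_annual_temperature": (16, 22),
             "mean_altitude": (579, 1634)},
}

#: Published sub-area ordering by descending succession index.
NSI_DESCENDING_ORDER: tuple[str, ...] = (
    "H-I", "H-IV", "W-I", "M-III", "H-III", "M-II",
    "W-III", "W-IV", "C-II", "W-II", "M-I", "H-II", "C-I",
)


def favorability_to_rates(theta: float) -> tuple[float, float]:
    """Monotone map from favorability θ in (0,1) to annual transition rates.

    Chosen so the default θ grid spans outcomes from mostly-grassland to
    mostly-forest over a 30-year window: at θ≈0.07 roughly half the plots
    never leave grassland; at θ≈0.93 nearly all reach forest.
    """
    if not 0 < theta < 1:
        raise ValueError(f"favorability must be in (0, 1), got {theta!r}")
    return 0.02 + 0.23 * theta, 0.02 + 0.18 * theta


@dataclass(frozen=True)
class SubAreaScenario:
    """Generating conditions for one sub-area's towns and plots."""

    subarea_label: str
    climate_box: Mapping[str, tuple[float, float]]
    favorability: float
    p_grass_to_shrub: float
    p_shrub_to_forest: float
    n_plots: int = 500

    def __post_init__(self) -> None:
        for p in (self.p_grass_to_shrub, self.p_shrub_to_forest):
            if not 0 <= p <= 1:
                raise ValueError(f"transition probability out of [0, 1]: {p!r}")
        if self.n_plots < 0:
            raise ValueError("n_plots must be non-negative")

    @classmethod
    def from_favorability(
        cls,
        subarea_label: str,
        favorability: float,
        n_plots: int = 500,
        climate_box: Mapping[str, tuple[float, float]] | None = None,
    ) -> "SubAreaScenario":
        p1, p2 = favorability_to_rates(favorability)
        box = climate_box if climate_box is not None else CLIMATE_BOXES[subarea_label]
        return cls(subarea_label, box, favorability, p1, p2, n_plots)


def default_scenarios(n_plots: int = 500) -> list[SubAreaScenario]:
    """The 13 sub-area scenarios with θ ranked as the published indices.

    θ = rank/14 over the ascending published-index order, so the synthetic
    province reproduces the published ordering in expectation.
    """
    ascending = list(reversed(NSI_DESCENDING_ORDER))
    return [
        SubAreaScenario.from_favorability(label, (rank + 1) / 14.0, n_plots)
        for rank, label in enumerate(ascending)
    ]


def _rngs(seed: int, n: int, stream: int = 0) -> list[np.random.Generator]:
    """n independent generators for one seed; ``stream`` keys the consumer
    (towns vs plots) so the two draws are independently reproducible."""
    root = np.random.SeedSequence([seed, stream])
    return [np.random.default_rng(s) for s in root.spawn(n)]


def town_ids(label: str, towns_per_subarea: int) -> list[str]:
    """Deterministic town ids encoding the generating sub-area."""
    return [f"{label}.T{i + 1:02d}" for i in range(towns_per_subarea)]


def generate_towns(
    scenarios: Sequence[SubAreaScenario], towns_per_subarea: int = 5, seed: int = 0
) -> list[TownClimateRecord]:
    """Draw each town's factors uniformly within its scenario's box."""
    if not scenarios:
        raise ValueError("no scenarios supplied")
    towns: list[TownClimateRecord] = []
    for sc, rng in zip(scenarios, _rngs(seed, len(scenarios))):
        for tid in town_ids(sc.subarea_label, towns_per_subarea):
            factors = {
                factor: float(rng.uniform(lo, hi))
                for factor, (lo, hi) in sc.climate_box.items()
            }
            towns.append(TownClimateRecord(town_id=tid, **factors))
    return towns


def _waiting_times(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    """Years until first success of an annual Bernoulli(p); inf when p = 0."""
    if p == 0:
        return np.full(size, np.inf)
    return rng.geometric(p, size=size).astype(float)


def generate_plots(
    scenarios: Sequence[SubAreaScenario],
    seed: int = 0,
    years: Sequence[int] = DEFAULT_YEARS,
    towns_per_subarea: int = 5,
) -> list[PlotSeries]:
    """Simulate the latent annual chain, observed at the census grid.

    Plots are spread round-robin over their sub-area's towns (ids match
    :func:`generate_towns` for the same ``towns_per_subarea``). All
    eligibility flags are true: the generator emulates the already-screened
    monitoring panel.
    """
    if not scenarios:
        raise ValueError("no scenarios supplied")
    years = tuple(int(y) for y in years)
    start = years[0]
    offsets = np.array([y - start for y in years])

    plots: list[PlotSeries] = []
    for sc, rng in zip(scenarios, _rngs(seed, len(scenarios), stream=1)):
        t_shrub = _waiting_times(rng, sc.p_grass_to_shrub, sc.n_plots)
        t_forest = t_shrub + _waiting_times(rng, sc.p_shrub_to_forest, sc.n_plots)
        tids = town_ids(sc.subarea_label, towns_per_subarea)
        for j in range(sc.n_plots):
            stages = np.where(
                offsets >= t_forest[j],
                SeralStage.FOREST.value,
                np.where(offsets >= t_shrub[j], SeralStage.SHRUB.value, SeralStage.GRASSLAND.value),
            )
            obs = tuple((y, SeralStage(int(s))) for y, s in zip(years, stages))
            plots.append(
                PlotSeries(
                    plot_id=f"{sc.subarea_label}.P{j + 1:04d}",
                    town_id=tids[j % len(tids)],
                    observations=obs,
                )
            )
    return plots


def outcome_probabilities(
    p_grass_to_shrub: float, p_shrub_to_forest: float, horizon: int = 30
) -> tuple[float, float, float]:
    """Closed-form (grassland, shrub, forest) outcome probabilities.

    For the two-step absorbing chain over ``horizon`` annual steps:
    P(grassland) = (1-p1)^T and P(shrub) sums over the year the first
    transition lands, P(shrub) = Σ_{k=1..T} p1 (1-p1)^(k-1) (1-p2)^(T-k).
    """
    p1, p2, T = p_grass_to_shrub, p_shrub_to_forest, horizon
    p_grass = (1 - p1) ** T
    p_shrub = float(
        sum(p1 * (1 - p1) ** (k - 1) * (1 - p2) ** (T - k) for k in range(1, T + 1))
    )
    return p_grass, p_shrub, 1.0 - p_grass - p_shrub


# ---------------------------------------------------------------------------
# Published per-stratum stage counts, kept verbatim as a regression fixture.
# ---------------------------------------------------------------------------

_TABLE3_COUNTS: Mapping[str, tuple[int, int, int]] = {
    # region rows (as printed; W and H are not the sums of their sub-areas)
    "C": (21, 29, 21),
    "M": (32, 19, 44),
    "W": (120, 138, 399),
    "H": (75, 40, 373),
    # sub-area rows
    "C-I": (9, 20, 6),
    "C-II": (12, 9, 15),
    "M-I": (13, 9, 9),
    "M-II": (15, 8, 26),
    "M-III": (4, 2, 9),
    "W-I": (32, 34, 100),
    "W-II": (48, 94, 60),
    "W-III": (62, 71, 135),
    "W-IV": (3, 8, 10),
    "H-I": (26, 20, 142),
    "H-II": (18, 18, 12),
    "H-III": (18, 22, 55),
    "H-IV": (21, 19, 117),
}


def table3_fixture(stratum: str | None = None) -> StageCounts | dict[str, StageCounts]:
    """Published per-stratum stage counts (13 sub-areas + 4 regions).

    With a stratum label, returns that row's counts; without, the full map.
    """
    if stratum is not None:
        if stratum not in _TABLE3_COUNTS:
            raise KeyError(f"unknown stratum {stratum!r}")
        return StageCounts(*_TABLE3_COUNTS[stratum])
    return {k: StageCounts(*v) for k, v in _TABLE3_COUNTS.items()}


def table3_subarea_fixture() -> dict[str, StageCounts]:
    """Only the 13 sub-area rows of the published counts."""
    return {k: StageCounts(*v) for k, v in _TABLE3_COUNTS.items() if "-" in k}


def table3_region_fixture() -> dict[str, StageCounts]:
    """Only the 4 region rows of the published counts (as printed)."""
    return {k: StageCounts(*v) for k, v in _TABLE3_COUNTS.items() if "-" not in k}
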