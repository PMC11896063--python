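"""Succession-outcome classification and interval-censored stage durations.

Every eligible plot starts as grassland in the first census. Thirty years
later it is in exactly one of three outcomes, determined solely by its final
observation:

* **non-succession** — still grassland;
* **hard succession** — reached shrub but not forest;
* **accessible succession** — reached forest.

Because the latent transitions happen between censuses, a transition time is
only ever known to an interval: (last year observed in the old stage, first
year observed in the new stage]. The point estimator is configurable —
``midpoint`` (default; unbiased if the transition time is uniform within the
interval), ``first_observation`` (upper bracket) or ``last_previous`` (lower
bracket). Durations whose end was never observed are right-censored and are
excluded from means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from scipy.stats import spearmanr

from .errors import IntegrityError, NonMonotoneSeriesError
from .records_io import PlotSeries, SeralStage, StageCounts

logger = logging.getLogger(__name__)

ESTIMATORS = ("midpoint", "first_observation", "last_previous")


class SuccessionOutcome(Enum):
    """Three succession outcomes after the 30-year monitoring window."""

    NON_SUCCESSION = "non_succession"  # grassland stage in the final census
    HARD_SUCCESSION = "hard_succession"  # shrub stage in the final census
    ACCESSIBLE_SUCCESSION = "accessible_succession"  # forest stage

    @property
    def stage(self) -> SeralStage:
        return _STAGE_OF_OUTCOME[self]


_OUTCOME_OF_STAGE: Mapping[SeralStage, SuccessionOutcome] = {
    SeralStage.GRASSLAND: SuccessionOutcome.NON_SUCCESSION,
    SeralStage.SHRUB: SuccessionOutcome.HARD_SUCCESSION,
    SeralStage.FOREST: SuccessionOutcome.ACCESSIBLE_SUCCESSION,
}
_STAGE_OF_OUTCOME = {v: k for k, v in _OUTCOME_OF_STAGE.items()}


def _check_monotone(plot: PlotSeries, on_nonmonotone: str) -> None:
    if plot.is_monotone:
        return
    if on_nonmonotone == "error":
        raise NonMonotoneSeriesError(
            f"plot {plot.plot_id}: series regresses to an earlier stage "
            f"({[s.name for s in plot.stages]}); succession is one-directional"
        )
    logger.warning("plot %s: non-monotone series; using final stage", plot.plot_id)


def classify_plot(plot: PlotSeries, on_nonmonotone: str = "error") -> SuccessionOutcome:
    """Outcome of an eligible plot from its final-census stage.

    Stage regressions (e.g. shrub back to grassland) violate the
    one-directional succession chain; by default they raise, or with
    ``on_nonmonotone="final"`` the final stage is used with a warning.
    """
    _check_monotone(plot, on_nonmonotone)
    return _OUTCOME_OF_STAGE[plot.final_stage]


@dataclass(frozen=True)
class Duration:
    """An interval-censored duration in years, relative to the series start.

    ``lower < true value <= upper``; ``upper`` is +inf (and ``point`` None)
    when the end of the duration was never observed.
    """

    lower: float
    upper: float
    point: float | None
    censored: bool


@dataclass(frozen=True)
class StageDurations:
    """Bracketed stage-transition times for one plot.

    ``grassland`` is the time to leave grassland (= enter shrub),
    ``time_to_forest`` the time to enter forest, ``shrub`` their difference
    (time spent in shrub), all measured from the first census.
    ``forest_tenure`` is the time spent in forest by the final census (None
    while forest is unreached).
    """

    grassland: Duration
    shrub: Duration
    time_to_forest: Duration
    forest_tenure: float | None
    estimator: str


def _point(lower: float, upper: float, estimator: str) -> float:
    if estimator == "midpoint":
        return (lower + upper) / 2.0
    if estimator == "first_observation":
        return upper
    if estimator == "last_previous":
        return lower
    raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")


def stage_durations(
    plot: PlotSeries, estimator: str = "midpoint", on_nonmonotone: str = "error"
) -> StageDurations:
    """Bracket each transition between the censuses that straddle it."""
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    _check_monotone(plot, on_nonmonotone)

    start = plot.start_year
    rel = [y - start for y in plot.years]
    stages = plot.stages
    total = rel[-1]

    first_non_grass = next((i for i, s in enumerate(stages) if s > SeralStage.GRASSLAND), None)
    first_forest = next((i for i, s in enumerate(stages) if s is SeralStage.FOREST), None)

    if first_non_grass is None:
        grass = Duration(lower=total, upper=math.inf, point=None, censored=True)
    else:
        lo, hi = rel[first_non_grass - 1], rel[first_non_grass]
        grass = Duration(lo, hi, _point(lo, hi, estimator), censored=False)

    if first_forest is None:
        ttf_lower = total
        ttf = Duration(lower=total, upper=math.inf, point=None, censored=True)
    else:
        lo, hi = rel[first_forest - 1], rel[first_forest]
        ttf = Duration(lo, hi, _point(lo, hi, estimator), censored=False)

    if first_forest is not None:
        # Shrub residence = entry-to-forest minus exit-from-grassland.
        lo = max(0.0, ttf.lower - grass.upper)
        hi = ttf.upper - grass.lower
        shrub = Duration(lo, hi, ttf.point - grass.point, censored=False)
    elif first_non_grass is not None:
        shrub = Duration(lower=total - grass.upper, upper=math.inf, point=None, censored=True)
    else:
        shrub = Duration(lower=0.0, upper=math.inf, point=None, censored=True)

    tenure = None if ttf.censored else total - ttf.point
    return StageDurations(grass, shrub, ttf, forest_tenure=tenure, estimator=estimator)


@dataclass(frozen=True)
class SubAreaSummary:
    """Per-sub-area outcome tallies and mean (uncensored) durations."""

    subarea_label: str
    counts: StageCounts
    mean_time_to_forest: float | None
    mean_forest_tenure: float | None
    log10_mean_forest_tenure: float | None


def summarize_subarea(
    plots: Iterable[PlotSeries],
    subarea_of: Mapping[str, str],
    estimator: str = "midpoint",
    on_nonmonotone: str = "error",
) -> dict[str, SubAreaSummary]:
    """Tally outcomes and average durations per sub-area.

    Means run over uncensored values only. The logarithm is taken of the
    mean forest tenure (log10 of the mean, not the mean of logs), matching
    how the trend comparison is displayed on a log axis.
    """
    by_sub: dict[str, list[PlotSeries]] = {}
    for p in plots:
        if p.plot_id not in subarea_of:
            raise IntegrityError(f"plot {p.plot_id} has no sub-area assignment")
        by_sub.setdefault(subarea_of[p.plot_id], []).append(p)

    out: dict[str, SubAreaSummary] = {}
    for label in sorted(by_sub):
        members = by_sub[label]
        tallies = {o: 0 for o in SuccessionOutcome}
        ttf: list[float] = []
        tenure: list[float] = []
        for p in members:
            tallies[classify_plot(p, on_nonmonotone)] += 1
            d = stage_durations(p, estimator, on_nonmonotone)
            if not d.time_to_forest.censored:
                ttf.append(d.time_to_forest.point)
                tenure.append(d.forest_tenure)
        counts = StageCounts(
            tallies[SuccessionOutcome.NON_SUCCESSION],
            tallies[SuccessionOutcome.HARD_SUCCESSION],
            tallies[SuccessionOutcome.ACCESSIBLE_SUCCESSION],
        )
        mean_ttf = sum(ttf) / len(ttf) if ttf else None
        mean_tenure = sum(tenure) / len(tenure) if tenure else None
        log_tenure = (
            math.log10(mean_tenure) if mean_tenure is not None and mean_tenure > 0 else None
        )
        out[label] = SubAreaSummary(label, counts, mean_ttf, mean_tenure, log_tenure)
    return out


def nsi_time_correlation(
    nsi_by_subarea: Mapping[str, float], log_tenure_by_subarea: Mapping[str, float]
) -> float:
    """Spearman rank correlation of sub-area NSI with log10 forest tenure.

    The sub-area is the unit. Requires at least three sub-areas carrying
    both quantities; a constant input yields an undefined correlation,
    reported as NaN with a warning.
    """
    common = sorted(set(nsi_by_subarea) & set(log_tenure_by_subarea))
    common = [c for c in common if log_tenure_by_subarea[c] is not None]
    if len(common) < 3:
        raise ValueError(f"need >= 3 sub-areas with both quantities, got {len(common)}")
    x = [nsi_by_subarea[c] for c in common]
    y = [log_tenure_by_subarea[c] for c in common]
    if len(set(x)) == 1 or len(set(y)) == 1:
        logger.warning("constant input: rank correlation undefined")
        return math.nan
    return float(spearmanr(x, y).statistic)
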