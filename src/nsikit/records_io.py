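"""Domain records and CSV readers/writers for towns and monitoring plots.

Two tables drive the analysis:

* a **town climate table** — one row per town with five climate/terrain
  factors (annual accumulated temperature in °C·day, annual precipitation in
  mm, relative humidity in %, mean annual temperature in °C, mean altitude
  in m);
* a **plot series table** (long format) — one row per (plot, year) with the
  seral stage observed on that date, plus per-plot eligibility flags from the
  monitoring protocol.

Column names are configuration, not convention: both readers accept a
column-name map with sensible defaults, because deposited supplementary
tables rarely share headers. Missing eligibility-flag columns default to
``True`` with a logged warning (archived tables are typically pre-filtered
to eligible plots).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, RowParseError, SchemaError, StageCodeError

logger = logging.getLogger(__name__)

#: Default observation grid: seven five-yearly censuses, 1987-2017.
DEFAULT_YEARS: tuple[int, ...] = tuple(range(1987, 2018, 5))


class SeralStage(IntEnum):
    """Ordered secondary-succession stages, earliest to latest.

    The succession chain runs grassland -> shrub -> forest; the ordering of
    the enum encodes the succession direction (a later stage compares
    greater). Bare ground before grassland is never observed in 30-year
    monitoring series that start on grassland and is not a member.
    """

    GRASSLAND = 1
    SHRUB = 2
    FOREST = 3

    @classmethod
    def from_code(cls, code: str, code_table: Mapping[str, "SeralStage"] | None = None) -> "SeralStage":
        """Map a land-cover code to a stage, case-insensitively.

        Raises :class:`StageCodeError` for anything outside the closed
        three-value vocabulary — dirty data fails loudly rather than being
        silently dropped.
        """
        table = {k.lower(): v for k, v in (code_table or DEFAULT_STAGE_CODES).items()}
        key = str(code).strip().lower()
        if key not in table:
            raise StageCodeError(f"unknown seral-stage code {code!r}; expected one of {sorted(table)}")
        return table[key]


DEFAULT_STAGE_CODES: Mapping[str, SeralStage] = {
    "grassland": SeralStage.GRASSLAND,
    "shrub": SeralStage.SHRUB,
    "forest": SeralStage.FOREST,
}

#: Stage -> canonical lower-case code used on output.
STAGE_NAMES: Mapping[SeralStage, str] = {s: s.name.lower() for s in SeralStage}


@dataclass(frozen=True)
class TownClimateRecord:
    """One town's five climate/terrain factors; the unit of zonation."""

    town_id: str
    accumulated_temperature: float  # °C·day, annual sum of daily means > 0 °C
    annual_precipitation: float  # mm
    relative_humidity: float  # percent
    mean_annual_temperature: float  # °C
    mean_altitude: float  # m

    def __post_init__(self) -> None:
        if not self.accumulated_temperature > 0:
            raise ValueError(f"town {self.town_id}: accumulated_temperature must be > 0")
        if not 0 < self.relative_humidity <= 100:
            raise ValueError(f"town {self.town_id}: relative_humidity must be in (0, 100]")
        if self.annual_precipitation < 0:
            raise ValueError(f"town {self.town_id}: annual_precipitation must be >= 0")


#: Secondary-division factors (everything but the primary factor).
SECONDARY_FACTORS: tuple[str, ...] = (
    "annual_precipitation",
    "relative_humidity",
    "mean_annual_temperature",
    "mean_altitude",
)

TOWN_FIELDS: tuple[str, ...] = ("town_id", "accumulated_temperature") + SECONDARY_FACTORS

ELIGIBILITY_FLAGS: tuple[str, ...] = (
    "initial_grassland",
    "disturbance_cleared",
    "disaster_free",
    "protected",
)


@dataclass(frozen=True)
class PlotSeries:
    """One monitoring plot's dated seral-stage observations plus flags.

    ``observations`` is an ordered tuple of ``(calendar_year, stage)`` pairs
    on an evenly spaced grid (default five-yearly). The four boolean flags
    encode the monitoring protocol's eligibility screen: the plot started as
    grassland, early grazing/cutting disturbance disappeared, no significant
    natural disaster occurred, and the plot was under patrol protection.
    """

    plot_id: str
    town_id: str
    observations: tuple[tuple[int, SeralStage], ...]
    initial_grassland: bool = True
    disturbance_cleared: bool = True
    disaster_free: bool = True
    protected: bool = True

    def __post_init__(self) -> None:
        years = [y for y, _ in self.observations]
        if len(years) < 1:
            raise ValueError(f"plot {self.plot_id}: no observations")
        diffs = {b - a for a, b in zip(years, years[1:])}
        if any(d <= 0 for d in diffs):
            raise ValueError(f"plot {self.plot_id}: observation years must be strictly increasing")
        if len(diffs) > 1:
            raise ValueError(f"plot {self.plot_id}: observation years must be evenly spaced, got gaps {sorted(diffs)}")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(y for y, _ in self.observations)

    @property
    def stages(self) -> tuple[SeralStage, ...]:
        return tuple(s for _, s in self.observations)

    @property
    def start_year(self) -> int:
        return self.observations[0][0]

    @property
    def final_stage(self) -> SeralStage:
        return self.observations[-1][1]

    @property
    def interval(self) -> int:
        """Observation spacing in years (0 for a single observation)."""
        ys = self.years
        return ys[1] - ys[0] if len(ys) > 1 else 0

    @property
    def is_monotone(self) -> bool:
        """True when the series never regresses to an earlier stage."""
        st = self.stages
        return all(b >= a for a, b in zip(st, st[1:]))


@dataclass(frozen=True)
class StageCounts:
    """(grassland, shrub, forest) sample tallies for one stratum."""

    n_grassland: int
    n_shrub: int
    n_forest: int

    def __post_init__(self) -> None:
        if min(self.n_grassland, self.n_shrub, self.n_forest) < 0:
            raise ValueError("stage counts must be non-negative")

    @property
    def N(self) -> int:
        """Total samples in the stratum."""
        return self.n_grassland + self.n_shrub + self.n_forest

    def count(self, stage: SeralStage) -> int:
        return {
            SeralStage.GRASSLAND: self.n_grassland,
            SeralStage.SHRUB: self.n_shrub,
            SeralStage.FOREST: self.n_forest,
        }[stage]

    def __add__(self, other: "StageCounts") -> "StageCounts":
        return StageCounts(
            self.n_grassland + other.n_grassland,
            self.n_shrub + other.n_shrub,
            self.n_forest + other.n_forest,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

DEFAULT_PLOT_COLUMNS: Mapping[str, str] = {
    "plot_id": "plot_id",
    "town_id": "town_id",
    "year": "year",
    "stage": "stage",
    **{f: f for f in ELIGIBILITY_FLAGS},
}

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(value: object, row: int, column: str) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RowParseError(f"row {row}: column {column!r}: cannot parse boolean from {value!r}", row=row)


def _require_columns(frame: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def read_town_records(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[TownClimateRecord]:
    """Read the town climate table.

    ``columns`` maps canonical field names to the file's header names;
    omitted entries fall back to the canonical names themselves. Units are
    taken at face value and nothing is imputed.
    """
    colmap = {f: f for f in TOWN_FIELDS} | dict(columns or {})
    frame = pd.read_csv(path, dtype=str)
    _require_columns(frame, colmap.values(), f"town table {path}")

    records: list[TownClimateRecord] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        town_id = str(row[colmap["town_id"]]).strip()
        if town_id in seen:
            raise IntegrityError(f"duplicate town_id {town_id!r} at row {i}")
        seen.add(town_id)
        values: dict[str, float] = {}
        for canon in TOWN_FIELDS[1:]:
            raw = row[colmap[canon]]
            try:
                values[canon] = float(raw)
            except (TypeError, ValueError):
                raise RowParseError(
                    f"row {i}: column {colmap[canon]!r}: non-numeric value {raw!r}", row=int(i)
                ) from None
        records.append(TownClimateRecord(town_id=town_id, **values))
    return records


def write_town_records(records: Sequence[TownClimateRecord], path: str | Path) -> None:
    """Write the town climate table with deterministic column order."""
    frame = pd.DataFrame([{f: getattr(r, f) for f in TOWN_FIELDS} for r in records])
    frame.to_csv(path, index=False, columns=list(TOWN_FIELDS))


def read_plot_series(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    stage_codes: Mapping[str, SeralStage] | None = None,
) -> list[PlotSeries]:
    """Read the long-format plot table: one row per (plot, year).

    Observations are sorted by year per plot. Eligibility-flag columns that
    are absent default to ``True`` (with a logged warning); within a plot the
    flags must be constant across rows.
    """
    colmap = dict(DEFAULT_PLOT_COLUMNS) | dict(columns or {})
    frame = pd.read_csv(path, dtype=str)
    core = [colmap[k] for k in ("plot_id", "town_id", "year", "stage")]
    _require_columns(frame, core, f"plot table {path}")

    present_flags = [f for f in ELIGIBILITY_FLAGS if colmap[f] in frame.columns]
    absent = [f for f in ELIGIBILITY_FLAGS if f not in present_flags]
    if absent:
        logger.warning(
            "plot table %s: eligibility columns %s absent; defaulting to True", path, absent
        )

    by_plot: dict[str, dict] = {}
    for i, row in frame.iterrows():
        plot_id = str(row[colmap["plot_id"]]).strip()
        town_id = str(row[colmap["town_id"]]).strip()
        try:
            year = int(float(row[colmap["year"]]))
        except (TypeError, ValueError):
            raise RowParseError(
                f"row {i}: column {colmap['year']!r}: non-numeric year {row[colmap['year']]!r}",
                row=int(i),
            ) from None
        stage = SeralStage.from_code(row[colmap["stage"]], stage_codes)
        flags = {f: _parse_bool(row[colmap[f]], int(i), colmap[f]) for f in present_flags}

        entry = by_plot.setdefault(
            plot_id, {"town_id": town_id, "obs": {}, "flags": flags}
        )
        if entry["town_id"] != town_id:
            raise IntegrityError(f"plot {plot_id}: inconsistent town_id ({entry['town_id']!r} vs {town_id!r})")
        if entry["flags"] != flags:
            raise IntegrityError(f"plot {plot_id}: eligibility flags vary across rows")
        if year in entry["obs"]:
            raise IntegrityError(f"duplicate observation for plot {plot_id!r}, year {year}")
        entry["obs"][year] = stage

    plots: list[PlotSeries] = []
    for plot_id, entry in by_plot.items():
        obs = tuple(sorted(entry["obs"].items()))
        flags = {f: entry["flags"].get(f, True) for f in ELIGIBILITY_FLAGS}
        plots.append(PlotSeries(plot_id=plot_id, town_id=entry["town_id"], observations=obs, **flags))
    return plots


def write_plot_series(plots: Sequence[PlotSeries], path: str | Path) -> None:
    """Write plots in long format (one row per observation), flags repeated."""
    rows = []
    for p in plots:
        for year, stage in p.observations:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "town_id": p.town_id,
                    "year": year,
                    "stage": STAGE_NAMES[stage],
                    **{f: getattr(p, f) for f in ELIGIBILITY_FLAGS},
                }
            )
    cols = ["plot_id", "town_id", "year", "stage", *ELIGIBILITY_FLAGS]
    pd.DataFrame(rows).to_csv(path, index=False, columns=cols)


def filter_eligible(plots: Iterable[PlotSeries]) -> list[PlotSeries]:
    """Keep only plots passing the monitoring protocol's eligibility screen.

    A plot is eligible when all four flags hold and its first observation is
    grassland. Order is preserved; the number of removals is logged. The
    operation is idempotent and its output is a subset of its input.
    """
    plots = list(plots)
    kept = [
        p
        for p in plots
        if all(getattr(p, f) for f in ELIGIBILITY_FLAGS)
        and p.observations[0][1] is SeralStage.GRASSLAND
    ]
    removed = len(plots) - len(kept)
    if removed:
        logger.info("filter_eligible: removed %d of %d plots", removed, len(plots))
    return kept
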