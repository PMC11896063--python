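"""Two-stage climate regionalization of towns.

The primary division splits towns into four regions (C, M, W, H, coldest to
hottest) on annual accumulated temperature alone; the secondary division
splits each region on the four remaining factors (precipitation, humidity,
mean temperature, altitude). Two modes are supported:

* ``cluster`` — agglomerative hierarchical clustering (Ward linkage on
  Euclidean distance, factors z-scored within region), the standard choice
  for climate regionalization;
* ``threshold`` — assignment by the published accumulated-temperature
  intervals, useful as a deterministic regression surface and for
  closed-loop tests against the synthetic generator.

Sub-area labels (roman numerals within a region) are an internal convention:
clusters are numbered by descending size, ties broken by ascending mean
precipitation then ascending minimum town id. Published label orderings
cannot be recovered from cluster output in general, so comparisons against
published sub-areas should be label-free (partition comparisons) or use
threshold mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigurationError, IntegrityError
from .records_io import SECONDARY_FACTORS, PlotSeries, TownClimateRecord

logger = logging.getLogger(__name__)

#: Published accumulated-temperature intervals (°C·day) per primary region.
PRIMARY_TEMPERATURE_INTERVALS: Mapping[str, tuple[float, float]] = {
    "C": (1489.0, 3215.0),
    "M": (3280.0, 4344.0),
    "W": (4348.0, 6281.0),
    "H": (6302.0, 8287.0),
}

#: Region labels, coldest to hottest.
REGION_ORDER: tuple[str, ...] = ("C", "M", "W", "H")

#: Published sub-area counts per region.
DEFAULT_SECONDARY_K: Mapping[str, int] = {"C": 2, "M": 3, "W": 4, "H": 4}

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def roman(n: int) -> str:
    """Roman numeral for small positive n (sub-area suffixes)."""
    if not 1 <= n <= len(_ROMAN):
        raise ValueError(f"roman numeral out of supported range: {n}")
    return _ROMAN[n - 1]


@dataclass(frozen=True)
class ZonationConfig:
    """Configuration for the two-stage division."""

    primary_k: int = 4
    secondary_k: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_SECONDARY_K))
    linkage: str = "ward"
    standardize: bool = True
    mode: str = "cluster"  # "cluster" | "threshold"

    def __post_init__(self) -> None:
        if self.primary_k < 1:
            raise ConfigurationError("primary_k must be >= 1")
        if self.mode not in ("cluster", "threshold"):
            raise ConfigurationError(f"unknown zonation mode {self.mode!r}")
        if any(k < 1 for k in self.secondary_k.values()):
            raise ConfigurationError("every secondary k must be >= 1")


@dataclass(frozen=True)
class SubAreaAssignment:
    """A town's region and sub-area membership."""

    town_id: str
    region_label: str
    subarea_label: str

    def __post_init__(self) -> None:
        if not self.subarea_label.startswith(self.region_label + "-"):
            raise ValueError(
                f"sub-area {self.subarea_label!r} does not belong to region {self.region_label!r}"
            )


def _threshold_region(value: float) -> str:
    for label, (lo, hi) in PRIMARY_TEMPERATURE_INTERVALS.items():
        if lo <= value <= hi:
            return label
    # Outside every published interval: snap to the nearest one.
    nearest = min(
        PRIMARY_TEMPERATURE_INTERVALS,
        key=lambda lab: min(
            abs(value - PRIMARY_TEMPERATURE_INTERVALS[lab][0]),
            abs(value - PRIMARY_TEMPERATURE_INTERVALS[lab][1]),
        ),
    )
    logger.warning(
        "accumulated temperature %.1f outside all published intervals; assigned to nearest region %s",
        value,
        nearest,
    )
    return nearest


def primary_division(
    towns: Sequence[TownClimateRecord], config: ZonationConfig | None = None
) -> dict[str, str]:
    """Partition towns into primary regions on accumulated temperature.

    Returns a ``town_id -> region_label`` map. In cluster mode, groups are
    relabeled C, M, W, H in ascending order of group-mean accumulated
    temperature, so labels are invariant under permutation of input rows.
    """
    config = config or ZonationConfig()
    if not towns:
        raise ConfigurationError("no towns to divide")
    if config.mode == "threshold":
        return {t.town_id: _threshold_region(t.accumulated_temperature) for t in towns}

    if len(towns) < config.primary_k:
        raise ConfigurationError(
            f"primary_k={config.primary_k} exceeds the number of towns ({len(towns)})"
        )
    # Sort by (value, id) first so the merge order, and hence any tie
    # handling inside the linkage, is independent of input row order.
    order = sorted(range(len(towns)), key=lambda i: (towns[i].accumulated_temperature, towns[i].town_id))
    values = np.array([[towns[i].accumulated_temperature] for i in order])
    if config.primary_k == 1:
        groups = np.ones(len(towns), dtype=int)
    else:
        tree = linkage(values, method=config.linkage)
        groups = fcluster(tree, t=config.primary_k, criterion="maxclust")

    means = {g: values[groups == g, 0].mean() for g in np.unique(groups)}
    if config.primary_k == len(REGION_ORDER):
        labels = REGION_ORDER
    else:
        labels = tuple(f"R{i + 1}" for i in range(config.primary_k))
    by_mean = sorted(means, key=means.get)
    relabel = {g: labels[rank] for rank, g in enumerate(by_mean)}
    return {towns[i].town_id: relabel[g] for i, g in zip(order, groups)}


def secondary_division(
    towns: Sequence[TownClimateRecord],
    region_label: str,
    k: int,
    config: ZonationConfig | None = None,
) -> dict[str, str]:
    """Cluster one region's towns into k sub-areas on the four factors.

    Factors are z-scored within the region when ``standardize`` is set.
    Clusters are relabeled I, II, ... by descending size, ties broken by
    ascending mean precipitation then ascending minimum town id, which makes
    the labeling fully deterministic.
    """
    config = config or ZonationConfig()
    if k > len(towns):
        raise ConfigurationError(
            f"region {region_label}: k={k} exceeds its town count ({len(towns)})"
        )
    order = sorted(range(len(towns)), key=lambda i: towns[i].town_id)
    X = np.array([[getattr(towns[i], f) for f in SECONDARY_FACTORS] for i in order], dtype=float)
    if config.standardize and len(towns) > 1:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if k == 1 or len(towns) == 1:
        groups = np.ones(len(towns), dtype=int)
    else:
        tree = linkage(X, method=config.linkage)
        groups = fcluster(tree, t=k, criterion="maxclust")

    precip = np.array([towns[i].annual_precipitation for i in order])
    ids = [towns[i].town_id for i in order]
    keys = {}
    for g in np.unique(groups):
        members = groups == g
        keys[g] = (-int(members.sum()), float(precip[members].mean()), min(np.array(ids)[members]))
    ranked = sorted(keys, key=keys.get)
    relabel = {g: f"{region_label}-{roman(rank + 1)}" for rank, g in enumerate(ranked)}
    return {tid: relabel[g] for tid, g in zip(ids, groups)}


def zonate(
    towns: Sequence[TownClimateRecord], config: ZonationConfig | None = None
) -> list[SubAreaAssignment]:
    """Run both divisions and return one assignment per town."""
    config = config or ZonationConfig()
    region_of = primary_division(towns, config)
    by_region: dict[str, list[TownClimateRecord]] = {}
    for t in towns:
        by_region.setdefault(region_of[t.town_id], []).append(t)

    assignments: list[SubAreaAssignment] = []
    for region, members in by_region.items():
        k = config.secondary_k.get(region, 1)
        sub_of = secondary_division(members, region, k, config)
        assignments.extend(
            SubAreaAssignment(t.town_id, region, sub_of[t.town_id]) for t in members
        )
    assignments.sort(key=lambda a: a.town_id)
    return assignments


def assign_plots(
    plots: Iterable[PlotSeries], assignments: Iterable[SubAreaAssignment]
) -> dict[str, str]:
    """Map each plot to its town's sub-area (pure inheritance, no geometry)."""
    sub_of_town = {a.town_id: a.subarea_label for a in assignments}
    result: dict[str, str] = {}
    orphans: list[str] = []
    for p in plots:
        if p.town_id not in sub_of_town:
            orphans.append(p.plot_id)
        else:
            result[p.plot_id] = sub_of_town[p.town_id]
    if orphans:
        raise IntegrityError(f"plots with towns absent from the assignment: {orphans}")
    return result
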