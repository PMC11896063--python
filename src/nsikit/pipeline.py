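"""End-to-end orchestration with file-based stage boundaries.

Each stage reads and writes CSV, so any stage's output can be inspected or
re-run on its own; a JSON run manifest records the configuration snapshot,
input digests, seed, stage timings and output files for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import investment_reallocation as realloc
from . import nsi_index, records_io, succession_stages, synthetic_data
from .climate_zonation import SubAreaAssignment, ZonationConfig, assign_plots, zonate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full run."""

    zonation: ZonationConfig = field(default_factory=ZonationConfig)
    estimator: str = "midpoint"
    on_nonmonotone: str = "error"
    resistance: Mapping[str, float] | None = None  # stage name -> resistance

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        zon = raw.get("zonation", {})
        zcfg = ZonationConfig(
            primary_k=zon.get("primary_k", 4),
            secondary_k=zon.get("secondary_k", dict(records_io_default_secondary())),
            linkage=zon.get("linkage", "ward"),
            standardize=zon.get("standardize", True),
            mode=zon.get("mode", "cluster"),
        )
        return cls(
            zonation=zcfg,
            estimator=raw.get("estimator", "midpoint"),
            on_nonmonotone=raw.get("on_nonmonotone", "error"),
            resistance=raw.get("resistance"),
        )

    def quality(self) -> nsi_index.HabitatQuality:
        if self.resistance is None:
            return nsi_index.HabitatQuality()
        by_stage = {
            records_io.SeralStage.from_code(name): float(r)
            for name, r in self.resistance.items()
        }
        return nsi_index.HabitatQuality(by_stage)


def records_io_default_secondary() -> Mapping[str, int]:
    from .climate_zonation import DEFAULT_SECONDARY_K

    return DEFAULT_SECONDARY_K


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to the outputs."""

    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    seed: int | None = None
    timings: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


class _Timer:
    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest, self.stage = manifest, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings[self.stage] = round(time.perf_counter() - self.t0, 6)
        return False


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["zonation"]["secondary_k"] = dict(snap["zonation"]["secondary_k"])
    return snap


def write_assignments(assignments: Sequence[SubAreaAssignment], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(a) for a in assignments],
        columns=["town_id", "region_label", "subarea_label"],
    ).to_csv(path, index=False)


def read_assignments(path: str | Path) -> list[SubAreaAssignment]:
    frame = pd.read_csv(path, dtype=str)
    return [
        SubAreaAssignment(r.town_id, r.region_label, r.subarea_label)
        for r in frame.itertuples()
    ]


def outcome_table(
    plots: Sequence[records_io.PlotSeries],
    subarea_of: Mapping[str, str],
    estimator: str = "midpoint",
    on_nonmonotone: str = "error",
) -> pd.DataFrame:
    """Per-plot outcome and bracketed durations as a flat table."""
    rows = []
    for p in plots:
        outcome = succession_stages.classify_plot(p, on_nonmonotone)
        d = succession_stages.stage_durations(p, estimator, on_nonmonotone)
        rows.append(
            {
                "plot_id": p.plot_id,
                "subarea_label": subarea_of[p.plot_id],
                "outcome": outcome.value,
                "grassland_lo": d.grassland.lower,
                "grassland_hi": d.grassland.upper,
                "grassland_pt": d.grassland.point,
                "grassland_censored": d.grassland.censored,
                "shrub_lo": d.shrub.lower,
                "shrub_hi": d.shrub.upper,
                "shrub_pt": d.shrub.point,
                "shrub_censored": d.shrub.censored,
                "time_to_forest_lo": d.time_to_forest.lower,
                "time_to_forest_hi": d.time_to_forest.upper,
                "time_to_forest_pt": d.time_to_forest.point,
                "time_to_forest_censored": d.time_to_forest.censored,
                "forest_tenure": d.forest_tenure,
            }
        )
    return pd.DataFrame(rows)


def run_simulate(
    output_dir: str | Path,
    scenarios: Sequence[synthetic_data.SubAreaScenario] | None = None,
    seed: int = 0,
    towns_per_subarea: int = 5,
) -> RunManifest:
    """Generate synthetic town and plot tables and write them as CSV."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = list(scenarios) if scenarios is not None else synthetic_data.default_scenarios()
    manifest = RunManifest(config={"scenarios": [s.subarea_label for s in scenarios],
                                   "towns_per_subarea": towns_per_subarea}, seed=seed)
    with _Timer(manifest, "generate_towns"):
        towns = synthetic_data.generate_towns(scenarios, towns_per_subarea, seed)
        records_io.write_town_records(towns, out / "towns.csv")
    with _Timer(manifest, "generate_plots"):
        plots = synthetic_data.generate_plots(scenarios, seed, towns_per_subarea=towns_per_subarea)
        records_io.write_plot_series(plots, out / "plots.csv")
    manifest.outputs = ["towns.csv", "plots.csv"]
    manifest.write(out / "manifest.json")
    return manifest


def run_full(
    town_path: str | Path,
    plot_path: str | Path,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    budgets: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Zonation -> plot assignment -> classification -> NSI -> reallocation.

    Outputs (CSV, flushed per stage): ``assignment.csv``, ``outcomes.csv``,
    ``nsi_table.csv`` and — when budgets are given — ``reallocation.csv``,
    plus ``manifest.json``. Budgets default to none (reallocation skipped).
    """
    config = config or PipelineConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    town_path, plot_path = Path(town_path), Path(plot_path)
    manifest = RunManifest(
        config=_config_snapshot(config),
        inputs={str(town_path): _sha256(town_path), str(plot_path): _sha256(plot_path)},
        seed=seed,
    )

    with _Timer(manifest, "read"):
        towns = records_io.read_town_records(town_path)
        plots = records_io.filter_eligible(records_io.read_plot_series(plot_path))

    with _Timer(manifest, "zonate"):
        assignments = zonate(towns, config.zonation)
        write_assignments(assignments, out / "assignment.csv")
        manifest.outputs.append("assignment.csv")

    with _Timer(manifest, "classify"):
        subarea_of = assign_plots(plots, assignments)
        outcomes = outcome_table(plots, subarea_of, config.estimator, config.on_nonmonotone)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        manifest.outputs.append("outcomes.csv")

    with _Timer(manifest, "nsi"):
        summaries = succession_stages.summarize_subarea(
            plots, subarea_of, config.estimator, config.on_nonmonotone
        )
        counts = {label: s.counts for label, s in summaries.items()}
        rows, ordering = nsi_index.nsi_table(counts, config.quality())
        nsi_index.write_nsi_table(rows, out / "nsi_table.csv")
        manifest.outputs.append("nsi_table.csv")
        logger.info("NSI ordering (descending): %s", " > ".join(ordering))

    if budgets is not None:
        with _Timer(manifest, "reallocate"):
            p_by_sub = {r.subarea_label: r.P for r in rows if "-" in r.subarea_label}
            plan = realloc.reallocate(budgets, p_by_sub)
            realloc.write_plan(plan, out / "reallocation.csv")
            manifest.outputs.append("reallocation.csv")

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest


def fixture_nsi_table(output_path: str | Path | None = None):
    """NSI table computed from the published stage counts.

    Region rows use the published region counts verbatim (in the source
    tables they are not the sums of their sub-areas).
    """
    counts = synthetic_data.table3_subarea_fixture()
    regions = synthetic_data.table3_region_fixture()
    rows, ordering = nsi_index.nsi_table(counts, region_counts=regions)
    if output_path is not None:
        nsi_index.write_nsi_table(rows, output_path)
    return rows, ordering
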