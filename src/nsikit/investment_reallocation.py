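"""Restoration-budget reallocation around the mean succession index.

With K the unweighted mean NSI across sub-areas, each sub-area's baseline
budget In is adjusted to

    I = In * (1 + (K - Px) / K),

so sub-areas succeeding above the mean (Px > K, "surplus") cede funds to
those below it (Px < K, "deficit"). Under equal baselines the adjustment
conserves the total budget exactly, because the deviations (K - Px) sum to
zero. The adjustment is not clamped: a sub-area with Px > 2K receives a
negative allocation, which is reported with a warning rather than hidden —
clamping would silently break the conservation identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import IntegrityError

logger = logging.getLogger(__name__)


class BudgetStatus(Enum):
    SURPLUS = "surplus"  # Px > K: funding reduced
    DEFICIT = "deficit"  # Px < K: funding increased
    NEUTRAL = "neutral"  # Px = K: funding unchanged


def mean_threshold(p_values) -> float:
    """Unweighted arithmetic mean K of exact sub-area NSI values."""
    values = list(p_values)
    if not values:
        raise ValueError("cannot take the mean threshold of an empty collection")
    if any(not 0 < v <= 1 for v in values):
        raise ValueError("NSI values must lie in (0, 1]")
    return sum(values) / len(values)


@dataclass(frozen=True)
class ReallocationRow:
    subarea_label: str
    P: float
    baseline: float  # In
    adjusted: float  # I
    status: BudgetStatus


@dataclass(frozen=True)
class ReallocationPlan:
    K: float
    rows: tuple[ReallocationRow, ...]

    @property
    def total_baseline(self) -> float:
        return sum(r.baseline for r in self.rows)

    @property
    def total_adjusted(self) -> float:
        return sum(r.adjusted for r in self.rows)


def reallocate(
    baselines: Mapping[str, float],
    p_by_subarea: Mapping[str, float],
    K: float | None = None,
) -> ReallocationPlan:
    """Apply the mean-threshold adjustment to every budgeted sub-area.

    ``K`` defaults to the mean of the supplied NSI values. The key sets of
    budgets and indices must coincide.
    """
    if set(baselines) != set(p_by_subarea):
        missing_p = sorted(set(baselines) - set(p_by_subarea))
        missing_b = sorted(set(p_by_subarea) - set(baselines))
        raise IntegrityError(
            f"budget/index key mismatch: no NSI for {missing_p}, no budget for {missing_b}"
        )
    if any(b < 0 for b in baselines.values()):
        raise ValueError("baseline budgets must be non-negative")
    if K is None:
        K = mean_threshold(p_by_subarea.values())
    if not K > 0:
        raise ValueError(f"threshold K must be positive, got {K!r}")

    rows = []
    for label in sorted(baselines):
        px, base = p_by_subarea[label], baselines[label]
        adjusted = base * (1.0 + (K - px) / K)
        if px > K:
            status = BudgetStatus.SURPLUS
        elif px < K:
            status = BudgetStatus.DEFICIT
        else:
            status = BudgetStatus.NEUTRAL
        if adjusted < 0:
            logger.warning(
                "sub-area %s: adjusted budget is negative (%.4g); Px=%.4f exceeds 2K=%.4f",
                label, adjusted, px, 2 * K,
            )
        rows.append(ReallocationRow(label, px, base, adjusted, status))
    return ReallocationPlan(K=K, rows=tuple(rows))


def plan_frame(plan: ReallocationPlan) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subarea_label": r.subarea_label,
                "P": r.P,
                "baseline": r.baseline,
                "adjusted": r.adjusted,
                "status": r.status.value,
            }
            for r in plan.rows
        ]
    )


def write_plan(plan: ReallocationPlan, path: str | Path) -> None:
    plan_frame(plan).to_csv(path, index=False)


def read_budgets(path: str | Path) -> dict[str, float]:
    """Read a (subarea_label, baseline) CSV into a budget map."""
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if not {"subarea_label", "baseline"} <= cols:
        raise IntegrityError(f"budget file {path}: need columns subarea_label, baseline; got {sorted(cols)}")
    return {str(r.subarea_label): float(r.baseline) for r in frame.itertuples()}
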