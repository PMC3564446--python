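"""Integrated timeline of redox events in chronologically aging yeast.

The cascade, per condition, in chronological order: NADPH decline ->
pro-oxidizing glutathione-potential shift -> early oxidation of a small
protein subset (thioredoxin reductase among them) -> proteome-wide redox
collapse -> loss of viability.  Under caloric restriction every redox
event lags its standard-condition counterpart by roughly 48 h, and the
50% viability crossing moves from ~day 7 to ~day 11; under hypometabolic
(water) cultivation the collapse does not occur within the observation
window at all.

Events are reported as (name, day) pairs sorted chronologically, with the
lags between consecutive defined events in hours, plus a parameter-by-day
grid suitable for heatmap rendering.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, ClusterRuleConfig, TimepointSchedule
from .early import EARLY_LABELS
from .metabolites import (
    MetaboliteSeries,
    egsh_series,
    egsh_shift_day,
    nadph_decline_onset,
)
from .quant import OxidationMatrix

__all__ = [
    "EVENT_ORDER",
    "TimelineEvent",
    "TimelineResult",
    "mean_lifespan",
    "collapse_day",
    "early_oxidation_onset",
    "build_timeline",
]

EVENT_ORDER = (
    "nadph_decline",
    "egsh_shift",
    "early_oxidation_onset",
    "redox_collapse",
    "viability_50",
)


@dataclass(frozen=True)
class TimelineEvent:
    name: str
    day: float | None
    condition: str

    @property
    def defined(self) -> bool:
        return self.day is not None


def mean_lifespan(series: MetaboliteSeries) -> float | None:
    """Day of the first 50% viability crossing, linearly interpolated.

    Requires the series to start at >= 50% viability; a series that never
    crosses 50% yields None with a warning.
    """
    days = np.asarray(series.days, dtype=float)
    v = np.asarray(series.viability, dtype=float)
    if v[0] < 50.0:
        raise ValueError("viability series must start at >= 50%")
    for i in range(1, len(v)):
        if v[i] <= 50.0:
            if v[i] == v[i - 1]:
                return float(days[i])
            frac = (v[i - 1] - 50.0) / (v[i - 1] - v[i])
            return float(days[i - 1] + frac * (days[i] - days[i - 1]))
    warnings.warn("viability never crosses 50%", stacklevel=2)
    return None


def collapse_day(
    matrix: OxidationMatrix,
    assignment: ClusterAssignment,
    threshold: float = 50.0,
) -> float | None:
    """First day the median oxidation of the A/B (general) peptides exceeds 50%."""
    general = sorted(assignment.peptides_with_label("A", "B"))
    if not general:
        return None
    sub = matrix.mean.loc[[p for p in general if p in matrix.mean.index]]
    if sub.empty:
        return None
    medians = sub.median(axis=0, skipna=True)
    for day, med in medians.items():
        if np.isfinite(med) and med > threshold:
            return float(day)
    return None


def early_oxidation_onset(
    matrix: OxidationMatrix,
    schedule: TimepointSchedule,
    rules: ClusterRuleConfig | None = None,
) -> float | None:
    """First day at which any peptide satisfies the early-rise (D/E) test."""
    rules = rules or ClusterRuleConfig()
    day0 = schedule.day0
    for day in schedule.early_days:
        for pid in matrix.peptides:
            traj = matrix.trajectory(pid)
            if day0 not in traj or day not in traj:
                continue
            v0, vd = traj[day0], traj[day]
            if vd >= rules.early_fold * v0 and vd - v0 >= rules.early_abs_min:
                return float(day)
    return None


@dataclass
class TimelineResult:
    condition: str
    events: list[TimelineEvent]
    lags_hours: dict[str, float] = field(default_factory=dict)
    grid: pd.DataFrame | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition": self.condition,
                "events": [{"name": e.name, "day": e.day} for e in self.events],
                "lags_hours": self.lags_hours,
            },
            indent=2,
        )


def build_timeline(
    metabolites: MetaboliteSeries,
    matrix: OxidationMatrix,
    assignment: ClusterAssignment,
    schedule: TimepointSchedule | None = None,
    rules: ClusterRuleConfig | None = None,
    temperature: float = 303.15,
) -> TimelineResult:
    """Order the five redox events for one condition.

    Undefined events (e.g. no collapse under water cultivation) are kept
    in the list with day None and sort after all defined events.  Lags are
    reported in hours between consecutive defined events.
    """
    schedule = schedule or TimepointSchedule.for_condition(matrix.condition)
    days: dict[str, float | None] = {
        "nadph_decline": nadph_decline_onset(metabolites),
        "egsh_shift": egsh_shift_day(metabolites, temperature=temperature),
        "early_oxidation_onset": early_oxidation_onset(matrix, schedule, rules),
        "redox_collapse": collapse_day(matrix, assignment),
        "viability_50": mean_lifespan(metabolites),
    }
    order = sorted(
        EVENT_ORDER,
        key=lambda n: (days[n] is None, days[n] if days[n] is not None else 0.0),
    )
    events = [TimelineEvent(n, days[n], matrix.condition) for n in order]

    lags: dict[str, float] = {}
    defined = [e for e in events if e.defined]
    for prev, nxt in zip(defined, defined[1:]):
        lags[f"{prev.name}->{nxt.name}"] = 24.0 * (nxt.day - prev.day)

    grid = _parameter_grid(metabolites, matrix, assignment, temperature)
    return TimelineResult(matrix.condition, events, lags, grid)


def _parameter_grid(
    metabolites: MetaboliteSeries,
    matrix: OxidationMatrix,
    assignment: ClusterAssignment,
    temperature: float,
) -> pd.DataFrame:
    """Parameter x day grid of raw values (heatmap-ready TSV payload)."""
    met_days = [float(d) for d in metabolites.days]
    ox_days = matrix.days
    all_days = sorted(set(met_days) | set(ox_days))
    grid = pd.DataFrame(np.nan, index=[
        "viability", "atp", "nadph", "egsh_mv", "median_ox_general", "median_ox_early",
    ], columns=all_days)
    e = egsh_series(metabolites, temperature)
    for i, d in enumerate(met_days):
        grid.loc["viability", d] = metabolites.viability[i]
        grid.loc["atp", d] = metabolites.atp[i]
        grid.loc["nadph", d] = metabolites.nadph[i]
        grid.loc["egsh_mv", d] = e[i]
    general = sorted(assignment.peptides_with_label("A", "B"))
    early = sorted(assignment.peptides_with_label(*EARLY_LABELS))
    for group, row in ((general, "median_ox_general"), (early, "median_ox_early")):
        members = [p for p in group if p in matrix.mean.index]
        if members:
            med = matrix.mean.loc[members].median(axis=0, skipna=True)
            for d in ox_days:
                grid.loc[row, d] = med[d]
    return grid
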