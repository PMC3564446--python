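"""Trajectory imputation, k-means partitioning, and rule-based A-G classes.

Oxidation trajectories of chronologically aging yeast fall into seven
recurring classes:

========  ==============================================================
A         low during log phase, jumps above 50% at the collapse day
B         low during log phase, jumps above 50% one day later
C         already ~50% oxidized at day 0, rises further at the collapse
D         early riser: >= 1.5-fold increase at the first early day
E         early riser: >= 1.5-fold increase at the second early day
F         remains reduced throughout
G         remains oxidized throughout
========  ==============================================================

The named days depend on the cultivation condition: under standard 2%
glucose the early days are 1 and 2 and the collapse day is 3; under 0.5%
glucose caloric restriction everything is shifted ~48 h (early days 3 and
4, collapse day 5) and the late day nominally falls on day 6, which is not
sampled, so it maps to the first sampled day >= 6 (day 7).

Two complementary partitions are provided: an unsupervised k-means
(Euclidean) partition, and the deterministic threshold rules above, applied
in the priority order F, G, D, E, A, B, C so that labels are mutually
exclusive (an early riser that would also pass the A rule is D/E).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .quant import OxidationMatrix

__all__ = [
    "CLUSTER_LABELS",
    "TimepointSchedule",
    "ClusterRuleConfig",
    "ClusterAssignment",
    "ImputationResult",
    "impute_missing",
    "kmeans_trajectories",
    "assign_rule_cluster",
    "classify_matrix",
    "fraction_assigned",
]

CLUSTER_LABELS = ("A", "B", "C", "D", "E", "F", "G")
UNASSIGNED = "unassigned"

#: Rule evaluation order; first match wins.
RULE_PRIORITY = ("F", "G", "D", "E", "A", "B", "C")


@dataclass(frozen=True)
class TimepointSchedule:
    """Sampling schedule and the named days the cluster rules refer to."""

    condition: str
    days: tuple[float, ...]
    early_days: tuple[float, float]
    collapse_day: float
    late_day: float

    def __post_init__(self) -> None:
        if not all(d < self.collapse_day for d in self.early_days):
            raise ValueError("early days must precede the collapse day")
        named = (*self.early_days, self.collapse_day, self.late_day)
        missing = [d for d in named if d not in self.days]
        if missing:
            raise ValueError(f"named days {missing} not in sampled days {self.days}")

    @property
    def day0(self) -> float:
        return self.days[0]

    @classmethod
    def standard(cls) -> "TimepointSchedule":
        return cls("standard", (0, 1, 2, 3, 4), (1, 2), 3, 4)

    @classmethod
    def caloric_restriction(cls) -> "TimepointSchedule":
        # sampling skips day 6; the nominal day-6 late day maps to day 7
        days = (0, 1, 2, 3, 4, 5, 7)
        late = min(d for d in days if d >= 6)
        return cls("caloric_restriction", days, (3, 4), 5, late)

    @classmethod
    def water(cls) -> "TimepointSchedule":
        return cls("water", tuple(range(11)), (1, 2), 3, 4)

    @classmethod
    def for_condition(cls, condition: str) -> "TimepointSchedule":
        try:
            return {
                "standard": cls.standard,
                "caloric_restriction": cls.caloric_restriction,
                "water": cls.water,
            }[condition]()
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}") from None


@dataclass(frozen=True)
class ClusterRuleConfig:
    """Numeric thresholds behind the A-G rules (percent scale).

    low_start:    log-phase ceiling for A/B ("less than 30% during log phase")
    high_ox:      the collapse level ("more than 50%")
    high_start:   day-0 floor for C (operationalizes its "~50%" start)
    early_fold:   fold increase defining early risers ("at least 1.5-fold")
    early_abs_min: absolute-rise floor suppressing spurious fold calls on
                  near-zero baselines, percentage points
    flat_range:   max range for F / min rise for C, percentage points
    oxidized_floor: min level for G ("remain oxidized")
    """

    low_start: float = 30.0
    high_ox: float = 50.0
    high_start: float = 40.0
    early_fold: float = 1.5
    early_abs_min: float = 10.0
    flat_range: float = 15.0
    oxidized_floor: float = 50.0

    def __post_init__(self) -> None:
        for name in ("low_start", "high_ox", "high_start", "flat_range", "oxidized_floor"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        if self.early_fold <= 1:
            raise ValueError("early_fold must exceed 1")
        if self.early_abs_min < 0:
            raise ValueError("early_abs_min must be non-negative")


@dataclass
class ImputationResult:
    matrix: OxidationMatrix
    dropped: list[str]


def impute_missing(
    matrix: OxidationMatrix,
    k: int = 5,
    min_known_frac: float = 0.3,
) -> ImputationResult:
    """k-nearest-neighbour imputation of missing trajectory values.

    A missing entry is replaced by the mean of that column in the ``k``
    rows nearest to the target row (Euclidean distance over the columns
    both rows have observed) among rows that have the column observed.
    Rows with at most ``min_known_frac`` of their values known are dropped
    from the matrix and reported, not imputed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mean = matrix.mean.copy()
    known_frac = mean.notna().mean(axis=1)
    dropped = list(mean.index[known_frac <= min_known_frac])
    mean = mean.drop(index=dropped)

    vals = mean.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    filled = vals.copy()
    for i in range(vals.shape[0]):
        for j in np.flatnonzero(~obs[i]):
            donors = np.flatnonzero(obs[:, j])
            donors = donors[donors != i]
            if donors.size == 0:
                continue  # stays missing: nobody observed this column
            dists = np.empty(donors.size)
            for t, d in enumerate(donors):
                shared = obs[i] & obs[d]
                if not shared.any():
                    dists[t] = np.inf
                    continue
                diff = vals[i, shared] - vals[d, shared]
                dists[t] = float(np.sqrt(np.sum(diff * diff)))
            eligible = donors[np.isfinite(dists)]
            if eligible.size < k:
                warnings.warn(
                    f"only {eligible.size} eligible neighbours (< k={k}) for "
                    f"row {mean.index[i]!r}, column {mean.columns[j]}; using all",
                    stacklevel=2,
                )
            order = np.argsort(dists[np.isfinite(dists)], kind="stable")
            nearest = eligible[order][:k]
            if nearest.size:
                filled[i, j] = float(np.clip(np.mean(vals[nearest, j]), 0.0, 100.0))

    out = OxidationMatrix(
        matrix.condition,
        pd.DataFrame(filled, index=mean.index, columns=mean.columns),
        matrix.sd.drop(index=dropped) if matrix.sd is not None else None,
        matrix.n.drop(index=dropped) if matrix.n is not None else None,
    )
    return ImputationResult(out, dropped)


def kmeans_trajectories(
    matrix: OxidationMatrix,
    k: int,
    seed: int,
    restarts: int = 10,
) -> np.ndarray:
    """Best-of-``restarts`` k-means (Euclidean) partition of the rows.

    Requires a complete matrix (impute first).  Returns the integer
    partition label per row, deterministic for a given seed.
    """
    vals = matrix.mean.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; impute before clustering")
    if k > vals.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({vals.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(vals)


def _early_rise(
    traj: Mapping[float, float], day: float, day0: float, rules: ClusterRuleConfig
) -> bool:
    v0, vd = traj[day0], traj[day]
    return vd >= rules.early_fold * v0 and vd - v0 >= rules.early_abs_min


def assign_rule_cluster(
    traj: Mapping[float, float],
    schedule: TimepointSchedule,
    rules: ClusterRuleConfig | None = None,
) -> str:
    """Assign one trajectory to A-G (or ``unassigned``) by threshold rules.

    ``traj`` maps sampled day to mean % oxidation and must cover the
    schedule's named days (impute beforehand).  Rules are evaluated in the
    priority order F, G, D, E, A, B, C; the first match wins.
    """
    rules = rules or ClusterRuleConfig()
    named = (schedule.day0, *schedule.early_days, schedule.collapse_day, schedule.late_day)
    for d in named:
        if d not in traj or not np.isfinite(traj[d]):
            raise ValueError(f"trajectory is missing required day {d}")

    values = np.array([traj[d] for d in schedule.days if d in traj], dtype=float)
    v0 = traj[schedule.day0]

    # F: remains reduced
    if values.max() - values.min() < rules.flat_range and values.max() < rules.low_start:
        return "F"
    # G: remains oxidized (never rises early_fold-fold over day 0)
    if values.min() >= rules.oxidized_floor and not np.any(
        values >= rules.early_fold * v0
    ):
        return "G"
    # D/E: early risers at the first/second early day
    if _early_rise(traj, schedule.early_days[0], schedule.day0, rules):
        return "D"
    if _early_rise(traj, schedule.early_days[1], schedule.day0, rules):
        return "E"
    # A/B: low start, collapse at the collapse/late day
    if v0 < rules.low_start and traj[schedule.collapse_day] > rules.high_ox:
        return "A"
    if v0 < rules.low_start and traj[schedule.late_day] > rules.high_ox:
        return "B"
    # C: high start with a further significant rise at the collapse day
    if v0 >= rules.high_start and traj[schedule.collapse_day] >= v0 + rules.flat_range:
        return "C"
    return UNASSIGNED


@dataclass
class ClusterAssignment:
    """Rule labels plus (optionally) the parallel k-means partition."""

    condition: str
    labels: dict[str, str]
    kmeans: dict[str, int] | None = None
    cluster_means: dict[str, np.ndarray] = field(default_factory=dict)

    def peptides_with_label(self, *wanted: str) -> set[str]:
        return {p for p, lab in self.labels.items() if lab in wanted}


def classify_matrix(
    matrix: OxidationMatrix,
    schedule: TimepointSchedule | None = None,
    rules: ClusterRuleConfig | None = None,
    k: int | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> ClusterAssignment:
    """Rule-classify every row of a matrix; optionally add a k-means partition.

    Rows missing any named day are labeled ``unassigned`` rather than
    raising, so partially observed peptides survive a condition-wise scan.
    The k-means partition (``k`` clusters) runs on the complete rows only.
    """
    schedule = schedule or TimepointSchedule.for_condition(matrix.condition)
    rules = rules or ClusterRuleConfig()
    labels: dict[str, str] = {}
    for pid in matrix.peptides:
        traj = matrix.trajectory(pid)
        try:
            labels[pid] = assign_rule_cluster(traj, schedule, rules)
        except ValueError:
            labels[pid] = UNASSIGNED

    assignment = ClusterAssignment(matrix.condition, labels)
    if k is not None:
        complete = matrix.strict_subset()
        if complete.peptides:
            part = kmeans_trajectories(complete, k, seed, restarts)
            assignment.kmeans = dict(zip(complete.peptides, (int(p) for p in part)))
    for lab in CLUSTER_LABELS:
        members = [p for p, l in labels.items() if l == lab]
        if members:
            assignment.cluster_means[lab] = (
                matrix.mean.loc[members].mean(axis=0).to_numpy(dtype=float)
            )
    return assignment


def fraction_assigned(assignment: ClusterAssignment) -> float:
    """Percent of peptides carrying one of the labels A-G."""
    if not assignment.labels:
        raise ValueError("empty assignment")
    n_ok = sum(1 for lab in assignment.labels.values() if lab in CLUSTER_LABELS)
    return 100.0 * n_ok / len(assignment.labels)
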