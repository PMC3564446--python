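"""Early-oxidation-target detection and summary statistics.

Early targets are protein thiols whose oxidation rises at least 1.5-fold
24-48 h before the proteome-wide redox collapse -- the rule-cluster classes
D and E.  Membership is pooled across cultivation conditions: a peptide
that rises early under caloric restriction but not under standard glucose
still counts (the two conditions probe the same cascade, time-shifted).

Cell-level flagging follows the stricter per-day criterion used for
highlighting trajectories: a day is flagged when its oxidation is at least
2-fold the day-0 level, or at least 1.5-fold the day-0 level while
exceeding 60% total oxidation ("exceeding" read strictly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .clustering import ClusterAssignment
from .quant import OxidationMatrix

__all__ = [
    "EarlySummary",
    "flag_cells",
    "fold_changes",
    "identify_early_targets",
    "summarize_early",
]

EARLY_LABELS = ("D", "E")


def flag_cells(
    traj: Mapping[float, float],
    fold_high: float = 2.0,
    fold_low: float = 1.5,
    abs_threshold: float = 60.0,
) -> dict[float, bool]:
    """Per-day flag mask for one trajectory relative to its day-0 value.

    Day d is flagged iff v_d >= fold_high * v_0, or
    (v_d >= fold_low * v_0 and v_d > abs_threshold).
    """
    days = sorted(traj)
    if not days:
        raise ValueError("empty trajectory")
    day0 = days[0]
    v0 = traj[day0]
    if v0 is None or not np.isfinite(v0):
        raise ValueError("day-0 value is missing")
    mask: dict[float, bool] = {}
    for d in days[1:]:
        v = traj[d]
        if v is None or not np.isfinite(v):
            mask[d] = False
            continue
        mask[d] = bool(v >= fold_high * v0 or (v >= fold_low * v0 and v > abs_threshold))
    return mask


def fold_changes(traj: Mapping[float, float]) -> dict[float, float | None]:
    """Day-wise fold change vs day 0; None where v_0 = 0 (undefined)."""
    days = sorted(traj)
    if not days:
        raise ValueError("empty trajectory")
    v0 = traj[days[0]]
    out: dict[float, float | None] = {}
    for d in days[1:]:
        v = traj[d]
        if v0 == 0 or not np.isfinite(v0):
            out[d] = None
        else:
            out[d] = float(v) / float(v0) if np.isfinite(v) else None
    return out


def identify_early_targets(
    assignments: Mapping[str, ClusterAssignment] | list[ClusterAssignment],
) -> set[str]:
    """Union over conditions of peptides labeled D or E."""
    if isinstance(assignments, Mapping):
        assignments = list(assignments.values())
    targets: set[str] = set()
    for a in assignments:
        targets |= a.peptides_with_label(*EARLY_LABELS)
    return targets


@dataclass
class EarlySummary:
    """Counts and fold ranges over an early-target set."""

    n_targets: int
    n_above_threshold: int
    fold_min: float | None
    fold_max: float | None
    n_peroxide_sensitive: int | None


def summarize_early(
    targets: set[str],
    matrix: OxidationMatrix,
    annotations: Mapping[str, bool] | None = None,
    day: float = 2.0,
    threshold: float = 45.0,
) -> EarlySummary:
    """Summarize an early-target set against one oxidation matrix.

    Reports how many targets exceed ``threshold`` % oxidation at ``day``
    (strictly), the min/max fold change at that day vs day 0 among those,
    and the overlap with a peroxide-sensitivity annotation if given.
    """
    day = float(day)
    above: list[str] = []
    folds: list[float] = []
    for pid in sorted(targets):
        if pid not in matrix.mean.index:
            continue
        traj = matrix.trajectory(pid)
        if day not in traj:
            continue
        if traj[day] > threshold:
            above.append(pid)
            fc = fold_changes(traj).get(day)
            if fc is not None:
                folds.append(fc)
    n_annot = None
    if annotations is not None:
        n_annot = sum(1 for pid in targets if annotations.get(pid, False))
    return EarlySummary(
        n_targets=len(targets),
        n_above_threshold=len(above),
        fold_min=min(folds) if folds else None,
        fold_max=max(folds) if folds else None,
        n_peroxide_sensitive=n_annot,
    )
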