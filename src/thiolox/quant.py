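"""ICAT light/heavy envelope-pair quantification of thiol oxidation.

Differential thiol trapping labels in-vivo reduced cysteines with a light
isotope tag and in-vivo oxidized (then chemically reduced) cysteines with a
heavy tag that is ~9.03 Da heavier per cysteine.  A peptide with ``n``
cysteines therefore appears in a centroided spectrum as up to ``n + 1``
isotopologue envelopes spaced by the per-label mass difference, and the
intensity-weighted share of heavy labels gives the fraction of the peptide
population that was oxidized in vivo::

    percent_oxidized = 100 * (sum_k k * I_k) / (n * sum_k I_k)

where ``I_k`` is the summed envelope intensity of the state carrying ``k``
heavy labels.  In the common case of two cysteines forming an intramolecular
disulfide, only the all-light (k=0) and all-heavy (k=n) states are populated
("two-state" mode, the default); the formula then reduces to the classic
heavy/(light+heavy) ratio.

Because the readout is a ratio within one spectrum it is independent of
absolute protein abundance, which is what makes this approach suitable for
following hundreds of protein thiols across a time course.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ISOTOPE_SPACING",
    "LabelConfig",
    "PeptideSpec",
    "Spectrum",
    "EnvelopeIntensity",
    "QuantResult",
    "Aggregate",
    "OxidationMatrix",
    "label_mass_shift",
    "locate_envelope",
    "quantify_oxidation",
    "aggregate_replicates",
    "build_matrix",
    "combine_replicate_matrices",
]

#: Mass difference between consecutive isotopologues (13C - 12C), Da.
ISOTOPE_SPACING = 1.0033548378


@dataclass(frozen=True)
class LabelConfig:
    """Parameters of the light/heavy cysteine label pair and peak matching.

    per_label_delta
        Mass added per heavy label relative to light, Da.  The heavy tag
        carries nine 13C atoms, hence 9.0302 Da; ``nominal`` work sometimes
        rounds this to 9.0.
    light_tag_mass
        Mass of the light tag itself (informational; the reduced-form m/z
        supplied with each peptide already includes the light labels).
    n_isotopologues
        Number of isotopologue positions summed per envelope.
    mz_tolerance
        Peak-matching half-window on the m/z axis, Da.
    charge
        Default charge state; mass shifts divide by it on the m/z axis.
    """

    per_label_delta: float = 9.0302
    light_tag_mass: float = 227.1270
    n_isotopologues: int = 5
    mz_tolerance: float = 0.1
    charge: int = 1

    def __post_init__(self) -> None:
        if self.per_label_delta <= 0:
            raise ValueError("per_label_delta must be positive")
        if self.n_isotopologues < 1:
            raise ValueError("n_isotopologues must be >= 1")
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


@dataclass(frozen=True)
class PeptideSpec:
    """A cysteine-containing peptide to be quantified.

    ``reduced_mz`` is the monoisotopic m/z of the all-light form; cysteine
    positions are 1-based within the parent protein.
    """

    peptide_id: str
    protein_id: str
    cys_positions: tuple[int, ...]
    reduced_mz: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.n_cys < 1:
            raise ValueError("peptide must contain at least one cysteine")
        if len(set(self.cys_positions)) != len(self.cys_positions):
            raise ValueError("cysteine positions must be distinct")
        if self.reduced_mz <= 0:
            raise ValueError("reduced_mz must be positive")

    @property
    def n_cys(self) -> int:
        return len(self.cys_positions)


class Spectrum:
    """A centroided peak list: parallel (m/z, intensity) arrays sorted by m/z."""

    __slots__ = ("mz", "intensity")

    def __init__(self, mz: Sequence[float], intensity: Sequence[float]):
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = intensity[order]

    def __len__(self) -> int:
        return self.mz.size

    def scaled(self, c: float) -> "Spectrum":
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return Spectrum(self.mz.copy(), self.intensity * c)


@dataclass(frozen=True)
class EnvelopeIntensity:
    """Summed envelope intensity plus a flag for an absent monoisotopic peak."""

    intensity: float
    missing: bool


@dataclass
class QuantResult:
    """Fractional oxidation of one peptide observation.

    ``percent_oxidized`` is None when no envelope carried signal (the
    observation is unquantifiable, flagged rather than numeric).
    """

    peptide_id: str
    percent_oxidized: float | None
    state_intensities: dict[int, float]
    flags: frozenset[str] = frozenset()
    day: float | None = None
    replicate: int | None = None

    @property
    def quantifiable(self) -> bool:
        return self.percent_oxidized is not None


def label_mass_shift(n_cys: int, cfg: LabelConfig | None = None) -> float:
    """Total light-to-heavy mass difference for a peptide with ``n_cys`` labels."""
    if n_cys < 0:
        raise ValueError("n_cys must be non-negative")
    cfg = cfg or LabelConfig()
    return n_cys * cfg.per_label_delta


def locate_envelope(
    spectrum: Spectrum, target_mz: float, cfg: LabelConfig | None = None
) -> EnvelopeIntensity:
    """Sum an isotopologue envelope anchored at ``target_mz``.

    For each of the first ``n_isotopologues`` positions (spaced by the
    13C-12C mass difference over the charge) the most intense peak within
    ``mz_tolerance`` is taken; their intensities are summed.  If no peak
    matches the monoisotopic position the envelope is reported as a flagged
    zero -- absence of signal is data, not an error.
    """
    cfg = cfg or LabelConfig()
    total = 0.0
    mono_found = False
    for j in range(cfg.n_isotopologues):
        pos = target_mz + j * ISOTOPE_SPACING / cfg.charge
        lo = np.searchsorted(spectrum.mz, pos - cfg.mz_tolerance, side="left")
        hi = np.searchsorted(spectrum.mz, pos + cfg.mz_tolerance, side="right")
        if hi > lo:
            best = float(np.max(spectrum.intensity[lo:hi]))
            total += best
            if j == 0:
                mono_found = True
    if not mono_found:
        return EnvelopeIntensity(0.0, missing=True)
    return EnvelopeIntensity(total, missing=False)


def quantify_oxidation(
    spectrum: Spectrum,
    pep: PeptideSpec,
    cfg: LabelConfig | None = None,
    mode: str = "two_state",
) -> QuantResult:
    """Quantify the oxidized fraction of ``pep`` from its envelope pair(s).

    ``mode='two_state'`` (default) considers only the all-light and
    all-heavy labeling states, matching the disulfide-coupled behaviour of
    vicinal cysteine pairs; ``mode='full'`` uses every state k = 0..n_cys.
    """
    if mode not in ("two_state", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or LabelConfig()
    cfg = replace(cfg, charge=pep.charge)
    n = pep.n_cys
    states = (0, n) if mode == "two_state" and n > 1 else tuple(range(n + 1))

    flags: set[str] = set()
    intensities: dict[int, float] = {}
    for k in states:
        target = pep.reduced_mz + k * cfg.per_label_delta / pep.charge
        env = locate_envelope(spectrum, target, cfg)
        intensities[k] = env.intensity
        if env.missing:
            flags.add(f"missing_envelope_k{k}")

    total = sum(intensities.values())
    if total <= 0.0:
        flags.add("unquantifiable")
        return QuantResult(pep.peptide_id, None, intensities, frozenset(flags))
    percent = 100.0 * sum(k * i for k, i in intensities.items()) / (n * total)
    return QuantResult(pep.peptide_id, percent, intensities, frozenset(flags))


@dataclass(frozen=True)
class Aggregate:
    """Replicate summary for one peptide at one timepoint."""

    peptide_id: str
    day: float
    mean: float | None
    sd: float | None
    n: int

    @property
    def masked(self) -> bool:
        return self.mean is None


def aggregate_replicates(
    results: Iterable[QuantResult],
    min_replicates: int = 3,
) -> list[Aggregate]:
    """Mean/SD/count per peptide per day over quantifiable replicates.

    A peptide-day observed in fewer than ``min_replicates`` replicates is
    masked missing (mean and SD withheld, count retained), enforcing the
    reproducibility filter used when assembling oxidation matrices.  SD is
    the sample standard deviation and is absent when n < 2.
    """
    groups: dict[tuple[str, float], list[float]] = {}
    for r in results:
        if not r.quantifiable:
            continue
        if r.day is None:
            raise ValueError(f"result for {r.peptide_id} lacks a day")
        groups.setdefault((r.peptide_id, r.day), []).append(r.percent_oxidized)

    out: list[Aggregate] = []
    for (pid, day), vals in sorted(groups.items()):
        n = len(vals)
        if n < min_replicates:
            out.append(Aggregate(pid, day, None, None, n))
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if n >= 2 else None
        out.append(Aggregate(pid, day, mean, sd, n))
    return out


@dataclass
class OxidationMatrix:
    """Peptides x timepoints of mean % oxidation for one condition.

    ``mean`` is a DataFrame indexed by peptide id with one column per
    sampled day (float day labels); NaN marks a masked/missing entry.
    ``sd`` and ``n`` are aligned DataFrames (optional).
    """

    condition: str
    mean: pd.DataFrame
    sd: pd.DataFrame | None = None
    n: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.mean.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("oxidation means must lie in [0, 100]")

    @property
    def days(self) -> list[float]:
        return [float(c) for c in self.mean.columns]

    @property
    def peptides(self) -> list[str]:
        return list(self.mean.index)

    def trajectory(self, peptide_id: str) -> dict[float, float]:
        row = self.mean.loc[peptide_id]
        return {float(d): float(v) for d, v in row.items() if np.isfinite(v)}

    def complete_rows(self) -> list[str]:
        mask = self.mean.notna().all(axis=1)
        return list(self.mean.index[mask])

    def strict_subset(self) -> "OxidationMatrix":
        """Retain only peptides observed at every sampled day."""
        keep = self.complete_rows()
        return OxidationMatrix(
            self.condition,
            self.mean.loc[keep].copy(),
            self.sd.loc[keep].copy() if self.sd is not None else None,
            self.n.loc[keep].copy() if self.n is not None else None,
        )


def build_matrix(
    aggregates: Iterable[Aggregate],
    schedule_days: Sequence[float],
    condition: str,
    strict: bool = False,
) -> OxidationMatrix:
    """Assemble aggregates into an :class:`OxidationMatrix`.

    Duplicate peptide-day entries are rejected; days outside the schedule
    are rejected.  With ``strict=True`` only peptides observed (unmasked)
    at every scheduled day are retained.
    """
    days = [float(d) for d in schedule_days]
    seen: set[tuple[str, float]] = set()
    cells: dict[str, dict[float, Aggregate]] = {}
    for a in aggregates:
        day = float(a.day)
        if day not in days:
            raise ValueError(f"day {day} not in schedule {days}")
        key = (a.peptide_id, day)
        if key in seen:
            raise ValueError(f"duplicate entry for peptide {a.peptide_id} day {day}")
        seen.add(key)
        cells.setdefault(a.peptide_id, {})[day] = a

    index = sorted(cells)
    mean = pd.DataFrame(np.nan, index=index, columns=days)
    sd = pd.DataFrame(np.nan, index=index, columns=days)
    n = pd.DataFrame(0, index=index, columns=days, dtype=int)
    for pid, per_day in cells.items():
        for day, a in per_day.items():
            if a.mean is not None:
                mean.loc[pid, day] = a.mean
            if a.sd is not None:
                sd.loc[pid, day] = a.sd
            n.loc[pid, day] = a.n
    matrix = OxidationMatrix(condition, mean, sd, n)
    return matrix.strict_subset() if strict else matrix


def combine_replicate_matrices(
    replicates: Sequence[OxidationMatrix],
    min_replicates: int = 3,
) -> OxidationMatrix:
    """Average per-replicate matrices into one mean/SD/count matrix.

    Entries observed in fewer than ``min_replicates`` replicates are masked,
    mirroring :func:`aggregate_replicates` at the matrix level.
    """
    if not replicates:
        raise ValueError("no replicate matrices given")
    condition = replicates[0].condition
    ref_cols = list(replicates[0].mean.columns)
    for m in replicates[1:]:
        if m.condition != condition or list(m.mean.columns) != ref_cols:
            raise ValueError("replicate matrices must share condition and schedule")
    index = sorted(set().union(*[set(m.mean.index) for m in replicates]))
    stack = np.stack(
        [m.mean.reindex(index).to_numpy(dtype=float) for m in replicates]
    )
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        counts = np.sum(np.isfinite(stack), axis=0)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    mean[counts < min_replicates] = np.nan
    sd[counts < 2] = np.nan
    sd[counts < min_replicates] = np.nan
    return OxidationMatrix(
        condition,
        pd.DataFrame(mean, index=index, columns=ref_cols),
        pd.DataFrame(sd, index=index, columns=ref_cols),
        pd.DataFrame(counts, index=index, columns=ref_cols),
    )
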