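"""Synthetic inputs for every pipeline stage, with known ground truth.

The generator emulates the study design of a chronological-aging redox
time course in budding yeast:

* oxidation trajectories drawn from seven archetypes (classes A-G) on the
  condition-specific sampling schedule, with four biological replicates,
  additive Gaussian noise, and optional missingness;
* protein libraries with a cysteine-proximity effect planted into the
  flanking windows of designated classes (early risers carry extra
  cysteines near the identified thiol);
* centroided light/heavy label-pair spectra at a known oxidation fraction;
* glutathione, NADPH/NADP+, ATP, and viability curves whose qualitative
  shapes match the biology: NADPH peaks around day 0.5 and then declines,
  the glutathione potential shifts >= 15 mV pro-oxidizing by day 1
  (standard) or day 3 (caloric restriction), ATP is maintained at or above
  the day-0 level until day 5 / day 7, and viability is a logistic with a
  50% crossing near day 7 (standard), day 11 (caloric restriction), or day
  16 (water).  Every redox event under caloric restriction lags standard
  cultivation by ~48 h.

Seeds are mandatory; identical configuration and seed give bit-identical
output.  Under the water (hypometabolic) condition the general-oxidation
archetypes deliberately stay flat and low -- there is no redox collapse to
recover -- so class labels there describe peptide identity, not the rule
the trajectory satisfies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

from .clustering import CLUSTER_LABELS, TimepointSchedule
from .metabolites import MetaboliteSeries, nernst_slope_mv
from .quant import ISOTOPE_SPACING, LabelConfig, OxidationMatrix, PeptideSpec, Spectrum

import pandas as pd

__all__ = [
    "ARCHETYPES",
    "AMINO_ACIDS",
    "SimConfig",
    "SyntheticTruth",
    "PeptideLibrary",
    "gen_trajectories",
    "gen_peptide_library",
    "gen_spectrum",
    "gen_metabolites",
]

#: Archetype trajectories (% oxidation at each scheduled day) per condition.
#: Each standard/CR archetype satisfies its own cluster rule at zero noise.
ARCHETYPES: dict[str, dict[str, tuple[float, ...]]] = {
    "standard": {
        "A": (20, 20, 22, 80, 90),
        "B": (18, 18, 20, 35, 75),
        "C": (50, 52, 55, 85, 90),
        "D": (20, 45, 65, 80, 88),
        "E": (20, 21, 55, 78, 88),
        "F": (10, 10, 11, 12, 12),
        "G": (85, 86, 88, 90, 92),
    },
    "caloric_restriction": {
        "A": (20, 20, 21, 21, 22, 80, 90),
        "B": (18, 18, 19, 20, 20, 35, 75),
        "C": (50, 51, 52, 53, 55, 85, 90),
        "D": (20, 20, 21, 45, 60, 80, 88),
        "E": (20, 20, 21, 22, 50, 78, 88),
        "F": (10, 10, 10, 11, 11, 12, 12),
        "G": (85, 85, 86, 88, 90, 90, 92),
    },
    # hypometabolic: only a minor oxidation increase, persisting to day 10
    "water": {
        "A": (20, 21, 23, 25, 25, 26, 26, 27, 27, 28, 28),
        "B": (15, 16, 17, 18, 18, 19, 19, 20, 20, 21, 21),
        "C": (45, 48, 52, 66, 70, 72, 73, 74, 75, 75, 76),
        "D": (20, 35, 45, 30, 26, 25, 24, 23, 22, 22, 21),
        "E": (20, 22, 40, 30, 26, 25, 24, 23, 22, 22, 21),
        "F": (10, 10, 10, 10, 11, 11, 11, 12, 12, 12, 12),
        "G": (85, 86, 86, 87, 87, 88, 88, 88, 89, 89, 90),
    },
}

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def _equal_proportions() -> dict[str, float]:
    return {lab: 1.0 / len(CLUSTER_LABELS) for lab in CLUSTER_LABELS}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a trajectory simulation.

    ``noise_sd`` is the per-replicate additive Gaussian noise in percentage
    points; ``n_replicates=4`` mirrors the four-biological-replicate study
    design; ``missing_rate`` masks individual replicate observations.
    """

    n_peptides: int
    seed: int
    label_proportions: Mapping[str, float] = field(default_factory=_equal_proportions)
    noise_sd: float = 5.0
    n_replicates: int = 4
    missing_rate: float = 0.0
    schedule: TimepointSchedule = field(default_factory=TimepointSchedule.standard)

    def __post_init__(self) -> None:
        if self.n_peptides < 0:
            raise ValueError("n_peptides must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        total = sum(self.label_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"label proportions must sum to 1 (got {total})")
        known = set(ARCHETYPES[self.schedule.condition])
        unknown = set(self.label_proportions) - known
        if unknown:
            raise ValueError(f"unknown archetype label(s): {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Generating archetype label and noise-free trajectory per peptide."""

    label_of: dict[str, str]
    true_values: dict[str, np.ndarray]

    def peptides_with_label(self, *wanted: str) -> set[str]:
        return {p for p, lab in self.label_of.items() if lab in wanted}


def _label_counts(cfg: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_peptides over the proportions."""
    labels = sorted(cfg.label_proportions)
    quotas = {lab: cfg.n_peptides * cfg.label_proportions[lab] for lab in labels}
    counts = {lab: int(np.floor(q)) for lab, q in quotas.items()}
    short = cfg.n_peptides - sum(counts.values())
    by_remainder = sorted(labels, key=lambda l: (counts[l] - quotas[l], l))
    for lab in by_remainder[:short]:
        counts[lab] += 1
    return counts


def gen_trajectories(
    cfg: SimConfig,
) -> tuple[list[OxidationMatrix], SyntheticTruth]:
    """Per-replicate oxidation matrices plus the generating ground truth.

    Each replicate value is archetype + iid N(0, noise_sd), clipped to
    [0, 100]; entries are masked missing with probability ``missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    condition = cfg.schedule.condition
    arch = ARCHETYPES[condition]
    days = [float(d) for d in cfg.schedule.days]
    counts = _label_counts(cfg)

    ids: list[str] = []
    label_of: dict[str, str] = {}
    true_values: dict[str, np.ndarray] = {}
    base_rows: list[np.ndarray] = []
    i = 0
    for lab in sorted(counts):
        base = np.asarray(arch[lab], dtype=float)
        for _ in range(counts[lab]):
            pid = f"pep{i:04d}"
            ids.append(pid)
            label_of[pid] = lab
            true_values[pid] = base.copy()
            base_rows.append(base)
            i += 1

    truth = SyntheticTruth(label_of, true_values)
    shape = (len(ids), len(days))
    replicates: list[OxidationMatrix] = []
    base_arr = (
        np.vstack(base_rows) if base_rows else np.empty(shape, dtype=float)
    )
    for _ in range(cfg.n_replicates):
        noisy = base_arr + rng.normal(0.0, cfg.noise_sd, size=shape) if cfg.noise_sd else base_arr.copy()
        noisy = np.clip(noisy, 0.0, 100.0)
        if cfg.missing_rate > 0:
            mask = rng.random(size=shape) < cfg.missing_rate
            noisy = np.where(mask, np.nan, noisy)
        replicates.append(
            OxidationMatrix(condition, pd.DataFrame(noisy, index=ids, columns=days))
        )
    return replicates, truth


@dataclass
class PeptideLibrary:
    """Generated protein set with one designated cysteine site per protein."""

    sequences: dict[str, str]
    sites: dict[str, int]  # protein id -> 1-based cysteine position
    labels: dict[str, str]  # protein id -> archetype label


def gen_peptide_library(
    n: int,
    seed: int,
    background_freqs: Mapping[str, float] | None = None,
    planted_cys_boost: float = 1.0,
    boost_labels: Sequence[str] = ("D", "E"),
    labels_cycle: Sequence[str] = CLUSTER_LABELS,
    flank: int = 5,
    protein_length: int = 41,
) -> PeptideLibrary:
    """Protein library with a cysteine-proximity effect planted per class.

    Residues are i.i.d. from ``background_freqs`` (default: uniform over
    the 20 standard amino acids, a neutral null) except in the +-``flank``
    window around the designated cysteine of proteins whose label is in
    ``boost_labels``, where the cysteine probability is multiplied by
    ``planted_cys_boost`` and the distribution renormalized.  The
    designated site itself is always C.
    """
    if planted_cys_boost < 0:
        raise ValueError("planted_cys_boost must be non-negative")
    if background_freqs is None:
        background_freqs = {aa: 1.0 / len(AMINO_ACIDS) for aa in AMINO_ACIDS}
    missing = set(AMINO_ACIDS) - set(background_freqs)
    if missing or abs(sum(background_freqs.values()) - 1.0) > 1e-9:
        raise ValueError("background_freqs must cover the 20 amino acids and sum to 1")

    aas = list(AMINO_ACIDS)
    p_bg = np.array([background_freqs[a] for a in aas])
    p_boost = p_bg.copy()
    p_boost[aas.index("C")] *= planted_cys_boost
    p_boost = p_boost / p_boost.sum()

    rng = np.random.default_rng(seed)
    center = protein_length // 2  # 0-based index of the designated cysteine
    lib = PeptideLibrary({}, {}, {})
    for i in range(n):
        label = labels_cycle[i % len(labels_cycle)]
        boosted = label in boost_labels
        residues = []
        for pos in range(protein_length):
            if pos == center:
                residues.append("C")
                continue
            in_window = abs(pos - center) <= flank
            p = p_boost if (boosted and in_window) else p_bg
            residues.append(aas[rng.choice(len(aas), p=p)])
        pid = f"prot{i:04d}"
        lib.sequences[pid] = "".join(residues)
        lib.sites[pid] = center + 1
        lib.labels[pid] = label
    return lib


def _envelope_shape(mass: float, n_isotopologues: int) -> np.ndarray:
    """Binomial isotopologue envelope from an averagine-like carbon count."""
    n_carbon = max(n_isotopologues, int(round(mass * 0.04444)))  # ~4.94 C / 111.1 Da
    j = np.arange(n_isotopologues)
    return binom.pmf(j, n_carbon, 0.0107)


def gen_spectrum(
    pep: PeptideSpec,
    oxidation_fraction: float,
    cfg: LabelConfig | None = None,
    noise: float = 0.0,
    seed: int = 0,
    mixed_states: bool = False,
    total_intensity: float = 1e5,
) -> Spectrum:
    """Centroided light/heavy label-pair spectrum at a known oxidized fraction.

    By default only the all-light and all-heavy states are emitted with
    weights (1 - f) and f, matching the disulfide-coupled two-state
    behaviour of vicinal cysteine pairs; ``mixed_states=True`` populates
    every state k with binomial weights C(n,k) f^k (1-f)^(n-k).
    Multiplicative Gaussian noise of relative SD ``noise`` is applied per
    peak.
    """
    if not 0.0 <= oxidation_fraction <= 1.0:
        raise ValueError("oxidation_fraction must be in [0, 1]")
    cfg = cfg or LabelConfig()
    f = oxidation_fraction
    n = pep.n_cys
    if mixed_states:
        weights = {k: float(binom.pmf(k, n, f)) for k in range(n + 1)}
    else:
        weights = {0: 1.0 - f, n: f}

    shape = _envelope_shape(pep.reduced_mz * pep.charge, cfg.n_isotopologues)
    rng = np.random.default_rng(seed)
    mzs: list[float] = []
    intens: list[float] = []
    for k, w in weights.items():
        if w <= 0:
            continue
        base = pep.reduced_mz + k * cfg.per_label_delta / pep.charge
        for j, s in enumerate(shape):
            mzs.append(base + j * ISOTOPE_SPACING / pep.charge)
            value = total_intensity * w * float(s)
            if noise > 0:
                value *= 1.0 + rng.normal(0.0, noise)
            intens.append(max(value, 0.0))
    return Spectrum(mzs, intens)


# --- metabolite/viability curves -------------------------------------------

_HALF = [0.0, 0.5]


def _grid(last_day: int) -> np.ndarray:
    return np.array(_HALF + list(range(1, last_day + 1)), dtype=float)


def _logistic_viability(days: np.ndarray, t50: float, slope: float) -> np.ndarray:
    return 100.0 / (1.0 + np.exp((days - t50) / slope))


#: Target glutathione potentials (mV) and NADPH/NADP+/ATP levels per day.
#: Standard: E_GSH shifts >= 15 mV at day 1, NADPH decline onset day 1,
#: ATP held >= day-0 through day 5, viability t50 = 7 d.  Caloric
#: restriction: the same events shifted by ~48 h, t50 = 11 d.  Water:
#: near-flat redox state, t50 = 16 d.
_CURVES: dict[str, dict[str, Sequence[float]]] = {
    "standard": {
        "egsh_mv": [-240, -236, -220, -214, -209, -205, -201, -198, -196, -194, -192, -190],
        "nadph": [1.0, 1.6, 1.15, 0.8, 0.6, 1.0, 0.7, 0.6, 0.55, 0.5, 0.5, 0.45],
        "nadp": [1.0, 0.8, 1.0, 1.2, 1.3, 1.6, 1.3, 1.2, 1.2, 1.1, 1.1, 1.0],
        "atp": [1.0, 1.05, 1.15, 1.25, 1.3, 1.25, 1.05, 0.85, 0.7, 0.6, 0.5, 0.45],
    },
    "caloric_restriction": {
        "egsh_mv": [-240, -238, -236, -233, -222, -218, -214, -210, -207, -204,
                    -201, -199, -197, -195, -193, -191],
        "nadph": [1.0, 1.7, 1.75, 1.6, 1.2, 0.9, 0.7, 0.65, 0.6, 0.55,
                  0.5, 0.5, 0.45, 0.45, 0.4, 0.4],
        "nadp": [1.0, 0.85, 0.9, 1.0, 1.1, 1.2, 1.3, 1.3, 1.25, 1.2,
                 1.15, 1.1, 1.1, 1.05, 1.0, 1.0],
        "atp": [1.0, 1.02, 1.1, 1.2, 1.3, 1.3, 1.25, 1.15, 1.05, 0.9,
                0.75, 0.65, 0.55, 0.5, 0.45, 0.4],
    },
    "water": {
        "egsh_mv": [-240, -239, -239, -238, -238, -237, -237, -236, -236, -235,
                    -235, -234, -234, -233, -233, -232, -232, -231],
        "nadph": [1.0, 1.1, 1.1, 1.05, 1.0, 1.0, 0.95, 0.95, 0.9, 0.9,
                  0.9, 0.85, 0.85, 0.85, 0.8, 0.8, 0.8, 0.75],
        "nadp": [1.0, 1.0, 1.0, 1.0, 1.05, 1.05, 1.05, 1.05, 1.1, 1.1,
                 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1, 1.1],
        "atp": [1.0, 1.0, 0.95, 0.9, 0.9, 0.85, 0.85, 0.85, 0.8, 0.8,
                0.8, 0.8, 0.75, 0.75, 0.75, 0.75, 0.7, 0.7],
    },
}

_LAST_DAY = {"standard": 10, "caloric_restriction": 14, "water": 16}
_T50 = {"standard": 7.0, "caloric_restriction": 11.0, "water": 16.0}
_V_SLOPE = {"standard": 0.8, "caloric_restriction": 0.9, "water": 1.0}
_GSH0_M = 8e-3  # total glutathione scale, molar
_GSH_DECAY = 0.05  # per day


def gen_metabolites(
    condition: str,
    seed: int,
    noise: float = 0.02,
    temperature: float = 303.15,
) -> MetaboliteSeries:
    """Glutathione/NADPH/ATP/viability time series for one condition.

    GSH decays slowly from 8 mM; GSSG is back-computed from the target
    glutathione potential via the Nernst relation so that the generated
    couple reproduces the intended E_GSH trajectory.  ``noise`` is the
    relative (multiplicative Gaussian) SD applied per measurement;
    viability noise is additive in percentage points of the same scale.
    """
    if condition not in _CURVES:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    days = _grid(_LAST_DAY[condition])
    curves = _CURVES[condition]
    slope = nernst_slope_mv(temperature)

    def jitter(values: Sequence[float]) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        if noise > 0:
            arr = arr * (1.0 + rng.normal(0.0, noise, size=arr.shape))
        return np.clip(arr, 0.0, None)

    gsh = jitter(_GSH0_M * np.exp(-_GSH_DECAY * days))
    e_target = np.asarray(curves["egsh_mv"], dtype=float)
    gssg = gsh**2 * np.exp((e_target - (-240.0)) / slope)
    if noise > 0:
        gssg = gssg * (1.0 + rng.normal(0.0, noise, size=gssg.shape))
    viability = _logistic_viability(days, _T50[condition], _V_SLOPE[condition])
    if noise > 0:
        viability = viability + rng.normal(0.0, 100.0 * noise / 2.0, size=days.shape)
    viability = np.clip(viability, 0.0, 100.0)

    return MetaboliteSeries(
        condition=condition,
        days=days,
        gsh=gsh,
        gssg=np.clip(gssg, 1e-12, None),
        nadph=jitter(curves["nadph"]),
        nadp=jitter(curves["nadp"]),
        atp=jitter(curves["atp"]),
        viability=viability,
    )
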