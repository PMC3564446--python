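"""Glutathione redox potentials and NADPH-decline detection.

The glutathione couple sets the cytosolic thiol redox potential through

    E_GSH = E0 + (RT / 2F) * ln([GSSG] / [GSH]^2)

with E0 = -240 mV for GSH/GSSG, R the gas constant, F the Faraday
constant, T in kelvin, and concentrations in molar.  Because two GSH are
consumed per GSSG formed, the potential depends on the absolute GSH
concentration, not only the GSSG/GSH ratio.  At the 30 degC cultivation
temperature (303.15 K) the slope RT/2F is ~13.06 mV per ln-unit.

NADPH supplies the electrons for both the thioredoxin and the glutathione
systems; its decline is the earliest event in the redox cascade.  The
decline onset is read as the first sampled day after the series maximum at
which NADPH has dropped by a configurable fraction (default 20%) of the
maximum, and between-condition delays are reported in hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "RedoxCouple",
    "MetaboliteSeries",
    "nernst_slope_mv",
    "egsh",
    "egsh_series",
    "egsh_shift_day",
    "nadph_decline_onset",
    "condition_delay",
]

GAS_CONSTANT = 8.314462  # J / (mol K)
FARADAY = 96485.332  # C / mol


@dataclass(frozen=True)
class RedoxCouple:
    """GSH/GSSG concentrations (molar) with temperature and standard potential."""

    gsh: float
    gssg: float
    temperature: float = 303.15  # K; 30 degC cultivation
    e0: float = -240.0  # mV

    def __post_init__(self) -> None:
        if self.gsh <= 0 or self.gssg <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def nernst_slope_mv(temperature: float = 303.15) -> float:
    """RT/2F in millivolts per ln-unit (12.846 at 298.15 K, 13.062 at 303.15 K)."""
    return 1000.0 * GAS_CONSTANT * temperature / (2.0 * FARADAY)


def egsh(couple: RedoxCouple) -> float:
    """Glutathione redox potential in mV via the Nernst equation."""
    slope = nernst_slope_mv(couple.temperature)
    return couple.e0 + slope * math.log(couple.gssg / couple.gsh**2)


@dataclass
class MetaboliteSeries:
    """Per-day metabolite and viability measurements for one condition.

    GSH and GSSG are molar; NADPH/NADP+/ATP are in consistent (relative)
    units; viability is percent.  Arrays are aligned with ``days``.
    """

    condition: str
    days: np.ndarray
    gsh: np.ndarray
    gssg: np.ndarray
    nadph: np.ndarray
    nadp: np.ndarray
    atp: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        n = len(self.days)
        for name in ("gsh", "gssg", "nadph", "nadp", "atp", "viability"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must align with days ({n} entries)")
            setattr(self, name, arr)
        vals = self.viability[np.isfinite(self.viability)]
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("viability must lie in [0, 100]")


def egsh_series(
    series: MetaboliteSeries, temperature: float = 303.15, e0: float = -240.0
) -> np.ndarray:
    """E_GSH (mV) per sampled day; days with missing GSH/GSSG become NaN."""
    out = np.full(len(series.days), np.nan)
    for i, (g, gg) in enumerate(zip(series.gsh, series.gssg)):
        if not (np.isfinite(g) and np.isfinite(gg)) or g <= 0 or gg <= 0:
            warnings.warn(
                f"day {series.days[i]}: missing GSH/GSSG, skipped", stacklevel=2
            )
            continue
        out[i] = egsh(RedoxCouple(g, gg, temperature, e0))
    return out


def egsh_shift_day(
    series: MetaboliteSeries,
    threshold_mv: float = 15.0,
    temperature: float = 303.15,
) -> float | None:
    """First day with a pro-oxidizing E_GSH shift >= ``threshold_mv`` vs day 0."""
    e = egsh_series(series, temperature)
    finite = np.flatnonzero(np.isfinite(e))
    if finite.size < 2:
        raise ValueError("need at least two days with valid GSH/GSSG")
    e0 = e[finite[0]]
    for i in finite[1:]:
        if e[i] - e0 >= threshold_mv:
            return float(series.days[i])
    return None


def nadph_decline_onset(
    series: MetaboliteSeries, drop_frac: float = 0.2
) -> float | None:
    """First day after the NADPH maximum with a drop >= ``drop_frac`` of it.

    Returns None for series that never decline past the threshold (e.g.
    monotone rising).
    """
    if not 0 < drop_frac < 1:
        raise ValueError("drop_frac must be in (0, 1)")
    vals = np.asarray(series.nadph, dtype=float)
    if not np.isfinite(vals).any():
        raise ValueError("NADPH series is empty")
    imax = int(np.nanargmax(vals))
    threshold = (1.0 - drop_frac) * vals[imax]
    for i in range(imax + 1, len(vals)):
        if np.isfinite(vals[i]) and vals[i] <= threshold:
            return float(series.days[i])
    return None


def condition_delay(
    series_std: MetaboliteSeries,
    series_cr: MetaboliteSeries,
    metric: Callable[[MetaboliteSeries], float | None] = nadph_decline_onset,
) -> float | None:
    """Hours by which an event under caloric restriction lags standard.

    Returns None (flagged by a warning) when the event is undefined in
    either condition.
    """
    onset_std = metric(series_std)
    onset_cr = metric(series_cr)
    if onset_std is None or onset_cr is None:
        warnings.warn("event undefined in at least one condition", stacklevel=2)
        return None
    return 24.0 * (onset_cr - onset_std)
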