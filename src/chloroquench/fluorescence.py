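"""Apparent photosynthetic parameters from pulse-fluorescence series.

Standard saturation-pulse quantities: F_0/F_M from the dark-adapted plant,
then per time point the steady-state fluorescence F_S, the flash-saturated
maximum in the light F_M′, and (when measured) the post-illumination
maximum F_M″ after the rapidly reversible quenching has relaxed.

    Φ_II  = (F_M′ − F_S)/F_M′          PSII operating efficiency
    NPQ   = F_M/F_M′ − 1               total non-photochemical quenching
    qE_SV = F_M/F_M′ − F_M/F_M″        fast, energy-dependent component
    qI    = F_M/F_M″ − 1               slow, photoinhibitory component

NPQ = qE_SV + qI holds as an algebraic identity. Φ_II is a ratio of two
yields measured in the same optical state, so any common multiplicative
modulation (in particular the change in light reception caused by
chloroplast photorelocation) cancels; NPQ and its components compare
yields across optical states and are biased by movement — see
:mod:`chloroquench.correction`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChloroquenchError


def _require_positive(**named: float) -> None:
    for name, v in named.items():
        if not (v > 0) or math.isnan(v):
            raise ChloroquenchError(f"{name} must be positive, got {v}")


def phi_ii(F_s: float, F_m_prime: float) -> float:
    """PSII operating efficiency (F_M′ − F_S)/F_M′."""
    _require_positive(F_m_prime=F_m_prime)
    return (F_m_prime - F_s) / F_m_prime


def npq(F_m: float, F_m_prime: float) -> float:
    """Apparent non-photochemical quenching F_M/F_M′ − 1."""
    _require_positive(F_m=F_m, F_m_prime=F_m_prime)
    return F_m / F_m_prime - 1.0


def qe_sv(F_m: float, F_m_prime: float, F_m_dprime: float) -> float:
    """Apparent energy-dependent quenching F_M/F_M′ − F_M/F_M″ (Stern–Volmer form)."""
    _require_positive(F_m=F_m, F_m_prime=F_m_prime, F_m_dprime=F_m_dprime)
    return F_m / F_m_prime - F_m / F_m_dprime


def qi(F_m: float, F_m_dprime: float) -> float:
    """Apparent photoinhibitory quenching F_M/F_M″ − 1."""
    _require_positive(F_m=F_m, F_m_dprime=F_m_dprime)
    return F_m / F_m_dprime - 1.0


@dataclass(frozen=True)
class PulseEvent:
    """One saturation-pulse measurement in the light."""

    time: float                    # minutes
    F_s: float                     # steady-state fluorescence, a.u.
    F_m_prime: float               # flash maximum in the light, a.u.
    F_m_dprime: float | None = None  # post-illumination flash maximum, a.u.
    t_dprime: float | None = None    # minutes; time F_M″ was taken

    def __post_init__(self) -> None:
        if self.F_s <= 0 or self.F_m_prime <= 0:
            raise ChloroquenchError(f"event at {self.time} min: yields must be positive")
        if (self.F_m_dprime is None) != (self.t_dprime is None):
            raise ChloroquenchError(
                f"event at {self.time} min: F_m_dprime and t_dprime go together"
            )
        if self.F_m_dprime is not None and self.F_m_dprime <= 0:
            raise ChloroquenchError(f"event at {self.time} min: F_m_dprime must be positive")
        if self.t_dprime is not None and self.t_dprime <= self.time:
            raise ChloroquenchError(
                f"event at {self.time} min: t_dprime must be later than the pulse"
            )


@dataclass
class PulseEventSeries:
    """Dark-adapted (F_0, F_M) pair plus ordered pulse events."""

    F_0: float
    F_m: float
    events: list[PulseEvent] = field(default_factory=list)
    genotype: str | None = None

    def __post_init__(self) -> None:
        if not (self.F_m >= self.F_0 > 0):
            raise ChloroquenchError("need F_M ≥ F_0 > 0")
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ChloroquenchError("event times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])


@dataclass
class QuenchingSeries:
    """Φ_II, NPQ, qE_SV, qI per pulse event, apparent or movement-corrected.

    ``frame`` columns: time_min, phi_ii, npq, qe_sv, qi (NaN where F_M″
    was not measured).
    """

    frame: pd.DataFrame
    corrected: bool = False
    genotype: str | None = None


def process_series(series: PulseEventSeries) -> QuenchingSeries:
    """Apply the four pulse formulas eventwise (apparent, uncorrected).

    qE_SV and qI are NaN where the event lacks F_M″; errors from the
    element formulas are re-raised with the event index attached.
    """
    rows = []
    for k, e in enumerate(series.events):
        try:
            row = {
                "time_min": e.time,
                "phi_ii": phi_ii(e.F_s, e.F_m_prime),
                "npq": npq(series.F_m, e.F_m_prime),
                "qe_sv": np.nan,
                "qi": np.nan,
            }
            if e.F_m_dprime is not None:
                row["qe_sv"] = qe_sv(series.F_m, e.F_m_prime, e.F_m_dprime)
                row["qi"] = qi(series.F_m, e.F_m_dprime)
        except ChloroquenchError as err:
            raise ChloroquenchError(f"event {k} (t={e.time} min): {err}") from err
        rows.append(row)
    return QuenchingSeries(pd.DataFrame(rows), corrected=False,
                           genotype=series.genotype)
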