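"""Movement-corrected NPQ decomposition.

Chloroplast photorelocation changes how much measuring and actinic light
the chlorophyll bed receives, so fluorescence yields measured while the
chloroplasts have moved are modulated relative to the dark-adapted
baseline. The correction rescales each in-the-light yield by a factor
derived from simultaneously imaged reflectance:

    c′ = 1 + m·(R′ − R_0)/R_0        at the time F_M′ was taken
    c″ = 1 + m·(R″ − R_0)/R_0        at the time F_M″ was taken

    NPQ_corr   = c′·F_M/F_M′ − 1
    qE_SVcorr  = c′·F_M/F_M′ − c″·F_M/F_M″
    qI_corr    = c″·F_M/F_M″ − 1

where m is the slope of the relationship between fluorescence yield and
relative reflectance, determined empirically (≈1 for Arabidopsis).
NPQ_corr = qE_SVcorr + qI_corr holds identically. Φ_II needs no
correction: the modulation cancels in its ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ChloroquenchError
from .fluorescence import PulseEventSeries, QuenchingSeries, phi_ii
from .reflectance import ReflectanceTrace

DEFAULT_M = 1.0


def correction_factor(x: float, m: float) -> float:
    """Light-reception correction 1 + m·x for relative reflectance x.

    A non-positive factor means the linearised reception model is outside
    its domain (|m·x| ≥ 1) and is rejected.
    """
    c = 1.0 + m * x
    if c <= 0:
        raise ChloroquenchError(
            f"non-physical correction factor {c} (x={x}, m={m})"
        )
    return c


def npq_corr(F_m: float, F_m_prime: float, c_prime: float) -> float:
    """Movement-corrected NPQ: c′·F_M/F_M′ − 1."""
    if F_m <= 0 or F_m_prime <= 0:
        raise ChloroquenchError("fluorescence yields must be positive")
    if c_prime <= 0:
        raise ChloroquenchError("correction factor must be positive")
    return c_prime * F_m / F_m_prime - 1.0


def qi_corr(F_m: float, F_m_dprime: float, c_dprime: float) -> float:
    """Movement-corrected qI: c″·F_M/F_M″ − 1."""
    if F_m <= 0 or F_m_dprime <= 0:
        raise ChloroquenchError("fluorescence yields must be positive")
    if c_dprime <= 0:
        raise ChloroquenchError("correction factor must be positive")
    return c_dprime * F_m / F_m_dprime - 1.0


def qe_sv_corr(F_m: float, F_m_prime: float, F_m_dprime: float,
               c_prime: float, c_dprime: float) -> float:
    """Movement-corrected qE_SV: c′·F_M/F_M′ − c″·F_M/F_M″."""
    if min(F_m, F_m_prime, F_m_dprime) <= 0:
        raise ChloroquenchError("fluorescence yields must be positive")
    if c_prime <= 0 or c_dprime <= 0:
        raise ChloroquenchError("correction factors must be positive")
    return c_prime * F_m / F_m_prime - c_dprime * F_m / F_m_dprime


def estimate_m(yield_rel_changes, reflectance_rel_changes) -> float:
    """Slope of relative fluorescence-yield change on relative reflectance change.

    Ordinary least squares through the origin: both variables are defined
    as changes from the same dark baseline, so they vanish together and a
    free intercept would only absorb baseline error. The slope is
    Σxy/Σx².
    """
    y = np.asarray(yield_rel_changes, float)
    x = np.asarray(reflectance_rel_changes, float)
    if x.shape != y.shape:
        raise ChloroquenchError("calibration inputs must have equal length")
    if x.size < 2:
        raise ChloroquenchError("need at least two calibration points")
    if np.ptp(x) == 0:
        raise ChloroquenchError("degenerate predictor: reflectance changes all equal")
    sxx = float(x @ x)
    if sxx == 0:
        raise ChloroquenchError("degenerate predictor: zero variance")
    return float(x @ y) / sxx


def correct_series(series: PulseEventSeries, trace: ReflectanceTrace,
                   m: float = DEFAULT_M) -> QuenchingSeries:
    """Apply the movement correction to every pulse event.

    For each event, x′ is the relative reflectance at the F_M′ time and x″
    at the (later) F_M″ time, each from the nearest trace sample (ties to
    the earlier sample; times past the end of the trace carry the last
    value forward with a warning). Φ_II passes through uncorrected.
    """
    rows = []
    for k, e in enumerate(series.events):
        try:
            c_p = correction_factor(trace.value_at(e.time), m)
            row = {
                "time_min": e.time,
                "phi_ii": phi_ii(e.F_s, e.F_m_prime),
                "npq": npq_corr(series.F_m, e.F_m_prime, c_p),
                "qe_sv": np.nan,
                "qi": np.nan,
            }
            if e.F_m_dprime is not None:
                c_pp = correction_factor(trace.value_at(e.t_dprime, clamp=True), m)
                row["qe_sv"] = qe_sv_corr(series.F_m, e.F_m_prime,
                                          e.F_m_dprime, c_p, c_pp)
                row["qi"] = qi_corr(series.F_m, e.F_m_dprime, c_pp)
        except ChloroquenchError as err:
            raise ChloroquenchError(f"event {k} (t={e.time} min): {err}") from err
        rows.append(row)
    return QuenchingSeries(pd.DataFrame(rows), corrected=True,
                           genotype=series.genotype)
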