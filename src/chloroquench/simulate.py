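"""Synthetic-data generator for the dual-imaging pipeline.

Forward models for the two signals the pipeline analyses, with ground
truth retained so every downstream stage is verifiable without real
plant data.

Movement
    Relative reflectance x(t) = ΔR/R_0 relaxes first-order toward a
    light-dependent target,

        dx/dt = (x*(I) − x)/τ(I),
        x*(I) = −acc_amplitude·I/(I + K_move)                    0 < I ≤ I_switch
        x*(I) = +avoid_amplitude·(I − I_switch)/((I − I_switch) + K_move)   I > I_switch
        x*(0) = 0 (relaxation in darkness, time constant tau_dark)

    Because light is piecewise constant on the sampling grid and the ODE
    is linear, each step is advanced with the exact exponential update —
    no integration error.

Quenching
    qE responds instantaneously to intensity (saturating, capacity
    qE_max); qI accumulates above a damage threshold and is repaired
    first-order,

        qE(t) = qE_max·I/(I + K_qE)
        dqI/dt = k_dmg·max(0, I − I_crit) − k_rep·qI,  qI(0) = 0
        Φ_II(t) = phi_max·K_phi/(K_phi + I) / (1 + beta_qI·qI)
        NPQ_true = qE + qI.

Observation
    Intrinsic yields follow the Stern–Volmer relations
    F_M′ = F_M/(1 + qE + qI), F_M″ = F_M/(1 + qI),
    F_S = F_M′·(1 − Φ_II); each in-the-light yield is then modulated by
    the light-reception factor (1 + m·x) at its own measurement time —
    the exact algebraic inverse of the movement correction — and
    multiplicative Gaussian noise of coefficient of variation cv_noise is
    applied. The dark-adapted F_0 and F_M are emitted unmodulated (x = 0
    by definition of the baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChloroquenchError
from .fluorescence import PulseEvent, PulseEventSeries
from .profiles import GenotypeProfile
from .reflectance import ReflectanceTrace
from .regimes import LightRegime

DEFAULT_DT = 1.0          # min; sampling and integration grid
DEFAULT_FM_DARK = 1000.0  # a.u.
DEFAULT_T_RELAX = 10.0    # min; dark interval before the F_M″ flash


@dataclass
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``frame`` columns: time_min, intensity, x (noiseless relative
    reflectance, NaN if movement was not simulated), qE, qI, npq, phi_ii.
    """

    frame: pd.DataFrame
    m_true: float | None = None
    seed: int | None = None
    regime: LightRegime | None = None
    profile: GenotypeProfile | None = None

    def at(self, t: float) -> pd.Series:
        """Truth row at the grid sample nearest ``t``."""
        idx = (self.frame["time_min"] - t).abs().idxmin()
        return self.frame.loc[idx]


def _movement_target(I: float, g: GenotypeProfile) -> tuple[float, float]:
    """(target x*, time constant τ) for intensity I."""
    if I <= 0:
        return 0.0, g.tau_dark
    if I <= g.I_switch:
        return -g.acc_amplitude * I / (I + g.K_move), g.tau_acc
    d = I - g.I_switch
    return g.avoid_amplitude * d / (d + g.K_move), g.tau_avoid


def _time_grid(regime: LightRegime, dt: float) -> np.ndarray:
    n = int(round((regime.end_time - regime.start_time) / dt))
    return regime.start_time + dt * np.arange(n + 1)


def simulate_movement(regime: LightRegime, g: GenotypeProfile,
                      noise_sd: float = 0.0, seed: int = 0,
                      dt: float = DEFAULT_DT,
                      R_0: float = 1.0) -> tuple[ReflectanceTrace, SimulationTruth]:
    """Simulate a reflectance trace under ``regime`` for genotype ``g``.

    Returns the (possibly noisy) :class:`ReflectanceTrace` and a
    :class:`SimulationTruth` holding the noiseless x(t). Identical seeds
    give bitwise-identical traces.
    """
    if noise_sd < 0:
        raise ChloroquenchError("noise_sd must be non-negative")
    times = _time_grid(regime, dt)
    x = np.zeros_like(times)
    for k in range(times.size - 1):
        I = regime.intensity_at(float(times[k]))
        target, tau = _movement_target(I, g)
        x[k + 1] = target + (x[k] - target) * math.exp(-dt / tau)
    rng = np.random.default_rng(seed)
    noisy = x + (rng.normal(0.0, noise_sd, x.shape) if noise_sd > 0 else 0.0)
    trace = ReflectanceTrace.from_relative(times, noisy, R_0=R_0, genotype=g.name)
    frame = pd.DataFrame({
        "time_min": times,
        "intensity": np.append(regime.intensities(times[:-1]),
                               regime.steps[-1].intensity),
        "x": x,
        "qE": np.nan, "qI": np.nan, "npq": np.nan, "phi_ii": np.nan,
    })
    return trace, SimulationTruth(frame, seed=seed, regime=regime, profile=g)


def simulate_quenching(regime: LightRegime, g: GenotypeProfile,
                       dt: float = DEFAULT_DT) -> SimulationTruth:
    """Simulate intrinsic qE, qI, NPQ and Φ_II trajectories (noiseless)."""
    times = _time_grid(regime, dt)
    I = np.append(regime.intensities(times[:-1]), regime.steps[-1].intensity)
    qE = g.qE_max * I / (I + g.K_qE)
    qI = np.zeros_like(times)
    for k in range(times.size - 1):
        a = g.k_dmg * max(0.0, I[k] - g.I_crit)
        if g.k_rep > 0:
            ss = a / g.k_rep
            qI[k + 1] = ss + (qI[k] - ss) * math.exp(-g.k_rep * dt)
        else:
            qI[k + 1] = qI[k] + a * dt
    phi = g.phi_max * g.K_phi / (g.K_phi + I) / (1.0 + g.beta_qI * qI)
    frame = pd.DataFrame({
        "time_min": times, "intensity": I, "x": np.nan,
        "qE": qE, "qI": qI, "npq": qE + qI, "phi_ii": phi,
    })
    return SimulationTruth(frame, regime=regime, profile=g)


def simulate_experiment(regime: LightRegime, g: GenotypeProfile,
                        noise_sd: float = 0.0, seed: int = 0,
                        dt: float = DEFAULT_DT,
                        R_0: float = 1.0,
                        m_true: float = 1.0) -> tuple[ReflectanceTrace, SimulationTruth]:
    """Movement and quenching truth on a shared grid (one call)."""
    trace, mov = simulate_movement(regime, g, noise_sd, seed, dt, R_0)
    que = simulate_quenching(regime, g, dt)
    frame = que.frame.copy()
    frame["x"] = mov.frame["x"]
    return trace, SimulationTruth(frame, m_true=m_true, seed=seed,
                                  regime=regime, profile=g)


def default_pulse_times(regime: LightRegime, dt: float = DEFAULT_DT) -> np.ndarray:
    """One saturation pulse at the end of each lit step.

    The pulse is placed one grid interval before the step boundary so the
    plant is still under that step's light. For constant-light days with
    hourly steps this reproduces the every-60-min measurement cadence.
    """
    return np.array([s.end_time - dt for s in regime.lit_steps()])


def render_observed_pulses(truth: SimulationTruth, trace: ReflectanceTrace,
                           m: float = 1.0,
                           F_M_dark: float = DEFAULT_FM_DARK,
                           cv_noise: float = 0.0, seed: int = 0,
                           pulse_times: np.ndarray | None = None,
                           t_relax: float = DEFAULT_T_RELAX) -> PulseEventSeries:
    """Render the observed pulse-fluorescence series from simulation truth.

    Each event reads the intrinsic yields off the truth at the pulse time,
    modulates them by (1 + m·x) with x taken at each yield's own
    measurement time (F_M″ is flashed ``t_relax`` minutes into the
    following dark relaxation, during which qE has fully relaxed and qI
    persists), and applies multiplicative Gaussian noise of CV
    ``cv_noise``.
    """
    if F_M_dark <= 0:
        raise ChloroquenchError("F_M_dark must be positive")
    if cv_noise < 0:
        raise ChloroquenchError("cv_noise must be non-negative")
    if truth.frame["qE"].isna().any():
        raise ChloroquenchError("truth lacks quenching trajectories; "
                                "use simulate_experiment or simulate_quenching")
    if pulse_times is None:
        if truth.regime is None:
            raise ChloroquenchError("no pulse times given and truth has no regime")
        pulse_times = default_pulse_times(truth.regime)
    rng = np.random.default_rng(seed)

    def jitter() -> float:
        return 1.0 + cv_noise * rng.standard_normal() if cv_noise > 0 else 1.0

    phi_dark = truth.profile.phi_max if truth.profile is not None \
        else float(truth.frame["phi_ii"].iloc[0])
    F_0 = F_M_dark * (1.0 - phi_dark) * jitter()
    F_m = F_M_dark * jitter()
    events = []
    for t in np.asarray(pulse_times, float):
        row = truth.at(float(t))
        qE, qI, phi = float(row["qE"]), float(row["qI"]), float(row["phi_ii"])
        f_mp_int = F_M_dark / (1.0 + qE + qI)
        f_mpp_int = F_M_dark / (1.0 + qI)
        f_s_int = f_mp_int * (1.0 - phi)
        x_p = trace.value_at(float(t), clamp=True)
        x_pp = trace.value_at(float(t) + t_relax, clamp=True)
        events.append(PulseEvent(
            time=float(t),
            F_s=f_s_int * (1.0 + m * x_p) * jitter(),
            F_m_prime=f_mp_int * (1.0 + m * x_p) * jitter(),
            F_m_dprime=f_mpp_int * (1.0 + m * x_pp) * jitter(),
            t_dprime=float(t) + t_relax,
        ))
    name = truth.profile.name if truth.profile is not None else None
    return PulseEventSeries(F_0=F_0, F_m=F_m, events=events, genotype=name)


def simulate_calibration(n: int = 200, m_true: float = 1.0,
                         cv_noise: float = 0.02, seed: int = 0,
                         x_low: float = -0.1, x_high: float = 0.4,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Calibration set for :func:`chloroquench.correction.estimate_m`.

    Draws relative reflectance changes uniformly over the physiological
    range and returns the matching relative fluorescence-yield changes,
    (F_obs − F_int)/F_int = m·x under noise-free observation, with
    multiplicative noise of CV ``cv_noise`` on the observed yield.
    """
    if n < 2:
        raise ChloroquenchError("need at least two calibration points")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_low, x_high, n)
    obs = (1.0 + m_true * x) * (1.0 + cv_noise * rng.standard_normal(n))
    return obs - 1.0, x


def render_image_frames(trace: ReflectanceTrace, image_size: int = 64,
                        plant_radius: int = 20, frames_per_burst: int = 30,
                        pixel_noise_sd: float = 0.01,
                        background: float = 0.1,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Render per-time-point image bursts for a reflectance trace.

    Each burst holds ``frames_per_burst`` frames: ``background`` outside a
    centred disk-shaped plant mask, R(t) inside, i.i.d. Gaussian pixel
    noise throughout. Returns (bursts, mask) with bursts shaped
    (n_times, frames_per_burst, H, W).
    """
    if frames_per_burst < 1:
        raise ChloroquenchError("frames_per_burst must be >= 1")
    if 2 * plant_radius >= image_size:
        raise ChloroquenchError("plant disk does not fit inside the image")
    if pixel_noise_sd < 0:
        raise ChloroquenchError("pixel_noise_sd must be non-negative")
    c = image_size / 2.0 - 0.5
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= plant_radius ** 2
    rng = np.random.default_rng(seed)
    bursts = np.empty((trace.times.size, frames_per_burst, image_size, image_size))
    for k, R in enumerate(trace.R):
        base = np.where(mask, R, background)
        noise = (rng.normal(0.0, pixel_noise_sd,
                            (frames_per_burst, image_size, image_size))
                 if pixel_noise_sd > 0 else 0.0)
        bursts[k] = base + noise
    return bursts, mask
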