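"""Light regimes: ordered dark/ambient/fluctuating schedules driving simulation and analysis.

A regime is a contiguous, non-overlapping sequence of constant-intensity
steps. Intensities are photon flux densities in µmol photons m⁻² s⁻¹ and
times are minutes from the start of the (simulated) day. ``fluctuating``
steps always carry exactly twice the intensity of the ambient step that
precedes them, mirroring the paired ambient/double-intensity exposures of
dynamic-light phenotyping protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ChloroquenchError

PHASES = ("dark", "ambient", "fluctuating")


@dataclass(frozen=True)
class LightStep:
    """One constant-intensity interval of a light schedule."""

    start_time: float  # minutes
    duration: float  # minutes
    intensity: float  # µmol photons m⁻² s⁻¹
    phase: str  # dark | ambient | fluctuating

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class LightRegime:
    """An ordered, gap-free schedule of light steps for one day.

    Parameters
    ----------
    steps
        Contiguous :class:`LightStep` objects; step ``k+1`` must start
        exactly where step ``k`` ends.
    photoperiod_length
        Length of the lit part of the day, minutes.
    day_index
        1-based day number within a multi-day protocol.
    """

    steps: list[LightStep]
    photoperiod_length: float
    day_index: int = 1
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ChloroquenchError("a light regime needs at least one step")
        if self.day_index < 1:
            raise ChloroquenchError("day_index must be >= 1")
        prev_end = self.steps[0].start_time
        prev: LightStep | None = None
        for k, s in enumerate(self.steps):
            if s.phase not in PHASES:
                raise ChloroquenchError(f"step {k}: unknown phase {s.phase!r}")
            if s.duration <= 0:
                raise ChloroquenchError(f"step {k}: non-positive duration")
            if s.start_time != prev_end:
                raise ChloroquenchError(
                    f"step {k}: starts at {s.start_time}, expected {prev_end}"
                )
            if s.intensity < 0:
                raise ChloroquenchError(f"step {k}: negative intensity")
            if (s.phase == "dark") != (s.intensity == 0):
                raise ChloroquenchError(
                    f"step {k}: phase 'dark' if and only if intensity is 0"
                )
            if s.phase == "fluctuating":
                if prev is None or prev.phase != "ambient":
                    raise ChloroquenchError(
                        f"step {k}: fluctuating step must follow an ambient step"
                    )
                if s.intensity != 2.0 * prev.intensity:
                    raise ChloroquenchError(
                        f"step {k}: fluctuating intensity {s.intensity} is not "
                        f"exactly twice the preceding ambient {prev.intensity}"
                    )
            prev_end = s.end_time
            prev = s
        self._starts = np.array([s.start_time for s in self.steps])

    @property
    def start_time(self) -> float:
        return self.steps[0].start_time

    @property
    def end_time(self) -> float:
        return self.steps[-1].end_time

    def step_at(self, t: float) -> LightStep:
        """Step whose half-open interval [start, end) contains ``t``.

        ``t`` equal to the regime end maps to the final step.
        """
        if t < self.start_time or t > self.end_time:
            raise ChloroquenchError(f"time {t} outside regime [{self.start_time}, {self.end_time}]")
        idx = int(np.searchsorted(self._starts, t, side="right")) - 1
        return self.steps[max(idx, 0)]

    def intensity_at(self, t: float) -> float:
        return self.step_at(t).intensity

    def intensities(self, times: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`intensity_at`."""
        return np.array([self.intensity_at(float(t)) for t in np.asarray(times, float)])

    def lit_steps(self) -> list[LightStep]:
        return [s for s in self.steps if s.intensity > 0]


def build_photorelocation_regime(
    intensity_ladder: list[float] = (10.0, 50.0, 100.0, 250.0, 500.0),
    step_minutes: float = 60.0,
) -> LightRegime:
    """Alternating dark / white-light ladder used for photorelocation assays.

    The schedule starts with one dark step, then alternates dark and light
    so that light step ``k`` carries ``intensity_ladder[k-1]``. With the
    default five-step ladder and 60-min steps the first light step ends at
    minute 120 (accumulation read-out) and the fifth at minute 600
    (avoidance read-out).
    """
    ladder = list(intensity_ladder)
    if not ladder:
        raise ChloroquenchError("intensity ladder is empty")
    if any(i <= 0 for i in ladder):
        raise ChloroquenchError("ladder intensities must be strictly positive")
    if step_minutes <= 0:
        raise ChloroquenchError("step_minutes must be positive")
    steps: list[LightStep] = []
    t = 0.0
    for intensity in ladder:
        steps.append(LightStep(t, step_minutes, 0.0, "dark"))
        t += step_minutes
        steps.append(LightStep(t, step_minutes, float(intensity), "ambient"))
        t += step_minutes
    return LightRegime(steps, photoperiod_length=t, day_index=1)


def _sinusoid_intensities(peak: float, n_steps: int) -> list[float]:
    # Half-sine sampled at step centres, renormalised so the two
    # mid-photoperiod steps hit the peak exactly.
    raw = [math.sin(math.pi * (k + 0.5) / n_steps) for k in range(n_steps)]
    top = max(raw)
    return [peak * r / top for r in raw]


def _constant_day(intensity: float, photoperiod: float, dark_tail: float,
                  day_index: int, step_minutes: float = 60.0) -> LightRegime:
    steps = []
    t = 0.0
    while t < photoperiod:
        steps.append(LightStep(t, step_minutes, intensity, "ambient"))
        t += step_minutes
    steps.append(LightStep(t, dark_tail, 0.0, "dark"))
    return LightRegime(steps, photoperiod_length=photoperiod, day_index=day_index)


def _sinusoidal_day(peak: float, photoperiod: float, dark_tail: float,
                    day_index: int, step_minutes: float = 60.0) -> LightRegime:
    n = int(round(photoperiod / step_minutes))
    steps = []
    t = 0.0
    for intensity in _sinusoid_intensities(peak, n):
        steps.append(LightStep(t, step_minutes, intensity, "ambient"))
        t += step_minutes
    steps.append(LightStep(t, dark_tail, 0.0, "dark"))
    return LightRegime(steps, photoperiod_length=photoperiod, day_index=day_index)


def _fluctuating_day(peak: float, photoperiod: float, dark_tail: float,
                     day_index: int, step_minutes: float = 60.0,
                     ambient_minutes: float = 40.0) -> LightRegime:
    """Each hourly ambient intensity is followed by a shorter step at exactly
    double that intensity."""
    n = int(round(photoperiod / step_minutes))
    fluct_minutes = step_minutes - ambient_minutes
    if fluct_minutes <= 0:
        raise ChloroquenchError("ambient_minutes must be shorter than the hourly step")
    steps = []
    t = 0.0
    for intensity in _sinusoid_intensities(peak, n):
        steps.append(LightStep(t, ambient_minutes, intensity, "ambient"))
        t += ambient_minutes
        steps.append(LightStep(t, fluct_minutes, 2.0 * intensity, "fluctuating"))
        t += fluct_minutes
    steps.append(LightStep(t, dark_tail, 0.0, "dark"))
    return LightRegime(steps, photoperiod_length=photoperiod, day_index=day_index)


def build_five_day_regime(
    constant_intensity: float = 100.0,
    peak_intensity: float = 500.0,
    photoperiod_minutes: float = 960.0,
    dark_minutes: float = 480.0,
) -> list[LightRegime]:
    """Five-day dynamic-light protocol.

    Days 1 and 4: constant light (default 100 µmol m⁻² s⁻¹) over a 16-h
    photoperiod. Day 2: hourly-discretised sinusoid peaking at 500 at
    mid-photoperiod. Days 3 and 5: the Day-2 ambient steps, each followed
    by a shorter exposure at exactly twice the ambient intensity.
    """
    return [
        _constant_day(constant_intensity, photoperiod_minutes, dark_minutes, 1),
        _sinusoidal_day(peak_intensity, photoperiod_minutes, dark_minutes, 2),
        _fluctuating_day(peak_intensity, photoperiod_minutes, dark_minutes, 3),
        _constant_day(constant_intensity, photoperiod_minutes, dark_minutes, 4),
        _fluctuating_day(peak_intensity, photoperiod_minutes, dark_minutes, 5),
    ]


def build_single_fluctuating_day(
    peak_intensity: float = 500.0,
    photoperiod_minutes: float = 960.0,
    dark_minutes: float = 480.0,
) -> LightRegime:
    """One day of fluctuating light (the Day-3 schedule), used for
    single-day dual-imaging experiments."""
    return _fluctuating_day(peak_intensity, photoperiod_minutes, dark_minutes, 1)
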