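"""Genotype profiles: simulator parameters for wild-type and division-mutant classes.

A profile bundles the movement kinetics (accumulation/avoidance amplitudes,
time constants, crossover intensity) and the quenching machinery (qE
capacity, photoinhibition damage/repair rates, PSII yield parameters) of one
genotype class. Presets are data, not logic: they are calibrated
qualitatively to the published chloroplast-size classes — large-chloroplast
mutants retain only ~25–35% of the wild-type avoidance response,
intermediate mutants ~55–80%, and small-chloroplast overexpressors are
indistinguishable from the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ChloroquenchError


@dataclass(frozen=True)
class GenotypeProfile:
    """Forward-model parameters for one genotype.

    Movement: relative reflectance relaxes first-order toward a
    light-dependent target — negative (accumulation) for intensities at or
    below ``I_switch``, positive (avoidance) above it, with Hill-type
    saturation of half-constant ``K_move``. Quenching: qE responds
    instantaneously to intensity with capacity ``qE_max``; qI accumulates at
    rate ``k_dmg`` per unit of intensity above ``I_crit`` and is repaired at
    rate ``k_rep``; steady-state PSII quantum yield declines with intensity
    (half-constant ``K_phi``) and with accumulated qI (sensitivity
    ``beta_qI``).
    """

    name: str
    # movement
    acc_amplitude: float = 0.9     # dimensionless, applied with negative sign
    avoid_amplitude: float = 0.45  # dimensionless
    tau_acc: float = 25.0          # min
    tau_avoid: float = 60.0        # min
    tau_dark: float = 30.0         # min
    I_switch: float = 20.0         # µmol m⁻² s⁻¹
    K_move: float = 100.0          # µmol m⁻² s⁻¹
    # quenching
    qE_max: float = 2.5            # dimensionless
    K_qE: float = 250.0            # µmol m⁻² s⁻¹
    k_dmg: float = 1.0e-5          # qI units per (µmol m⁻² s⁻¹ · min)
    I_crit: float = 200.0          # µmol m⁻² s⁻¹
    k_rep: float = 5.0e-3          # min⁻¹
    phi_max: float = 0.8           # dimensionless
    K_phi: float = 500.0           # µmol m⁻² s⁻¹
    beta_qI: float = 0.3           # dimensionless

    def __post_init__(self) -> None:
        nonneg = (
            "acc_amplitude", "avoid_amplitude", "I_switch", "qE_max", "K_qE",
            "k_dmg", "I_crit", "k_rep", "beta_qI",
        )
        for f in nonneg:
            if getattr(self, f) < 0:
                raise ChloroquenchError(f"{self.name}: {f} must be non-negative")
        for f in ("tau_acc", "tau_avoid", "tau_dark", "K_move", "K_phi"):
            if getattr(self, f) <= 0:
                raise ChloroquenchError(f"{self.name}: {f} must be positive")
        if not (0.0 < self.phi_max <= 1.0):
            raise ChloroquenchError(f"{self.name}: phi_max must be in (0, 1]")


_WT = GenotypeProfile(name="WT")

#: Presets keyed by chloroplast-size class. The large class combines a
#: severely attenuated avoidance response with slower movement onset and a
#: higher photodamage rate; the intermediate class is partially attenuated;
#: the small class shares every parameter with the wild type.
PRESETS: dict[str, GenotypeProfile] = {
    "WT": _WT,
    "large": replace(
        _WT, name="large",
        acc_amplitude=_WT.acc_amplitude * 0.60,
        avoid_amplitude=_WT.avoid_amplitude * 0.30,
        tau_avoid=90.0,
        k_dmg=2.5e-5,
    ),
    "intermediate": replace(
        _WT, name="intermediate",
        acc_amplitude=_WT.acc_amplitude * 0.80,
        avoid_amplitude=_WT.avoid_amplitude * 0.65,
        tau_avoid=75.0,
        k_dmg=1.6e-5,
    ),
    "small": replace(_WT, name="small"),
}


def get_profile(name_or_profile: str | GenotypeProfile) -> GenotypeProfile:
    """Resolve a preset name to its profile; pass profiles through."""
    if isinstance(name_or_profile, GenotypeProfile):
        return name_or_profile
    try:
        return PRESETS[name_or_profile]
    except KeyError:
        raise ChloroquenchError(
            f"unknown genotype preset {name_or_profile!r}; "
            f"available: {sorted(PRESETS)}"
        ) from None
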