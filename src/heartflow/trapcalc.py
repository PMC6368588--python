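"""Closed-form design calculators for a dual-transducer acoustic trap with
flow-through perfusion.

The trap consists of two confocal, spherically focused ultrasonic transducers
facing each other; samples are held at a pressure node of the resulting
standing wave.  All routines here are pure closed-form functions of the
transducer geometry, the propagation medium, and the perfusion chamber, so the
same inputs always produce identical outputs.

Water properties are derived from temperature with standard empirical
polynomials (Marczak's sound-speed polynomial, Kell's density formula), both
valid over 0–100 °C at atmospheric pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TransducerSpec",
    "MediumSpec",
    "PerfusionChamber",
    "water_sound_speed",
    "water_density",
    "wavelength",
    "f_number",
    "resonator_axial_length",
    "beam_diameter_6db",
    "plane_wave_intensity",
    "pressure_from_intensity",
    "sphere_apparent_weight",
    "washout_concentration",
    "washout_time_constant",
    "resource_equation_n",
    "design_report",
]

G_STANDARD = 9.80665  # m/s², standard gravity

#: −6 dB full beamwidth coefficient for a spherically focused piston,
#: beam diameter ≈ 1.41 · λ · f#  (standard focused-piston approximation).
BEAMWIDTH_6DB_COEFF = 1.41


def water_sound_speed(temperature_c: float) -> float:
    """Speed of sound in pure water (m/s) at atmospheric pressure.

    Marczak (1997) fifth-order polynomial, 0–95 °C.
    """
    t = float(temperature_c)
    if not 0.0 <= t <= 95.0:
        raise ValueError(f"temperature {t} °C outside polynomial validity (0–95)")
    return (
        1.402385e3
        + 5.038813 * t
        - 5.799136e-2 * t**2
        + 3.287156e-4 * t**3
        - 1.398845e-6 * t**4
        + 2.787860e-9 * t**5
    )


def water_density(temperature_c: float) -> float:
    """Density of air-free pure water (kg/m³), Kell (1975) formulation."""
    t = float(temperature_c)
    if not 0.0 <= t <= 100.0:
        raise ValueError(f"temperature {t} °C outside formula validity (0–100)")
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.897850e-3 * t)


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry of one bowl-shaped focused transducer.

    ``focal_radius_mm`` is the radius of curvature of the active element,
    which for a spherical bowl equals its focal length.
    """

    aperture_diameter_mm: float = 20.0
    focal_radius_mm: float = 16.0
    frequency_mhz: float = 1.5

    def __post_init__(self) -> None:
        if min(self.aperture_diameter_mm, self.focal_radius_mm, self.frequency_mhz) <= 0:
            raise ValueError("transducer dimensions and frequency must be positive")
        if self.focal_radius_mm < self.aperture_diameter_mm / 4.0:
            raise ValueError(
                "focal radius below aperture/4: bowl cannot be physically concave"
            )


@dataclass(frozen=True)
class MediumSpec:
    """Acoustic propagation medium; defaults describe water at 22 °C.

    Either pass density/sound speed explicitly or let them be derived from
    ``temperature_c``.
    """

    temperature_c: float = 22.0
    density_kg_m3: float | None = None
    sound_speed_m_s: float | None = None

    def __post_init__(self) -> None:
        if self.density_kg_m3 is None:
            object.__setattr__(self, "density_kg_m3", water_density(self.temperature_c))
        if self.sound_speed_m_s is None:
            object.__setattr__(
                self, "sound_speed_m_s", water_sound_speed(self.temperature_c)
            )
        if self.density_kg_m3 <= 0 or self.sound_speed_m_s <= 0:
            raise ValueError("density and sound speed must be positive")


@dataclass(frozen=True)
class PerfusionChamber:
    """Well-mixed sample chamber flushed by a peristaltic pump."""

    fluid_volume_ml: float = 57.5
    pump_rate_ml_min: float = 20.0

    def __post_init__(self) -> None:
        if self.fluid_volume_ml <= 0 or self.pump_rate_ml_min <= 0:
            raise ValueError("chamber volume and pump rate must be positive")


def wavelength(transducer: TransducerSpec, medium: MediumSpec | None = None) -> float:
    """Acoustic wavelength λ = c/f in the medium, in mm."""
    medium = medium or MediumSpec()
    return medium.sound_speed_m_s / (transducer.frequency_mhz * 1e6) * 1e3


def f_number(transducer: TransducerSpec) -> float:
    """f-number: focal length over aperture diameter (dimensionless)."""
    return transducer.focal_radius_mm / transducer.aperture_diameter_mm


def resonator_axial_length(transducer: TransducerSpec) -> float:
    """Axial length (mm) of the confocal counter-propagating resonator.

    Two identical bowls share a focus, so the cavity spans twice the focal
    radius.
    """
    return 2.0 * transducer.focal_radius_mm


def beam_diameter_6db(
    transducer: TransducerSpec, medium: MediumSpec | None = None
) -> float:
    """−6 dB focal beam diameter (mm) of a spherically focused piston."""
    return BEAMWIDTH_6DB_COEFF * wavelength(transducer, medium) * f_number(transducer)


def plane_wave_intensity(
    pressure_amplitude_mpa: float, medium: MediumSpec | None = None
) -> float:
    """Time-averaged intensity (W/cm²) of a sinusoidal plane wave.

    I = p²/(2ρc) with p the peak pressure amplitude.
    """
    if pressure_amplitude_mpa <= 0:
        raise ValueError("pressure amplitude must be positive")
    medium = medium or MediumSpec()
    p_pa = pressure_amplitude_mpa * 1e6
    i_w_m2 = p_pa**2 / (2.0 * medium.density_kg_m3 * medium.sound_speed_m_s)
    return i_w_m2 * 1e-4  # W/m² → W/cm²


def pressure_from_intensity(
    intensity_w_cm2: float, medium: MediumSpec | None = None
) -> float:
    """Inverse of :func:`plane_wave_intensity`: peak pressure (MPa) from W/cm²."""
    if intensity_w_cm2 <= 0:
        raise ValueError("intensity must be positive")
    medium = medium or MediumSpec()
    i_w_m2 = intensity_w_cm2 * 1e4
    p_pa = math.sqrt(2.0 * medium.density_kg_m3 * medium.sound_speed_m_s * i_w_m2)
    return p_pa * 1e-6


def sphere_apparent_weight(
    diameter_um: float, sphere_density_kg_m3: float, medium: MediumSpec | None = None
) -> float:
    """Apparent (submerged) weight of a sphere in the medium, in μN.

    (ρ_s − ρ_f)·(π/6)d³·g — the minimum lateral trap force needed to levitate
    the sphere against gravity minus buoyancy.  Negative values mean the
    sphere floats.
    """
    if diameter_um <= 0 or sphere_density_kg_m3 <= 0:
        raise ValueError("diameter and density must be positive")
    medium = medium or MediumSpec()
    d_m = diameter_um * 1e-6
    force_n = (
        (sphere_density_kg_m3 - medium.density_kg_m3)
        * (math.pi / 6.0)
        * d_m**3
        * G_STANDARD
    )
    return force_n * 1e6  # N → μN


def washout_time_constant(chamber: PerfusionChamber) -> float:
    """Washout time constant τ = V/Q of the well-mixed chamber, minutes."""
    return chamber.fluid_volume_ml / chamber.pump_rate_ml_min


def washout_concentration(
    chamber: PerfusionChamber, c0: float, t_min: float, lag_min: float = 0.0
) -> float:
    """Drug concentration during washout of a well-mixed chamber.

    Fresh medium enters at the pump rate while the outlet goes to waste, so
    C(t) = C0·exp(−(t−lag)/τ) with τ = V/Q.  ``lag_min`` models transport
    delay from the reservoir to the sample (concentration holds at C0 until
    then).
    """
    if t_min < 0:
        raise ValueError("time must be nonnegative")
    t_eff = max(0.0, t_min - lag_min)
    return c0 * math.exp(-t_eff / washout_time_constant(chamber))


def resource_equation_n(
    groups: int, e_min: int = 10, e_max: int = 20
) -> tuple[int, int]:
    """Admissible per-group sample size range by the resource-equation method.

    With k groups of n animals each, the error degrees of freedom of a
    one-way ANOVA are E = N − k = k·n − k; the method asks for
    ``e_min ≤ E ≤ e_max`` (conventionally 10–20).  Returns the smallest and
    largest integer n satisfying the bound.
    """
    if groups < 2:
        raise ValueError("need at least 2 groups")
    if e_min > e_max:
        raise ValueError("e_min must not exceed e_max")
    lo = math.ceil(e_min / groups + 1)
    hi = math.floor(e_max / groups + 1)
    if hi < lo:
        raise ValueError(
            f"no integer group size satisfies {e_min} <= {groups}*n-{groups} <= {e_max}"
        )
    return lo, hi


def design_report(
    transducer: TransducerSpec | None = None,
    medium: MediumSpec | None = None,
    chamber: PerfusionChamber | None = None,
) -> dict[str, float]:
    """All derived trap/perfusion quantities as a flat mapping with units in keys."""
    transducer = transducer or TransducerSpec()
    medium = medium or MediumSpec()
    chamber = chamber or PerfusionChamber()
    return {
        "sound_speed_m_s": medium.sound_speed_m_s,
        "density_kg_m3": medium.density_kg_m3,
        "wavelength_mm": wavelength(transducer, medium),
        "f_number": f_number(transducer),
        "resonator_axial_length_mm": resonator_axial_length(transducer),
        "beam_diameter_6db_mm": beam_diameter_6db(transducer, medium),
        "washout_tau_min": washout_time_constant(chamber),
    }
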