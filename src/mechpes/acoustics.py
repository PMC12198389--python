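"""Ultrasound dosimetry: intensity, linear-approximation pressure, and the
FDA mechanical index.

For probe sonication the intensity is the output power over the emitting
area, I = P/A with P = E/t_on (spent energy over sonication on-time) and
A = πr².  For sinusoidal waves in the linear approximation, intensity and
acoustic pressure are related through the plane-wave impedance ρc:
I = p_rms²/(ρc), with peak pressure p_peak = √2·p_rms.  The mechanical
index is MI = p_neg/√f with the peak negative pressure in MPa and the
frequency in MHz; in the linear approximation the peak negative pressure
equals the peak pressure, which is the convention used here (FDA safety
margin: MI ≤ 1.9).

Defaults for the fluid are water near room temperature, ρ = 998 kg m⁻³ and
c = 1482 m s⁻¹; MI values rounded to one decimal are insensitive to the
exact temperature in the 20–37 °C range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

WATER_DENSITY = 998.0  # kg m⁻³ (20 °C)
WATER_SPEED_OF_SOUND = 1482.0  # m s⁻¹ (20 °C)

PRESSURE_CONVENTIONS = ("rms", "peak")


@dataclass(frozen=True)
class SonicationSetting:
    """One sonication condition: frequency plus either intensity directly or
    the energy/on-time/probe-radius triple it derives from."""

    frequency_mhz: float
    intensity_w_cm2: Optional[float] = None
    spent_energy_j: Optional[float] = None
    on_time_s: Optional[float] = None
    probe_radius_mm: Optional[float] = None
    duty_on_s: float = 2.0
    duty_off_s: float = 1.0
    density: float = WATER_DENSITY
    speed_of_sound: float = WATER_SPEED_OF_SOUND

    def __post_init__(self):
        if self.frequency_mhz <= 0:
            raise ValueError("frequency must be positive")
        if self.duty_on_s < 0 or self.duty_off_s < 0:
            raise ValueError("duty-cycle times must be non-negative")
        if self.density <= 0 or self.speed_of_sound <= 0:
            raise ValueError("fluid density and speed of sound must be positive")
        if self.intensity_w_cm2 is None:
            missing = [n for n, v in (("spent_energy_j", self.spent_energy_j),
                                      ("on_time_s", self.on_time_s),
                                      ("probe_radius_mm", self.probe_radius_mm))
                       if v is None]
            if missing:
                raise ValueError(
                    f"need intensity_w_cm2 or spent energy/on-time/radius; missing {missing}"
                )

    def intensity(self) -> float:
        """Intensity in W cm⁻² (given, or derived from energy/time/radius)."""
        if self.intensity_w_cm2 is not None:
            return float(self.intensity_w_cm2)
        return intensity_from_power(self.spent_energy_j, self.on_time_s,
                                    self.probe_radius_mm)

    def mechanical_index(self) -> float:
        p = pressure_from_intensity(self.intensity(), self.density,
                                    self.speed_of_sound, convention="peak")
        return mechanical_index(p, self.frequency_mhz)


def intensity_from_power(spent_energy_j: float, on_time_s: float,
                         probe_radius_mm: float) -> float:
    """I = (E/t_on)/(πr²) in W cm⁻²."""
    if on_time_s <= 0:
        raise ValueError(f"on-time must be positive, got {on_time_s}")
    if probe_radius_mm <= 0:
        raise ValueError(f"probe radius must be positive, got {probe_radius_mm}")
    if spent_energy_j < 0:
        raise ValueError(f"spent energy must be non-negative, got {spent_energy_j}")
    power_w = spent_energy_j / on_time_s
    area_cm2 = math.pi * (probe_radius_mm / 10.0) ** 2
    return power_w / area_cm2


def pressure_from_intensity(intensity_w_cm2: float,
                            density: float = WATER_DENSITY,
                            speed_of_sound: float = WATER_SPEED_OF_SOUND,
                            convention: str = "peak") -> float:
    """Acoustic pressure in MPa from I = p²/ρc (linear approximation).

    ``rms`` returns p = sqrt(I·ρ·c); ``peak`` returns the sinusoidal peak,
    sqrt(2·I·ρ·c).
    """
    if convention not in PRESSURE_CONVENTIONS:
        raise ValueError(f"convention must be one of {PRESSURE_CONVENTIONS}, "
                         f"got {convention!r}")
    if intensity_w_cm2 < 0:
        raise ValueError(f"intensity must be non-negative, got {intensity_w_cm2}")
    i_si = intensity_w_cm2 * 1e4  # W m⁻²
    p_pa = math.sqrt(i_si * density * speed_of_sound)
    if convention == "peak":
        p_pa *= math.sqrt(2.0)
    return p_pa / 1e6


def intensity_from_pressure(pressure_mpa: float,
                            density: float = WATER_DENSITY,
                            speed_of_sound: float = WATER_SPEED_OF_SOUND,
                            convention: str = "peak") -> float:
    """Inverse of :func:`pressure_from_intensity` (W cm⁻²)."""
    if convention not in PRESSURE_CONVENTIONS:
        raise ValueError(f"convention must be one of {PRESSURE_CONVENTIONS}, "
                         f"got {convention!r}")
    p_pa = pressure_mpa * 1e6
    i_si = p_pa**2 / (density * speed_of_sound)
    if convention == "peak":
        i_si /= 2.0
    return i_si / 1e4


def mechanical_index(p_peak_negative_mpa: float, frequency_mhz: float) -> float:
    """MI = p⁻ (MPa) / sqrt(f (MHz)) — the FDA cavitation-safety metric."""
    if frequency_mhz <= 0:
        raise ValueError(f"frequency must be positive, got {frequency_mhz}")
    if p_peak_negative_mpa < 0:
        raise ValueError("peak negative pressure magnitude must be non-negative")
    return p_peak_negative_mpa / math.sqrt(frequency_mhz)


def mechanical_index_from_intensity(intensity_w_cm2: float, frequency_mhz: float,
                                    density: float = WATER_DENSITY,
                                    speed_of_sound: float = WATER_SPEED_OF_SOUND) -> float:
    """MI from intensity via the peak-pressure linear approximation."""
    p = pressure_from_intensity(intensity_w_cm2, density, speed_of_sound, "peak")
    return mechanical_index(p, frequency_mhz)


def duty_cycle_energy(total_time_s: float, on_s: float, off_s: float,
                      power_w: float):
    """(on-time, spent energy) for pulsed sonication, e.g. 2 s on / 1 s off.

    on-fraction = on/(on+off); spent energy = P · total_time · on-fraction.
    """
    if on_s < 0 or off_s < 0 or total_time_s < 0:
        raise ValueError("times must be non-negative")
    if on_s + off_s <= 0:
        raise ValueError("duty cycle needs on_s + off_s > 0")
    on_fraction = on_s / (on_s + off_s)
    on_time = total_time_s * on_fraction
    return on_time, power_w * on_time
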