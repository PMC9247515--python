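"""Thermodynamic parameterizations for heterogeneous ice nucleation.

All quantities are SI (K, m, J). The classical-nucleation-theory layer
(:mod:`inproice.cnt`) consumes a :class:`ThermoParams` bundle holding the
temperature-dependent properties of supercooled water and ice:

* ``saturation_ratio`` -- S12(T), the ratio of the saturation vapour pressure
  of supercooled liquid water to that of ice.  S12 > 1 below 0 degC and is the
  thermodynamic driving force for freezing.
* ``ice_molecular_volume`` -- v_ice(T), the volume per H2O molecule in ice Ih.
* ``sigma_ice_water`` -- sigma12(T), the ice/supercooled-water interfacial
  free energy.
* ``sigma_ice_template`` (sigma23), ``line_tension`` (tau123) and
  ``contact_angle`` (theta) describe the ice/template interface for the cuboid
  and spherical-cap cluster geometries.

The default parameterizations are standard literature fits: Murphy & Koop
(2005) saturation vapour pressures over liquid water and ice, an ice-density
polynomial of the Pruppacher & Klett type, and a linear fit for the ice-water
interfacial energy.  Every component is injectable, so tests and users can
substitute fixed synthetic values or alternative fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

__all__ = [
    "BOLTZMANN_CONSTANT",
    "AVOGADRO_CONSTANT",
    "T_MELT_K",
    "ThermoParams",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "saturation_pressure_liquid",
    "saturation_pressure_ice",
    "default_saturation_ratio",
    "default_ice_molecular_volume",
    "default_sigma_ice_water",
]

BOLTZMANN_CONSTANT = 1.38065e-23  # J/K
AVOGADRO_CONSTANT = 6.02214076e23  # 1/mol
T_MELT_K = 273.15
_WATER_MOLAR_MASS = 18.015  # g/mol


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15


def saturation_pressure_liquid(T: float) -> float:
    """Saturation vapour pressure over supercooled liquid water (Pa).

    Murphy & Koop (2005), valid 123 K < T < 332 K.
    """
    return math.exp(
        54.842763
        - 6763.22 / T
        - 4.210 * math.log(T)
        + 0.000367 * T
        + math.tanh(0.0415 * (T - 218.8))
        * (53.878 - 1331.22 / T - 9.44523 * math.log(T) + 0.014025 * T)
    )


def saturation_pressure_ice(T: float) -> float:
    """Saturation vapour pressure over hexagonal ice (Pa). Murphy & Koop (2005)."""
    return math.exp(
        9.550426 - 5723.265 / T + 3.53068 * math.log(T) - 0.00728332 * T
    )


def default_saturation_ratio(T: float) -> float:
    """S12(T) = p_liquid(T) / p_ice(T); > 1 for supercooled water."""
    return saturation_pressure_liquid(T) / saturation_pressure_ice(T)


def default_ice_molecular_volume(T: float) -> float:
    """Volume per molecule of ice Ih (m^3), from an ice-density polynomial.

    rho_ice(t) = 0.9167 - 1.75e-4 t - 5.0e-7 t^2  [g/cm^3], t in degC
    (Pruppacher & Klett fit). v_ice ~ 3.2e-29 m^3 throughout the supercooled
    range.
    """
    t = kelvin_to_celsius(T)
    rho = 0.9167 - 1.75e-4 * t - 5.0e-7 * t * t  # g/cm^3
    v_cm3 = _WATER_MOLAR_MASS / (rho * AVOGADRO_CONSTANT)
    return v_cm3 * 1e-6


def default_sigma_ice_water(T: float) -> float:
    """Ice/supercooled-water interfacial free energy (J/m^2).

    Linear fit sigma12 = 28.0 + 0.25 (T - 273.15) mJ/m^2, anchored near the
    commonly used ~28 mJ/m^2 at the melting point and decreasing with
    supercooling.
    """
    return (28.0 + 0.25 * (T - T_MELT_K)) * 1e-3


@dataclass(frozen=True)
class ThermoParams:
    """Bundle of thermodynamic inputs for the CNT cluster models.

    Parameters
    ----------
    saturation_ratio, ice_molecular_volume, sigma_ice_water
        Callables of absolute temperature (K).
    sigma_ice_template
        sigma23, the ice/template interfacial free energy (J/m^2); constant.
    line_tension
        tau123, the three-phase line tension (J/m); constant.
    contact_angle
        theta (radians) for the spherical-cap geometry.
    t_min_k, t_max_k
        Supported temperature range of the parameterization.
    """

    saturation_ratio: Callable[[float], float] = default_saturation_ratio
    ice_molecular_volume: Callable[[float], float] = default_ice_molecular_volume
    sigma_ice_water: Callable[[float], float] = default_sigma_ice_water
    sigma_ice_template: float = 0.0
    line_tension: float = 0.0
    contact_angle: float = math.pi / 2
    t_min_k: float = 233.15
    t_max_k: float = 273.14
    boltzmann_constant: float = BOLTZMANN_CONSTANT

    def __post_init__(self) -> None:
        if not (0.0 < self.contact_angle <= math.pi):
            raise ValueError(
                f"contact_angle must be in (0, pi], got {self.contact_angle}"
            )
        if self.t_min_k >= self.t_max_k:
            raise ValueError("t_min_k must be below t_max_k")

    def check_temperature(self, T: float) -> None:
        if not (self.t_min_k <= T <= self.t_max_k):
            raise ValueError(
                f"temperature {T} K outside the supported parameterization "
                f"range [{self.t_min_k} K, {self.t_max_k} K]"
            )

    def with_overrides(self, **kwargs) -> "ThermoParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def default(cls) -> "ThermoParams":
        return cls()

    @classmethod
    def constant(
        cls,
        s12: float,
        v_ice: float,
        sigma12: float,
        sigma23: float = 0.0,
        tau123: float = 0.0,
        contact_angle: float = math.pi / 2,
        t_min_k: float = 233.15,
        t_max_k: float = 273.14,
    ) -> "ThermoParams":
        """Fixed-value parameterization, mainly for tests and hand checks."""
        return cls(
            saturation_ratio=lambda T: s12,
            ice_molecular_volume=lambda T: v_ice,
            sigma_ice_water=lambda T: sigma12,
            sigma_ice_template=sigma23,
            line_tension=tau123,
            contact_angle=contact_angle,
            t_min_k=t_min_k,
            t_max_k=t_max_k,
        )
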