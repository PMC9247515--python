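"""Classical nucleation theory for cuboid ice clusters on elongated templates.

Bacterial ice-nucleation proteins present a long, narrow template to
supercooled water.  This module implements a geometric (critical-size) CNT
description of an ice cluster with cuboid shape -- axes ``a`` (length, along
the protein's longitudinal axis), ``b`` (width, fixed by the protein/oligomer)
and ``c`` (height) -- together with the classical spherical-cap model used as
a baseline.

The Gibbs free energy of forming a cuboid cluster (phase 2 = ice) from
supercooled water (1) on a template (3) is

    dG = a b c dG_V + sigma12 (2ac + 2bc + ab) + sigma23 ab
         + 2 b tau123 + 2 a tau123

with dG_V(T) = -k T / v_ice(T) * ln S12(T) the volumetric free-energy gain
(negative below 0 degC).  Setting the partial derivatives to zero at fixed
width b gives the critical length and height

    a_crit = -2 b sigma12 / (dG_V b + 2 sigma12)
    c_crit = -(b (sigma12 + sigma23) + 2 tau123) / (dG_V b + 2 sigma12)

which are finite and positive only when b exceeds the spherical critical
radius r_crit = -2 sigma12 / dG_V; a template narrower than r_crit cannot
host a critical cuboid cluster at that temperature (infeasible state, which
is returned, not raised -- characteristic-length curves legitimately
terminate).  a_crit is the model's characteristic length: it sets the
template length needed to nucleate at a given temperature, and its inverse
function maps a construct's length to a predicted characteristic freezing
temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy.optimize import bisect

from .thermo import ThermoParams, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "CuboidCluster",
    "CriticalLengthResult",
    "InversionResult",
    "volumetric_free_energy",
    "cuboid_free_energy",
    "critical_length_cuboid",
    "critical_height_cuboid",
    "critical_radius_cap",
    "char_length_cap",
    "char_temperature_from_length",
]


@dataclass(frozen=True)
class CuboidCluster:
    """Cuboid ice cluster; ``a`` longest axis, ``b`` width, ``c`` height (m)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("cluster axes must be non-negative")


@dataclass(frozen=True)
class CriticalLengthResult:
    """Critical cuboid length at (T, b); infeasible when b <= r_crit(T)."""

    temperature_k: float
    width_b: float
    a_crit: Optional[float]
    feasible: bool


@dataclass(frozen=True)
class InversionResult:
    """Solution of characteristic-length = target for temperature."""

    temperature_k: Optional[float]
    feasible: bool
    attainable_range: tuple[float, float]

    @property
    def temperature_c(self) -> Optional[float]:
        if self.temperature_k is None:
            return None
        return kelvin_to_celsius(self.temperature_k)


def volumetric_free_energy(T: float, params: ThermoParams) -> float:
    """dG_V(T) = -k T / v_ice(T) * ln S12(T)  [J/m^3]; negative when S12 > 1."""
    params.check_temperature(T)
    s12 = params.saturation_ratio(T)
    v_ice = params.ice_molecular_volume(T)
    if v_ice <= 0:
        raise ValueError(f"ice molecular volume must be positive, got {v_ice}")
    return -params.boltzmann_constant * T / v_ice * math.log(s12)


def cuboid_free_energy(cluster: CuboidCluster, T: float, params: ThermoParams) -> float:
    """Gibbs free energy (J) of a cuboid ice cluster on the template."""
    dgv = volumetric_free_energy(T, params)
    s12 = params.sigma_ice_water(T)
    s23 = params.sigma_ice_template
    tau = params.line_tension
    a, b, c = cluster.a, cluster.b, cluster.c
    return (
        a * b * c * dgv
        + s12 * (2 * a * c + 2 * b * c + a * b)
        + s23 * a * b
        + 2 * b * tau
        + 2 * a * tau
    )


def _denominator(T: float, b: float, params: ThermoParams) -> float:
    return volumetric_free_energy(T, params) * b + 2.0 * params.sigma_ice_water(T)


def critical_length_cuboid(T: float, b: float, params: ThermoParams) -> CriticalLengthResult:
    """Critical cuboid length a_crit at temperature T and fixed width b."""
    if b <= 0:
        raise ValueError(f"width b must be positive, got {b}")
    denom = _denominator(T, b, params)
    if denom >= 0:
        # b <= r_crit(T): no finite critical length, template too narrow.
        return CriticalLengthResult(T, b, None, False)
    a_crit = -2.0 * b * params.sigma_ice_water(T) / denom
    return CriticalLengthResult(T, b, a_crit, True)


def critical_height_cuboid(T: float, b: float, params: ThermoParams) -> Optional[float]:
    """Critical cuboid height c_crit; None when infeasible (b <= r_crit)."""
    if b <= 0:
        raise ValueError(f"width b must be positive, got {b}")
    denom = _denominator(T, b, params)
    if denom >= 0:
        return None
    s12 = params.sigma_ice_water(T)
    return -(b * (s12 + params.sigma_ice_template) + 2.0 * params.line_tension) / denom


def critical_radius_cap(T: float, params: ThermoParams) -> Optional[float]:
    """Spherical-cap critical radius r_crit = -2 sigma12 / dG_V; None at/above melting."""
    dgv = volumetric_free_energy(T, params)
    if dgv >= 0:
        return None
    return -2.0 * params.sigma_ice_water(T) / dgv


def char_length_cap(T: float, params: ThermoParams) -> Optional[float]:
    """Characteristic interface length of the spherical cap, r_crit * sin(theta)."""
    r = critical_radius_cap(T, params)
    if r is None:
        return None
    return r * math.sin(params.contact_angle)


def _char_length(T: float, b: Optional[float], params: ThermoParams, model: str) -> Optional[float]:
    if model == "cuboid":
        if b is None:
            raise ValueError("cuboid model requires a width b")
        res = critical_length_cuboid(T, b, params)
        return res.a_crit if res.feasible else None
    if model == "cap":
        return char_length_cap(T, params)
    raise ValueError(f"unknown model {model!r}; expected 'cuboid' or 'cap'")


def char_temperature_from_length(
    length: float,
    b: Optional[float] = None,
    params: Optional[ThermoParams] = None,
    model: Literal["cuboid", "cap"] = "cuboid",
    tol_k: float = 0.01,
) -> InversionResult:
    """Invert the characteristic-length curve: temperature at which the
    critical length equals ``length`` (m).

    The characteristic length grows monotonically with temperature for both
    geometries (warmer = larger critical cluster), so the solution, when it
    exists inside the parameterization's range, is unique and found by
    bisection to ``tol_k``.  When no solution exists the result carries the
    attainable length range at this width.
    """
    if params is None:
        params = ThermoParams.default()
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    t_lo = params.t_min_k
    t_hi = params.t_max_k

    # Upper end of the feasible temperature window (cuboid: b > r_crit(T)).
    def feasible_at(T: float) -> bool:
        return _char_length(T, b, params, model) is not None

    if not feasible_at(t_lo):
        return InversionResult(None, False, (math.nan, math.nan))
    if not feasible_at(t_hi):
        # bracket the feasibility boundary, stay strictly below it
        lo, hi = t_lo, t_hi
        while hi - lo > 1e-6:
            mid = 0.5 * (lo + hi)
            if feasible_at(mid):
                lo = mid
            else:
                hi = mid
        t_hi = lo
    l_lo = _char_length(t_lo, b, params, model)
    l_hi = _char_length(t_hi, b, params, model)
    assert l_lo is not None and l_hi is not None
    if length < l_lo or length > l_hi:
        return InversionResult(None, False, (l_lo, l_hi))

    def g(T: float) -> float:
        val = _char_length(T, b, params, model)
        assert val is not None
        return val - length

    if g(t_lo) == 0.0:
        return InversionResult(t_lo, True, (l_lo, l_hi))
    root = bisect(g, t_lo, t_hi, xtol=min(tol_k, 0.01) / 2.0)
    return InversionResult(float(root), True, (l_lo, l_hi))


def char_length_curve(
    b_nm: Optional[float],
    t_min_c: float,
    t_max_c: float,
    step_c: float = 0.1,
    params: Optional[ThermoParams] = None,
    model: Literal["cuboid", "cap"] = "cuboid",
):
    """Characteristic length (nm) vs temperature (degC) table.

    Returns a list of (temperature_C, char_length_nm or None, feasible)
    tuples, the curve behind the length-temperature comparison of cuboid and
    spherical-cap geometries.
    """
    if params is None:
        params = ThermoParams.default()
    rows = []
    n = int(round((t_max_c - t_min_c) / step_c))
    for i in range(n + 1):
        t_c = t_min_c + i * step_c
        t_k = celsius_to_kelvin(t_c)
        if not (params.t_min_k <= t_k <= params.t_max_k):
            continue
        b_m = None if b_nm is None else b_nm * 1e-9
        val = _char_length(t_k, b_m, params, model)
        rows.append((t_c, None if val is None else val * 1e9, val is not None))
    return rows
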