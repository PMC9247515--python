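"""Construct geometry: from repeat counts to template dimensions and
CNT-predicted characteristic nucleation temperatures.

The central repeat domain (CRD) of an ice-nucleation protein is a linear
stack of 16-residue repeats, so its longitudinal axis length grows linearly
with the repeat count.  A through-origin least-squares fit of measured
(repeat count, length) pairs gives the per-repeat rise; combined with the
transverse width of the relevant oligomer (monomer 2.3 nm, dimer 5.5 nm)
the cuboid CNT model maps each construct to a predicted characteristic
nucleation temperature via the inverse of the critical-length curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnt import InversionResult, char_temperature_from_length
from .thermo import ThermoParams

__all__ = [
    "Construct",
    "OligomerState",
    "MONOMER",
    "DIMER",
    "R10_79_CONSTRUCTS",
    "fit_rise_per_repeat",
    "crd_length",
    "predict_characteristic_temperature",
    "comparison_table",
]


@dataclass(frozen=True)
class Construct:
    """A truncated ice-nucleation protein construct."""

    name: str
    n_repeats: int
    has_n_terminal: bool = True
    has_c_terminal: bool = True
    measured_longitudinal_nm: Optional[float] = None
    measured_t_char50_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.measured_longitudinal_nm is not None and self.measured_longitudinal_nm <= 0:
            raise ValueError("measured length must be positive")


@dataclass(frozen=True)
class OligomerState:
    """Oligomeric state setting the transverse template width b."""

    state: str
    width_b_nm: float

    def __post_init__(self) -> None:
        if self.width_b_nm <= 0:
            raise ValueError("width must be positive")


MONOMER = OligomerState("monomer", 2.3)
DIMER = OligomerState("dimer", 5.5)

# Reference truncation series of the P. syringae R10.79 INpro: structural-model
# CRD lengths (nm) and measured characteristic nucleation temperatures (degC).
R10_79_CONSTRUCTS: tuple[Construct, ...] = (
    Construct("INpro-9R", 9, measured_longitudinal_nm=4.1, measured_t_char50_c=-23.7),
    Construct("INpro-16R", 16, measured_longitudinal_nm=7.3, measured_t_char50_c=-21.7),
    Construct("INpro-28R", 28, measured_longitudinal_nm=12.8, measured_t_char50_c=-15.8),
    Construct("INpro-67R", 67, measured_longitudinal_nm=30.6, measured_t_char50_c=-11.2),
)


def fit_rise_per_repeat(pairs: Sequence[tuple[float, float]]) -> float:
    """Through-origin least-squares rise (nm/repeat) from (n, length_nm) pairs.

    slope = sum(n * L) / sum(n^2); the intercept is pinned to zero because a
    zero-repeat CRD has zero length.
    """
    if not pairs:
        raise ValueError("need at least one (n_repeats, length) pair")
    n = np.array([p[0] for p in pairs], dtype=float)
    length = np.array([p[1] for p in pairs], dtype=float)
    if np.any(n <= 0) or np.any(length <= 0):
        raise ValueError("repeat counts and lengths must be positive")
    return float((n * length).sum() / (n * n).sum())


def crd_length(n_repeats: int, rise_nm_per_repeat: float) -> float:
    """Longitudinal CRD length (nm) of a linear repeat stack."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if rise_nm_per_repeat <= 0:
        raise ValueError("rise must be positive")
    return n_repeats * rise_nm_per_repeat


def predict_characteristic_temperature(
    construct: Construct,
    state: OligomerState,
    params: Optional[ThermoParams] = None,
    rise_nm_per_repeat: Optional[float] = None,
    tol_k: float = 0.01,
) -> InversionResult:
    """Predicted characteristic nucleation temperature of a construct.

    The construct's longitudinal length (measured, or repeat count x rise)
    is equated with the critical cuboid length at the oligomer's width; the
    unique temperature solving that equation is the prediction.  An
    infeasible result means no critical cluster of that length exists in the
    supported temperature range (e.g. monomer widths below the critical
    radius at warm temperatures).
    """
    if construct.measured_longitudinal_nm is not None:
        length_nm = construct.measured_longitudinal_nm
    elif rise_nm_per_repeat is not None:
        length_nm = crd_length(construct.n_repeats, rise_nm_per_repeat)
    else:
        raise ValueError(
            "construct has no measured length; supply rise_nm_per_repeat"
        )
    return char_temperature_from_length(
        length_nm * 1e-9,
        b=state.width_b_nm * 1e-9,
        params=params,
        model="cuboid",
        tol_k=tol_k,
    )


def comparison_table(
    constructs: Sequence[Construct] = R10_79_CONSTRUCTS,
    state: OligomerState = DIMER,
    params: Optional[ThermoParams] = None,
) -> pd.DataFrame:
    """Predicted vs measured characteristic temperatures for a construct set.

    No thermodynamic parameter is fitted to the measurements; the table is a
    consistency check of the cuboid model at the given oligomer width.
    """
    rows = []
    for c in constructs:
        res = predict_characteristic_temperature(c, state, params)
        rows.append(
            {
                "construct": c.name,
                "n_repeats": c.n_repeats,
                "length_nm": c.measured_longitudinal_nm,
                "width_nm": state.width_b_nm,
                "t_pred_c": res.temperature_c,
                "feasible": res.feasible,
                "t_measured_c": c.measured_t_char50_c,
            }
        )
    return pd.DataFrame(rows)
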