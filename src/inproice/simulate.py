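"""Synthetic droplet-freezing assays with Poisson-loaded nucleator molecules.

The generator emulates two immersion-freezing instruments:

* a microfluidic array of ~0.5 nL (100 um) droplets scanned down to the
  homogeneous-freezing limit, measured over a serial 10x/100x dilution
  series, and
* a cold-stage array of 90 x 1 uL droplets for rare, warm-active nucleators.

The freezing model is singular (time-independent): every active molecule
carries a fixed characteristic activation temperature drawn from a narrow
Gaussian for its population, and a droplet freezes at the warmest activation
temperature among its molecules (or at a homogeneous-freezing draw near
-37 degC).  Molecule counts per droplet are Poisson with mean
lambda = c_m V N_A / M; a molecule is active for population s with
probability p_active(s), the plateau Nn level of that population.

Sampling detail: the number of active molecules of population s in a droplet
is Poisson(lambda * p_s) (Poisson thinning), and the maximum of k Gaussian
activation draws is sampled in O(1) through the inverse CDF of the maximum,
mu + sigma * Phi^-1(u^(1/k)).  This is distributionally identical to drawing
every molecule individually but remains fast at realistic loadings
(lambda ~ 1e10 molecules per droplet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .spectra import AssayConditions, FreezingAssay
from .thermo import AVOGADRO_CONSTANT

__all__ = [
    "INproSpecies",
    "SimConfig",
    "simulate_assay",
    "expected_frozen_fraction",
    "make_dilution_series",
]

_LAMBDA_GUARD = 1e12


@dataclass(frozen=True)
class INproSpecies:
    """One nucleator population (e.g. dimers = class C, oligomers = class A).

    ``p_active`` is the probability that a protein molecule belongs to this
    population *and* is active -- it equals the population's plateau Nn per
    molecule.  Activation temperatures are Normal(mean_activation_t_c,
    spread_k).
    """

    label: str
    mean_activation_t_c: float
    spread_k: float
    p_active: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_active <= 1.0):
            raise ValueError(f"p_active must be in [0, 1], got {self.p_active}")
        if self.spread_k <= 0:
            raise ValueError(f"spread must be positive, got {self.spread_k}")
        if not (-38.0 < self.mean_activation_t_c < 0.0):
            raise ValueError(
                f"mean activation temperature must lie in (-38, 0) degC, "
                f"got {self.mean_activation_t_c}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Assay conditions and scan parameters for the generator.

    Defaults describe a cold-stage (1 uL droplet) run; the classmethods
    build the two instrument archetypes.  ``replicates`` repeats each
    dilution with independent child seeds, emulating repeated analyses of
    the same concentration.
    """

    n_droplets: int = 90
    droplet_volume_l: float = 1e-6
    c_m: float = 1e-2
    molar_mass: float = 1.2e5
    dilution_factors: tuple[float, ...] = (1.0,)
    t_min_c: float = -40.0
    t_max_c: float = -0.5
    homog_mean_c: float = -37.0
    homog_spread_k: float = 1.0
    temperature_resolution_k: float = 0.1
    replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("need at least one droplet")
        if self.droplet_volume_l <= 0 or self.c_m <= 0 or self.molar_mass <= 0:
            raise ValueError("volume, concentration and molar mass must be positive")
        if self.t_min_c >= self.t_max_c:
            raise ValueError("t_min_c must be below t_max_c")
        if any(f < 1 for f in self.dilution_factors):
            raise ValueError("dilution factors must be >= 1")

    def molecules_per_droplet(self, dilution_factor: float = 1.0) -> float:
        return (
            self.c_m
            / dilution_factor
            * self.droplet_volume_l
            * AVOGADRO_CONSTANT
            / self.molar_mass
        )

    @classmethod
    def microfluidic(cls, **kwargs) -> "SimConfig":
        """~0.5 nL (100 um diameter) droplets, deep-supercooling scan."""
        defaults = dict(
            n_droplets=300,
            droplet_volume_l=math.pi / 6 * (1e-4) ** 3 * 1e3,  # 100 um sphere, L
            c_m=9.5e-3,
            molar_mass=6.0e4,
            dilution_factors=(1.0, 10.0, 100.0),
            t_min_c=-40.0,
            t_max_c=-0.5,
            replicates=3,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    @classmethod
    def microliter(cls, **kwargs) -> "SimConfig":
        """90 x 1 uL droplets on a cold stage; detects rare warm nucleators."""
        defaults = dict(
            n_droplets=90,
            droplet_volume_l=1e-6,
            c_m=1e-2,
            molar_mass=1.2e5,
            dilution_factors=(1.0, 10.0, 100.0),
            t_min_c=-25.0,
            t_max_c=-0.5,
            replicates=3,
        )
        defaults.update(kwargs)
        return cls(**defaults)


def _child_rng(config: SimConfig, dilution_index: int, replicate: int) -> np.random.Generator:
    seq = np.random.SeedSequence(
        entropy=int(config.rng_seed), spawn_key=(dilution_index, replicate)
    )
    return np.random.default_rng(seq)


def _max_of_normals(
    rng: np.random.Generator, k: np.ndarray, mu: float, sigma: float
) -> np.ndarray:
    """Sample max of k iid Normal(mu, sigma) draws per entry; -inf where k=0.

    Uses inverse-CDF sampling of the maximum: max = mu + sigma*Phi^-1(u^(1/k)).
    """
    out = np.full(k.shape, -np.inf)
    pos = k > 0
    if pos.any():
        u = rng.random(int(pos.sum()))
        # u**(1/k) via exp(log(u)/k) for numerical stability at large k
        q = np.exp(np.log(u) / k[pos])
        out[pos] = mu + sigma * ndtri(q)
    return out


def simulate_assay(
    species: Sequence[INproSpecies],
    config: SimConfig,
    dilution_factor: float = 1.0,
    dilution_index: int = 0,
    replicate: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> FreezingAssay:
    """Simulate one cooling scan and return the resulting event table.

    Each droplet's freezing temperature is the maximum of the activation
    draws of all its active molecules and one homogeneous-freezing draw;
    droplets whose maximum falls below the scanned range are recorded as
    unfrozen, and reported temperatures are rounded to the instrument's
    temperature resolution.  Deterministic given (rng_seed, dilution_index,
    replicate).
    """
    lam = config.molecules_per_droplet(dilution_factor)
    if lam > _LAMBDA_GUARD:
        raise ValueError(
            f"expected molecule count per droplet {lam:.3g} exceeds {_LAMBDA_GUARD:.0e}; "
            "dilute the sample"
        )
    if rng is None:
        rng = _child_rng(config, dilution_index, replicate)
    n = config.n_droplets
    freeze_t = rng.normal(config.homog_mean_c, config.homog_spread_k, size=n)
    for s in species:
        k = rng.poisson(lam * s.p_active, size=n)
        t_s = _max_of_normals(rng, k, s.mean_activation_t_c, s.spread_k)
        freeze_t = np.maximum(freeze_t, t_s)
    freeze_t = np.minimum(freeze_t, config.t_max_c)
    res = config.temperature_resolution_k
    if res > 0:
        freeze_t = np.round(freeze_t / res) * res
    frozen = freeze_t >= config.t_min_c
    conditions = AssayConditions(
        c_m=config.c_m,
        droplet_volume_l=config.droplet_volume_l,
        molar_mass=config.molar_mass,
        dilution_factor=dilution_factor,
    )
    return FreezingAssay(
        conditions=conditions,
        freezing_temperatures_c=freeze_t[frozen],
        n_unfrozen=int((~frozen).sum()),
        instrument="synthetic",
    )


def expected_frozen_fraction(
    species: Sequence[INproSpecies],
    config: SimConfig,
    t_c,
    dilution_factor: float = 1.0,
):
    """Closed-form frozen fraction, ignoring the homogeneous background.

    f(T) = 1 - exp(-lambda * sum_s p_s * (1 - Phi((T - mu_s) / sigma_s))).
    Inverting through the Nn normalization returns the per-molecule survival
    sum exactly, which makes this the analytic oracle for the pipeline.
    """
    t = np.asarray(t_c, dtype=float)
    lam = config.molecules_per_droplet(dilution_factor)
    total = np.zeros_like(t)
    for s in species:
        total += s.p_active * (1.0 - ndtr((t - s.mean_activation_t_c) / s.spread_k))
    out = 1.0 - np.exp(-lam * total)
    return float(out) if np.isscalar(t_c) else out


def make_dilution_series(
    species: Sequence[INproSpecies],
    config: SimConfig,
    factors: Optional[Sequence[float]] = None,
) -> list[FreezingAssay]:
    """One assay per (dilution factor, replicate), with independent child seeds.

    Emulates serially diluting the stock by 10x or 100x after each analysis
    to extend the observable temperature range of the spectrum.
    """
    if factors is None:
        factors = config.dilution_factors
    factors = list(factors)
    if any(f < 1 for f in factors):
        raise ValueError("dilution factors must be >= 1")
    if sorted(factors) != factors:
        raise ValueError("dilution factors must be sorted ascending")
    assays = []
    for i, f in enumerate(factors):
        for r in range(config.replicates):
            assays.append(
                simulate_assay(species, config, dilution_factor=f, dilution_index=i, replicate=r)
            )
    return assays
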