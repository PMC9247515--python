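"""Droplet-freezing spectra: frozen fractions, per-molecule site densities,
knee points and characteristic nucleation temperatures.

An immersion-freezing assay cools an array of droplets containing a known
mass concentration of protein and records each droplet's freezing
temperature.  The cumulative frozen fraction f_ice(T) is converted to the
ice-nucleation site density per molecule

    Nn(T) = -ln(1 - f_ice(T)) * M / (c_m V_liquid N_A)

i.e. the Poisson-corrected number of freezing events per protein molecule,
which is independent of concentration and droplet volume.  Spectra from a
dilution series are pooled, averaged as log10 Nn in fixed temperature bins,
and characterized by

* the knee point -- the curvature maximum of the binned log-spectrum,
  located with the Kneedle algorithm; its Nn is read as the total number of
  active molecules per molecule (the plateau level) of a freezing mode;
* T_char,50 -- the temperature at which Nn reaches 50 % of the knee-point
  value, used as the characteristic nucleation temperature of the mode;
* activity classes -- two steep rises separated by a plateau indicate two
  nucleator populations (class A, warm and rare; class C, colder and more
  abundant), each characterized separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .thermo import AVOGADRO_CONSTANT

__all__ = [
    "AssayConditions",
    "FreezingAssay",
    "NucleationSpectrum",
    "BinnedSpectrum",
    "KneeConfig",
    "CharacterizationResult",
    "frozen_fraction_curve",
    "nn_per_molecule",
    "spectrum_from_assay",
    "merge_and_bin",
    "kneedle_difference_curve",
    "find_knee",
    "t_char_50",
    "detect_activity_classes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayConditions:
    """Assay-level quantities entering the Nn normalization.

    ``c_m`` is the stock mass concentration (g/L); the concentration in the
    droplets is ``c_m / dilution_factor``.  ``molar_mass`` is the molar mass
    of the protein construct (g/mol), ``droplet_volume_l`` the droplet volume
    in litres.
    """

    c_m: float
    droplet_volume_l: float
    molar_mass: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError(f"c_m must be positive, got {self.c_m}")
        if self.droplet_volume_l <= 0:
            raise ValueError(f"droplet volume must be positive, got {self.droplet_volume_l}")
        if self.molar_mass <= 0:
            raise ValueError(f"molar mass must be positive, got {self.molar_mass}")
        if self.dilution_factor < 1:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution_factor}")

    @property
    def molecules_per_droplet(self) -> float:
        """Expected protein molecules per droplet, lambda = c_m V N_A / M."""
        return (
            self.c_m
            / self.dilution_factor
            * self.droplet_volume_l
            * AVOGADRO_CONSTANT
            / self.molar_mass
        )


@dataclass
class FreezingAssay:
    """Per-droplet freezing events from one cooling scan.

    ``freezing_temperatures_c`` holds one entry per frozen droplet (degC);
    droplets that never froze in the scanned range are only counted.
    """

    conditions: AssayConditions
    freezing_temperatures_c: np.ndarray
    n_unfrozen: int = 0
    instrument: str = ""

    def __post_init__(self) -> None:
        self.freezing_temperatures_c = np.asarray(self.freezing_temperatures_c, dtype=float)
        if self.total_droplets <= 0:
            raise ValueError("assay must contain at least one droplet")
        t = self.freezing_temperatures_c
        if t.size and (t.min() <= -45.0 or t.max() >= 0.0):
            raise ValueError("freezing temperatures must lie within (-45, 0) degC")

    @property
    def total_droplets(self) -> int:
        return int(self.freezing_temperatures_c.size) + int(self.n_unfrozen)


@dataclass
class NucleationSpectrum:
    """(temperature, Nn per molecule) points, stored warm to cold."""

    temperature_c: np.ndarray
    nn: np.ndarray
    dilution_factors: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.temperature_c = np.asarray(self.temperature_c, dtype=float)
        self.nn = np.asarray(self.nn, dtype=float)
        if self.temperature_c.shape != self.nn.shape:
            raise ValueError("temperature and Nn arrays must have equal length")
        if np.any(np.diff(self.temperature_c) >= 0):
            raise ValueError("temperatures must be strictly decreasing")
        if np.any(self.nn < 0):
            raise ValueError("Nn must be non-negative")


@dataclass
class BinnedSpectrum:
    """Temperature-bin averaged log10 Nn, ordered warm to cold."""

    temperature_c: np.ndarray  # bin centres
    log10_nn: np.ndarray
    n_points: np.ndarray

    @property
    def nn(self) -> np.ndarray:
        return 10.0 ** self.log10_nn


@dataclass(frozen=True)
class KneeConfig:
    """Knobs for binning, knee detection and class segmentation.

    ``sensitivity`` is the Kneedle S parameter (1 throughout this package);
    ``bin_width_k`` the temperature bin width for log-averaging;
    ``plateau_slope`` the |d log10 Nn / dT| threshold (decades per K) below
    which adjacent bins count as plateau; a bin pair additionally needs a
    total rise of at least ``min_rise_decades`` to count as steep, so that
    sub-half-decade wiggles on a plateau are not mistaken for a freezing
    mode; ``homog_cutoff_c`` excludes bins at or below this temperature,
    where freezing is dominated by the homogeneous background near -38 degC
    rather than by the protein.
    """

    sensitivity: float = 1.0
    bin_width_k: float = 0.5
    min_points_per_bin: int = 1
    plateau_slope: float = 0.1
    min_rise_decades: float = 0.3
    homog_cutoff_c: float = -35.0

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.bin_width_k <= 0:
            raise ValueError("bin width must be positive")


@dataclass
class CharacterizationResult:
    """Knee point, plateau level and T_char,50 of one freezing mode."""

    t_knee_c: float
    nn_knee: float
    t_char50_c: float
    class_label: Optional[str] = None


def frozen_fraction_curve(assay: FreezingAssay, t_grid_c: Sequence[float]) -> np.ndarray:
    """Cumulative frozen fraction at each grid temperature.

    f_ice(T) = (# droplets frozen at or above T) / total droplets.
    """
    t_grid = np.asarray(t_grid_c, dtype=float)
    temps = assay.freezing_temperatures_c
    counts = np.array([(temps >= t).sum() for t in np.atleast_1d(t_grid)], dtype=float)
    return counts / assay.total_droplets


def nn_per_molecule(f_ice, conditions: AssayConditions):
    """Ice-nucleation site density per molecule, Nn = -ln(1-f_ice)/lambda.

    lambda = c_m V N_A / M is the expected molecule count per droplet.
    Accepts scalars or arrays; f_ice must lie in [0, 1).
    """
    f = np.asarray(f_ice, dtype=float)
    if np.any(f < 0) or np.any(f >= 1):
        raise ValueError("f_ice must lie in [0, 1); f_ice = 1 points are dropped upstream")
    out = -np.log1p(-f) / conditions.molecules_per_droplet
    return float(out) if np.isscalar(f_ice) else out


def spectrum_from_assay(assay: FreezingAssay) -> NucleationSpectrum:
    """Derive the Nn spectrum of a single assay.

    The spectrum is evaluated at each distinct observed freezing temperature
    with the cumulative frozen fraction reached there.  Fully frozen points
    (f_ice = 1) leave Nn undefined and are dropped with a log message.
    """
    temps = np.sort(assay.freezing_temperatures_c)[::-1]
    if temps.size == 0:
        raise ValueError("assay has no freezing events; cannot derive a spectrum")
    uniq, last_idx = [], {}
    for i, t in enumerate(temps):
        last_idx[t] = i  # keep the largest cumulative count per distinct temp
    uniq = sorted(last_idx, reverse=True)
    t_arr = np.array(uniq)
    f_arr = np.array([(last_idx[t] + 1) / assay.total_droplets for t in uniq])
    keep = f_arr < 1.0
    if not np.all(keep):
        logger.warning(
            "dropping %d fully-frozen point(s) (f_ice = 1, Nn undefined)",
            int((~keep).sum()),
        )
    t_arr, f_arr = t_arr[keep], f_arr[keep]
    if t_arr.size == 0:
        raise ValueError("all points have f_ice = 1; spectrum is empty")
    nn = nn_per_molecule(f_arr, assay.conditions)
    return NucleationSpectrum(t_arr, nn, (assay.conditions.dilution_factor,))


def merge_and_bin(
    spectra: Iterable[NucleationSpectrum], config: KneeConfig = KneeConfig()
) -> BinnedSpectrum:
    """Pool spectra from a dilution series and average log10 Nn in fixed bins.

    Bins form a fixed grid of width ``bin_width_k`` anchored at 0 degC; each
    bin reports the arithmetic mean of log10 Nn over all contributing points
    (binned log-averaging is the smoothing step ahead of knee detection).
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("need at least one spectrum")
    t_all = np.concatenate([s.temperature_c for s in spectra])
    nn_all = np.concatenate([s.nn for s in spectra])
    pos = nn_all > 0
    t_all, nn_all = t_all[pos], nn_all[pos]
    if t_all.size == 0:
        raise ValueError("no positive-Nn points to bin")
    w = config.bin_width_k
    idx = np.floor(-t_all / w).astype(int)  # bin k covers (-(k+1)w, -kw]
    order = {}
    for k in np.unique(idx):
        in_bin = idx == k
        if in_bin.sum() < config.min_points_per_bin:
            continue
        order[k] = (np.log10(nn_all[in_bin]).mean(), int(in_bin.sum()))
    if not order:
        raise ValueError("no bin satisfied min_points_per_bin")
    ks = sorted(order)  # increasing k = warm to cold
    centres = np.array([-(k + 0.5) * w for k in ks])
    means = np.array([order[k][0] for k in ks])
    counts = np.array([order[k][1] for k in ks])
    return BinnedSpectrum(centres, means, counts)


def kneedle_difference_curve(binned: BinnedSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Kneedle difference curve d = y_norm - x_norm.

    x = -T (so the curve increases left to right as it gets colder) and
    y = mean log10 Nn, both min-max normalized to [0, 1].
    """
    x = -binned.temperature_c
    y = binned.log10_nn
    if x.size < 2:
        raise ValueError("need at least 2 bins for a difference curve")
    x_n = (x - x.min()) / (x.max() - x.min())
    y_n = (y - y.min()) / (y.max() - y.min())
    return x_n, y_n - x_n


def _restrict(binned: BinnedSpectrum, config: KneeConfig) -> BinnedSpectrum:
    keep = binned.temperature_c > config.homog_cutoff_c
    if keep.sum() < 2:
        return binned
    return BinnedSpectrum(
        binned.temperature_c[keep], binned.log10_nn[keep], binned.n_points[keep]
    )


def find_knee(
    binned: BinnedSpectrum, config: KneeConfig = KneeConfig()
) -> Optional[tuple[float, float]]:
    """Kneedle knee point of the binned spectrum.

    Local maxima of the difference curve are knee candidates; a candidate at
    index i is accepted once d drops below the threshold d_i - S * mean(dx)
    before the next local maximum.  If no candidate is confirmed the global
    difference-curve maximum is used (logged).  Returns (T_knee_C, Nn_knee)
    or None when the curve has no interior local maximum.  Ties between
    equal-d neighbours break toward the warmer temperature.
    """
    binned = _restrict(binned, config)
    if binned.temperature_c.size < 5:
        logger.warning("knee detection on fewer than 5 bins is unreliable")
    if binned.temperature_c.size < 3:
        return None
    x_n, d = kneedle_difference_curve(binned)
    n = d.size
    if d.max() - d.min() < 1e-12:
        return None  # degenerate (straight-line) curve: no knee
    local_max = [
        i for i in range(1, n - 1) if d[i] > d[i - 1] and d[i] >= d[i + 1]
    ]
    if not local_max:
        return None
    mean_dx = float(np.mean(np.diff(x_n)))
    thresh_of = {i: d[i] - config.sensitivity * mean_dx for i in local_max}
    lm_set = set(local_max)
    for i in local_max:
        for j in range(i + 1, n):
            if j in lm_set and j != i:
                break  # reached the next candidate without confirmation
            if d[j] < thresh_of[i]:
                return float(binned.temperature_c[i]), float(binned.nn[i])
    i = int(np.argmax(d))
    logger.info("no Kneedle candidate confirmed; falling back to global maximum")
    return float(binned.temperature_c[i]), float(binned.nn[i])


def t_char_50(spectrum, knee: tuple[float, float]) -> float:
    """Characteristic nucleation temperature: Nn = 50 % of the knee value.

    Interpolates linearly in (T, log10 Nn) between the points bracketing the
    half-knee level on the warm side of the knee.  When the spectrum's
    warmest point already sits at or above the level (a step-like onset),
    that onset temperature is returned.
    """
    t_knee, nn_knee = knee
    if nn_knee <= 0:
        raise ValueError("knee Nn must be positive")
    if isinstance(spectrum, BinnedSpectrum):
        t, y = spectrum.temperature_c, spectrum.log10_nn
    else:
        pos = spectrum.nn > 0
        t, y = spectrum.temperature_c[pos], np.log10(spectrum.nn[pos])
    level = math.log10(0.5 * nn_knee)
    warm = t >= t_knee
    t_w, y_w = t[warm], y[warm]
    if t_w.size == 0:
        raise ValueError("no spectrum points at or warmer than the knee")
    # walk from the knee toward warmer temperatures to the first crossing
    order = np.argsort(t_w)  # cold -> warm
    t_s, y_s = t_w[order], y_w[order]
    below = np.where(y_s < level)[0]
    if below.size == 0:
        # entire warm side at/above the 50 % level: step-like onset
        return float(t_s[-1])
    j = below[0]  # first (coldest->warm walk) point below the level
    if j == 0:
        raise ValueError(
            "50 % level not bracketed: spectrum spans log10 Nn "
            f"[{y.min():.3g}, {y.max():.3g}], level {level:.3g}"
        )
    t_c, y_c = t_s[j - 1], y_s[j - 1]  # colder neighbour, above level
    t_wm, y_wm = t_s[j], y_s[j]  # warmer point, below level
    t50 = t_c + (level - y_c) * (t_wm - t_c) / (y_wm - y_c)
    return float(max(t50, t_knee))


def detect_activity_classes(
    binned: BinnedSpectrum, config: KneeConfig = KneeConfig()
) -> list[CharacterizationResult]:
    """Segment the binned spectrum into freezing modes and characterize each.

    Adjacent-bin pairs are steep when |d log10 Nn / dT| >=
    ``config.plateau_slope`` (decades/K) *and* the pair rises by at least
    ``config.min_rise_decades``; everything else is plateau.  Maximal steep
    runs each define a freezing mode consisting of the rise plus its
    trailing plateau.  Each mode gets a knee (Kneedle where the segment is
    long enough, otherwise the steep-to-plateau transition bin; for a final
    rise truncated by full-freezing saturation, the coldest bin -- the
    highest observed Nn of the mode) and a T_char,50.  With exactly two
    modes the warmer is labelled class A and the colder class C.  Without
    any plateau a single global-knee result is returned.
    """
    binned = _restrict(binned, config)
    t, y = binned.temperature_c, binned.log10_nn
    if t.size < 4:
        raise ValueError(f"need at least 4 bins for class detection, got {t.size}")
    if t.size < 8:
        logger.warning("class detection on %d bins (< 8) is unreliable", t.size)
    dT = t[:-1] - t[1:]  # positive (warm to cold)
    dy = y[1:] - y[:-1]
    slopes = dy / dT  # decades per K as it gets colder
    steep_pair = (np.abs(slopes) >= config.plateau_slope) & (
        np.abs(dy) >= config.min_rise_decades
    )

    def global_result() -> list[CharacterizationResult]:
        knee = find_knee(binned, config)
        if knee is None:
            raise ValueError("no knee found in spectrum")
        return [CharacterizationResult(knee[0], knee[1], t_char_50(binned, knee))]

    if not steep_pair.any() or steep_pair.all():
        return global_result()

    # maximal runs of steep pairs
    runs = []
    i = 0
    n_pairs = steep_pair.size
    while i < n_pairs:
        if steep_pair[i]:
            j = i
            while j + 1 < n_pairs and steep_pair[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    results: list[CharacterizationResult] = []
    for r, (i0, i1) in enumerate(runs):
        seg_start = i0  # first bin of the steep run
        seg_end = runs[r + 1][0] if r + 1 < len(runs) else t.size - 1
        seg = BinnedSpectrum(
            t[seg_start : seg_end + 1],
            y[seg_start : seg_end + 1],
            binned.n_points[seg_start : seg_end + 1],
        )
        if seg_end <= i1:
            # final rise truncated by saturation (f_ice -> 1 ends the data):
            # the coldest bin is the best available plateau estimate
            knee = (float(seg.temperature_c[-1]), float(seg.nn[-1]))
        else:
            knee = None
            if seg.temperature_c.size >= 5:
                knee = find_knee(seg, config)
            if knee is None:
                k = i1 + 1 - seg_start  # first plateau bin of the segment
                knee = (float(seg.temperature_c[k]), float(seg.nn[k]))
        results.append(CharacterizationResult(knee[0], knee[1], t_char_50(seg, knee)))
    if not results:
        return global_result()
    if len(results) == 2:
        results[0].class_label = "A"
        results[1].class_label = "C"
    return results
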