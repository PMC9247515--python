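# Methods

`inproice` links the size and oligomeric state of bacterial ice-nucleation
proteins (INpro) to the temperature at which they nucleate ice.  It has
four scientific layers — droplet-freezing spectrum statistics, a cuboid
classical-nucleation-theory (CNT) template model, construct geometry, and
repeat-consensus sequence analysis — plus a synthetic assay generator that
provides ground-truthed data for all of them.  This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Droplet-freezing spectra

An immersion-freezing assay cools an array of droplets containing protein
at mass concentration `c_m` and records each droplet's freezing
temperature.  The cumulative frozen fraction `f_ice(T)` is converted to an
ice-nucleation site density per molecule

    Nn(T) = -ln(1 - f_ice(T)) * M / (c_m * V_liquid * N_A)

where `M` is the construct's molar mass and `V_liquid` the droplet volume;
the denominator of the equivalent form `-ln(1 - f_ice)/lambda` is the
expected number of protein molecules per droplet.  The Poisson correction
makes `Nn` independent of concentration and droplet volume, so spectra
measured at different dilutions of the same sample collapse onto one curve
and a serial dilution series extends the observable temperature range: the
concentrated sample resolves the rare warm tail, the dilute samples
resolve the plateau.  Points with `f_ice = 1` leave `Nn` undefined and are
dropped with a logged warning; no continuity correction is applied.

Characterization of a pooled spectrum proceeds as:

1. **Binning.**  All points from all dilutions are assigned to fixed 0.5 K
   temperature bins anchored at 0 °C and each bin reports the arithmetic
   mean of `log10 Nn`.  Binned log-averaging is the only smoothing.  The
   0.5 K default (configurable) averages several points per bin at the
   0.1 K instrument resolution emulated by the generator.
2. **Knee point.**  The knee — the curvature maximum where the steep rise
   of the spectrum turns into a plateau — is read as the total number of
   active molecules per molecule of the freezing mode.  It is located with
   the Kneedle procedure: with `x = -T` and `y = mean log10 Nn` both
   min–max normalized, the difference curve `d = y_n - x_n` is scanned for
   local maxima; a candidate at `i` is accepted once `d` falls below
   `d_i - S * mean(dx)` before the next candidate.  Sensitivity `S = 1` is
   used everywhere.  Ties break toward the warmer temperature (the knee is
   the *onset* of the plateau, which is the conservative choice for the
   plateau level).  If no candidate confirms, the global maximum of the
   difference curve is used and logged; an exactly straight curve returns
   "no knee".
3. **T_char,50.**  The characteristic nucleation temperature of a mode is
   where `Nn` reaches 50 % of the knee-point value, found by linear
   interpolation in `(T, log10 Nn)` on the warm side of the knee.
   Interpolating in log space is a choice (spectra span decades; for the
   narrow populations simulated here the difference from linear-space
   interpolation is far below the reported precision).  A step-like onset
   whose warmest point is already above the level returns that onset
   temperature.
4. **Activity classes.**  Two steep rises separated by a plateau indicate
   two nucleator populations: class A (warm, rare — attributed to
   higher-order oligomers) and class C (colder, more abundant —
   dimers).  Segmentation classifies adjacent-bin pairs as steep when the
   slope exceeds 0.1 decades/K *and* the pair rises by at least 0.3
   decades; the second condition keeps sub-half-decade wiggles across
   sparsely populated plateau regions from reading as modes.  Each maximal
   steep run plus its trailing plateau is one mode, characterized with the
   machinery above (Kneedle on the segment where it has ≥ 5 bins,
   otherwise the steep-to-plateau transition bin).  A final rise truncated
   by `f_ice → 1` saturation takes its coldest bin as the plateau
   estimate — the highest `Nn` actually observed for the mode.  Exactly
   two modes are labelled A (warmer) and C.  Class detection requires at
   least 4 bins and warns below 8.
5. **Homogeneous cutoff.**  Bins at or below −35 °C are excluded from knee
   and class detection: freezing there is dominated by the homogeneous
   background near −38 °C, and in dilute samples the resulting jump in
   apparent `Nn` would otherwise register as a spurious extra mode.

## Cuboid CNT template model

The central repeat domain presents a long, narrow, flat template.  The ice
cluster forming on it is modelled as a cuboid with axes `a` (length),
`b` (width, fixed by the protein or oligomer) and `c` (height).  The Gibbs
free energy of cluster formation is

    dG = a·b·c·dG_V + σ12(2ac + 2bc + ab) + σ23·ab + 2b·τ123 + 2a·τ123

with `dG_V(T) = -kT/v_ice(T) · ln S12(T)` the volumetric free-energy gain.
The expression is used exactly as written; note it contains no term
releasing the water–template interfacial energy (no `σ13·ab` subtraction),
which users substituting non-zero `σ23` should keep in mind.  Setting the
partial derivatives to zero at fixed `b` gives

    a_crit = -2bσ12 / (dG_V·b + 2σ12)
    c_crit = -(b(σ12 + σ23) + 2τ123) / (dG_V·b + 2σ12)

`a_crit` and `c_crit` are independent of each other; `a_crit` is also
independent of `σ23` and `τ123`.  Both are finite and positive only when
`b` exceeds the spherical-cap critical radius `r_crit = -2σ12/dG_V`; a
template narrower than `r_crit` cannot host a critical cluster at that
temperature.  Infeasibility is a returned state, not an exception —
characteristic-length curves legitimately terminate where the width drops
below `r_crit`.  As `b → ∞`, `a_crit → r_crit` (with
`a_crit/r_crit - 1 ≤ r_crit/(b - r_crit)`), and in the feasible regime
`a_crit > r_crit ≥ r_crit·sin θ`, i.e. the elongated template is always a
less efficient geometry than the spherical cap.

`a_crit(T, b)` grows monotonically with temperature, so its inverse maps a
template length to the warmest temperature at which a cluster of that
length is critical.  The inversion brackets the feasibility boundary and
bisects to 0.01 K (bisection chosen for robustness over speed on a
monotone function; the supported range is 233.15–273.14 K).

### Thermodynamic parameterizations

The temperature-dependent inputs are injected through `ThermoParams` and
default to standard literature fits chosen by this package (none are
uniquely mandated by the problem):

| quantity | default | units |
| --- | --- | --- |
| `S12(T)` | Murphy & Koop (2005) saturation vapour pressures, liquid/ice | – |
| `v_ice(T)` | Pruppacher–Klett ice-density polynomial, `M_w/(ρ_ice N_A)` (≈ 3.2e-29) | m³ |
| `σ12(T)` | `(28.0 + 0.25·(T - 273.15))` mJ/m² linear fit | J/m² |
| `σ23` | 0 (the headline quantity `a_crit` does not depend on it) | J/m² |
| `τ123` | 0 | J/m |
| `θ` | π/2 (cap baseline) | rad |

All internal units are SI (K, m, J); user-facing interfaces accept °C and
nm and convert with `T[K] = T[°C] + 273.15` exactly.  Predicted absolute
temperatures depend on these fits — with different published `σ12`
parameterizations the dimer predictions shift by several kelvin — so the
construct comparison should be read for its *structure* (monotone increase
with repeat count, diminishing returns, monomer ≪ dimer), which is robust
to the parameterization, rather than for exact agreement.

## Construct geometry

The repeat domain is a linear stack, so its length is `n_repeats × rise`.
The rise is fitted through the origin by least squares
(`slope = Σ(n·L)/Σ(n²)`) on measured (repeat count, length) pairs; the
four reference constructs (9R 4.1 nm, 16R 7.3 nm, 28R 12.8 nm, 67R
30.6 nm) are collinear through the origin to < 0.1 nm, which is why no
terminal-domain length offset is modelled.  A construct's predicted
characteristic temperature equates its longitudinal length with
`a_crit(T, b)` at the width of its oligomeric state (monomer 2.3 nm, dimer
5.5 nm) and solves for `T`.  No thermodynamic parameter is fitted to the
measured temperatures; the comparison table is a consistency check, not a
fit.  Filament (class A) temperatures are not predicted from first
principles — no filament-width model is attempted.

## Repeat-consensus sequence analysis

The 16-residue consensus `GYGSTxTAxxxSxL[T/I]A` has five wildcard
positions (6, 9, 10, 11, 13, 1-based) and tolerates T or I at position 15.
Similarity of a repeat to the consensus is the mean over the 11
constrained positions of a per-position score: 1 for identity or a
same-biochemical-class residue, 0 otherwise, with classes
{AILMV} {FWY} {KRH} {DE} {STNQ} {G} {P} {C}.  Excluding wildcards from the
mean (rather than auto-scoring them 1 among 16) makes a single mismatch
cost exactly 1/11; the inclusive mode is available as an option.  The
class weight is configurable for graded schemes.

The tandem-repeat scanner tries all 16 phases, chops the sequence into
consecutive non-overlapping 16-mers, and keeps the contiguous run of
windows scoring ≥ 60 % with the largest total similarity.  The structural
register places two β-strands at positions 4–7 (carrying the TxT motif at
5–7) and 12–15 (the SxL[T/I] motif), the remainder being the two sharp
turns, with the tyrosine ladder at position 2 — giving 8/16 = 50 %
strand content.  The exact strand boundaries are a judgment call recorded
here; the three-strand and shortened-strand variants used for comparison
(≈ 69 % and 37.5 %) are expressible through the same `strand_spans`
argument.

Circular-dichroism structure fractions are cumulative over residues, so
for nested constructs the content of the repeats separating them is
`(f_large·n_large - f_small·n_small)/(n_large - n_small)`.  Noisy inputs
can push this outside [0, 1]; the value is returned as computed so the
caller can flag it, never clamped.

## Synthetic assay generator

The generator emulates the two assay styles the analyses need:
`SimConfig.microfluidic()` (300 droplets of ~0.52 nL — 100 µm diameter —
per dilution, 10× steps, scan to −40 °C, M = 60 kg/mol, c_m = 9.5 mg/L)
and `SimConfig.microliter()` (90 × 1 µL droplets, 3 replicates per
concentration, scan to −25 °C, M = 120 kg/mol, c_m = 10 mg/L).  The
replicate count mirrors the practice of repeating each concentration at
least three times; the stock concentrations were chosen once so that
`λ·p_active ≈ 5` at the base concentration, i.e. the plateau of the
target population is observable before full freezing — the same criterion
an experimenter uses when setting up a dilution series.

The freezing model is *singular* (time-independent): each active molecule
carries a fixed activation temperature drawn from a narrow Gaussian for
its population, and a droplet freezes at the warmest activation
temperature among its molecules, or at a homogeneous-freezing draw from
Normal(−37 °C, 1 K).  Cooling rates are therefore not simulated.  Molecule
counts are Poisson with mean `λ = c_m·V·N_A/M` (guarded at 10¹²;
beyond that the code asks for dilution).  Sampling uses Poisson thinning
(`k ~ Poisson(λ·p_active)` active molecules per population) and draws the
maximum of `k` Gaussians in O(1) through the inverse CDF of the maximum,
`μ + σ·Φ⁻¹(u^{1/k})` — distributionally identical to drawing every
molecule, but fast at realistic loadings of 10¹⁰ molecules per droplet.
Reported temperatures are rounded to the 0.1 K instrument grid and values
below the scan minimum are censored as unfrozen.  Seeding is
hierarchical: one master seed, child streams per (dilution, replicate), so
a dilution series is reproducible as a whole.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: time-dependent (stochastic) nucleation and
cooling-rate effects, droplet-volume polydispersity, temperature
calibration error, protein aggregation/degradation kinetics (a broad
low-activity tail can be added as an extra species, but its parameters
are unconstrained), and surface or oil-interface artifacts.  The Gaussian
activation-temperature populations encode the assumption that a steep
spectrum slope means a homogeneous molecular population; real spectra mix
oligomer sizes continuously.

## Numerical choices and degenerate inputs

- Root finding: bisection with `xtol` = half the reported 0.01 K
  tolerance; feasibility boundaries pre-bracketed to 1 µK.
- Kneedle on fewer than 5 bins warns; fewer than 3 returns no knee;
  difference curves flat to 1e-12 return no knee.
- `merge_and_bin` requires at least one positive-`Nn` point; bins with
  fewer than `min_points_per_bin` points are omitted (empty temperature
  intervals are genuinely empty bins, since a cumulative spectrum cannot
  rise where no droplet froze).
- `t_char_50` errors when the 50 % level lies below the spectrum's
  warm-side range, reporting the attainable `Nn` range.
- Exact `b = r_crit` is a floating-point tie on the feasibility boundary;
  callers should treat results within machine epsilon of the boundary as
  boundary cases.

## Problem sizes

The bundled analyses and checks use 3 × 300 droplets (single-population
series) and 3 × 3 × 90 droplets (two-class series), the assay sizes the
instrument archetypes define; each full pipeline run takes well under a
second, and the 50-seed recovery study a few seconds.

## Known limitations

- Geometric (critical-size) CNT only: no nucleation rates, no ellipsoidal
  caps or rounded cuboids.
- Absolute temperature predictions inherit the uncertainty of the
  `σ12(T)` and `S12(T)` fits (several kelvin across published
  parameterizations).
- The plateau-level estimate of a saturation-truncated mode is biased
  low by up to ~0.2 decades (the plateau is never fully observed); the
  two-class ratio in the bundled analysis reads ≈ 1.9 rather than 2.0
  for this reason.
- The repeat scanner assumes a fixed 16-residue period and does not
  handle insertions/deletions within repeats.
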