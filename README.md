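# inproice

Quantitative analysis of how the size and oligomeric state of bacterial
ice-nucleation proteins (INpro) set the temperature at which they freeze
water.

INpro — membrane-associated proteins of plant pathogens such as
*Pseudomonas syringae* — are the most efficient ice nucleators known,
triggering freezing only a few degrees below 0 °C while pure water
supercools to −38 °C.  Their central repeat domain (CRD), a β-helix built
from 16-residue tandem repeats with consensus `GYGSTxTAxxxSxL[T/I]A`,
forms an elongated, narrow template for ice-cluster formation.  This
package provides the machinery to connect that geometry to measured
freezing activity, for researchers working with droplet-freezing assays
and protein-construct series:

- **Freezing spectra** (`inproice.spectra`): per-droplet freezing events →
  frozen fraction → ice-nucleation site density per molecule
  `Nn(T) = −ln(1−f_ice)·M/(c_m·V·N_A)`; dilution-series pooling,
  temperature-bin log-averaging, Kneedle knee-point detection (S = 1),
  characteristic nucleation temperature T_char,50 (where Nn is 50 % of the
  knee value), and segmentation into activity classes A and C.
- **Cuboid CNT model** (`inproice.cnt`, `inproice.thermo`): classical
  nucleation theory for a cuboid ice cluster on an elongated template,
  `ΔG = abc·ΔG_V + σ12(2ac+2bc+ab) + σ23·ab + 2(a+b)τ123`, with critical
  length `a_crit = −2bσ12/(ΔG_V·b + 2σ12)`, the spherical-cap baseline
  `r_crit = −2σ12/ΔG_V`, feasibility handling (`b` must exceed `r_crit`),
  and temperature↔length inversion.
- **Construct geometry** (`inproice.geometry`): per-repeat rise fits,
  CRD-length extrapolation, and CNT-predicted characteristic temperatures
  for monomer (b = 2.3 nm) and dimer (b = 5.5 nm) widths.
- **Repeat analysis** (`inproice.repeats`): tandem-repeat scanning,
  biochemical-class similarity scoring against the consensus,
  strand/motif/tyrosine-ladder annotation, and the cumulative-difference
  secondary-structure calculation for nested constructs.
- **Synthetic assays** (`inproice.simulate`): a generator for
  droplet-freezing experiments with Poisson-loaded molecules, narrow
  Gaussian activation-temperature populations and a homogeneous-freezing
  background, providing ground truth for every pipeline stage.

See `docs/methods.md` for the models, assumptions and design choices.

## Worked example

Simulate a two-population microliter assay — rare "class A" nucleators
(p_active = 1e-10) activating near −3.9 °C and 100× more abundant
"class C" nucleators (p_active = 1e-8) near −7.6 °C, 90 droplets × 3
replicates × dilutions 1/10/100 — and characterize the pooled spectrum:

```python
import math
import inproice as ip

species = [
    ip.INproSpecies("A", mean_activation_t_c=-3.9, spread_k=0.3, p_active=1e-10),
    ip.INproSpecies("C", mean_activation_t_c=-7.6, spread_k=0.3, p_active=1e-8),
]
assays = ip.make_dilution_series(species, ip.SimConfig.microliter(rng_seed=1))
res = ip.characterize_assays(assays, classes=True)
for r in res.results:
    print(f"class {r.class_label}: knee {r.t_knee_c:.2f} C, "
          f"Nn_knee = {r.nn_knee:.3g}, T_char,50 = {r.t_char50_c:.2f} C")
a, c = res.results
print(f"plateau ratio: {math.log10(c.nn_knee / a.nn_knee):.2f} orders of magnitude")
```

prints

```
class A: knee -4.25 C, Nn_knee = 7.62e-11, T_char,50 = -3.88 C
class C: knee -7.75 C, Nn_knee = 5.72e-09, T_char,50 = -7.56 C
plateau ratio: 1.88 orders of magnitude
```

Both generating activation temperatures are recovered to within 0.1 K,
the knee-point Nn values estimate the plateau levels (the fraction of
molecules that are active in each mode), and the ~2-orders-of-magnitude
abundance difference between the two classes is read directly off the
plateau ratio.

The CNT layer turns construct geometry into predicted freezing
temperatures:

```python
rise = ip.fit_rise_per_repeat([(9, 4.1), (16, 7.3), (28, 12.8)])  # nm/repeat
print(round(ip.crd_length(67, rise), 1))          # -> 30.6 (nm)
print(ip.comparison_table()[["construct", "t_pred_c", "t_measured_c"]])
```

The dimer-width predictions increase monotonically with repeat count with
diminishing returns — the physical argument for why assembling dimers
into higher-order oligomers raises the nucleation temperature more
effectively than adding repeats — while monomer widths are infeasible or
far colder at every length.

## Analysis scripts

Numbered drivers under `analysis/` rerun the full study on synthetic
data and write tables under `results/`:

```
python analysis/01_simulate_assays.py --seed 1    # event tables + ground truth
python analysis/02_characterize_spectra.py        # spectra, knees, T_char,50, classes
python analysis/03_cnt_geometry.py                # rise fit, CNT comparison, curves
python analysis/04_repeat_consensus.py            # consensus scan, strand content
```

A command-line interface wraps the same library calls
(`inproice simulate | spectrum | knee | classes | cnt-curve |
predict-tchar | repeats`); run `inproice --help`.

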