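#!/usr/bin/env python
"""Cuboid-CNT analysis of the construct series: rise fit, predicted vs
measured characteristic temperatures, and characteristic-length curves.

Fits the per-repeat rise of the CRD on the reference construct lengths,
extrapolates held-out lengths, tabulates CNT-predicted characteristic
nucleation temperatures for dimer (b = 5.5 nm) and monomer (b = 2.3 nm)
widths against the measured values, and writes characteristic-length vs
temperature curves for both geometries to results/.

Usage: python analysis/03_cnt_geometry.py
"""

from pathlib import Path

import pandas as pd

import inproice as ip
from inproice.cnt import char_length_curve
from inproice.thermo import ThermoParams

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    params = ThermoParams.default()

    pairs = [(c.n_repeats, c.measured_longitudinal_nm) for c in ip.R10_79_CONSTRUCTS]
    rise3 = ip.fit_rise_per_repeat(pairs[:3])
    rise2 = ip.fit_rise_per_repeat(pairs[:2])
    print(f"per-repeat rise (9R/16R/28R fit): {rise3:.4f} nm/repeat")
    print(f"  -> 67R length extrapolates to {ip.crd_length(67, rise3):.1f} nm "
          f"(reference 30.6 nm)")
    print(f"per-repeat rise (9R/16R fit): {rise2:.4f} nm/repeat")
    print(f"  -> 28R length extrapolates to {ip.crd_length(28, rise2):.1f} nm "
          f"(reference 12.8 nm)")

    table = ip.comparison_table(params=params)
    mono = ip.comparison_table(state=ip.MONOMER, params=params)
    table["t_pred_monomer_c"] = mono["t_pred_c"]
    table["monomer_feasible"] = mono["feasible"]
    table.to_csv(out / "cnt_comparison.csv", index=False, float_format="%.4g")
    print("\npredicted vs measured characteristic temperatures (dimer b = 5.5 nm):")
    print(table.to_string(index=False))

    rows = []
    for model, b_nm in (("cuboid", 5.5), ("cuboid", 2.3), ("cap", None)):
        for t_c, length, feasible in char_length_curve(b_nm, -38.0, -2.0, 0.1, params, model):
            rows.append(
                {"model": model, "b_nm": b_nm, "temperature_C": t_c,
                 "char_length_nm": length, "feasible": feasible}
            )
    pd.DataFrame(rows).to_csv(out / "cnt_curves.csv", index=False, float_format="%.6g")
    print(f"\ncurves written to {out / 'cnt_curves.csv'}")


if __name__ == "__main__":
    main()
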