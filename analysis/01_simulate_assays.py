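#!/usr/bin/env python
"""Simulate the two droplet-freezing datasets used by the downstream analyses.

Generates (a) a microfluidic-style dilution series (300 x ~0.5 nL droplets,
10x dilution steps, scan to -40 degC) of a single narrow nucleator
population at -21.7 degC, and (b) a cold-stage microliter series (90 x 1 uL
droplets, 3 replicates per concentration) of a two-population sample: rare
class A nucleators at -3.9 degC and 100x more abundant class C nucleators
at -7.6 degC.  Event tables and ground-truth sidecars go to results/.

Usage: python analysis/01_simulate_assays.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import inproice as ip
from inproice import io as iomod

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    out = ROOT / "results"
    out.mkdir(exist_ok=True)

    # single-population microfluidic series (construct-characterization style)
    single = [ip.INproSpecies("C", -21.7, 0.3, 1e-7)]
    cfg_single = ip.SimConfig.microfluidic(rng_seed=args.seed, replicates=1)
    assays = ip.make_dilution_series(single, cfg_single)
    iomod.write_droplet_table(
        out / "events_single_population.csv", assays, sample_id="single", seed=args.seed
    )
    (out / "events_single_population.truth.json").write_text(
        json.dumps({"species": [s.__dict__ for s in single]}, indent=2) + "\n"
    )
    n_frozen = sum(a.freezing_temperatures_c.size for a in assays)
    print(f"single-population series: {len(assays)} assays, {n_frozen} freezing events")

    # two-population microliter series (activity-class style)
    two = [
        ip.INproSpecies("A", -3.9, 0.3, 1e-10),
        ip.INproSpecies("C", -7.6, 0.3, 1e-8),
    ]
    cfg_two = ip.SimConfig.microliter(rng_seed=args.seed)
    assays2 = ip.make_dilution_series(two, cfg_two)
    iomod.write_droplet_table(
        out / "events_two_class.csv", assays2, sample_id="two_class", seed=args.seed
    )
    (out / "events_two_class.truth.json").write_text(
        json.dumps({"species": [s.__dict__ for s in two]}, indent=2) + "\n"
    )
    n_frozen2 = sum(a.freezing_temperatures_c.size for a in assays2)
    print(f"two-class series: {len(assays2)} assays, {n_frozen2} freezing events")
    print(f"event tables written to {out}")


if __name__ == "__main__":
    main()
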