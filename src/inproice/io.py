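"""Tabular formats, configuration and provenance for the pipeline.

Droplet event tables are plain CSV with columns ``droplet_id``,
``freezing_temp_C`` (empty = unfrozen), ``volume_L`` (or ``diameter_um``),
``dilution_factor`` and ``sample_id``; assay conditions (mass concentration,
molar mass) are supplied per sample.  Every artifact written by the pipeline
carries provenance header lines (``# key = value``: package version, master
seed, config hash) which readers skip transparently.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .spectra import AssayConditions, FreezingAssay, NucleationSpectrum

__all__ = [
    "REQUIRED_EVENT_COLUMNS",
    "parse_droplet_table",
    "write_droplet_table",
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_json",
    "load_config",
    "config_hash",
    "provenance_header",
]

REQUIRED_EVENT_COLUMNS = ("droplet_id", "freezing_temp_C", "dilution_factor", "sample_id")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: Optional[int] = None, config: Optional[dict] = None) -> list[str]:
    from . import __version__

    lines = [f"# inproice_version = {__version__}"]
    if seed is not None:
        lines.append(f"# seed = {seed}")
    if config is not None:
        lines.append(f"# config_hash = {config_hash(config)}")
    return lines


def load_config(path) -> dict:
    """Read a YAML/JSON configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def parse_droplet_table(path, conditions: dict) -> list[FreezingAssay]:
    """Read a droplet event CSV into one assay per (sample_id, dilution).

    ``conditions`` maps sample_id to ``{"c_m_g_per_L": ..,
    "molar_mass_g_per_mol": ..}``.  Droplet volume comes from a ``volume_L``
    column, or from ``diameter_um`` via V = (pi/6) d^3.  Blank
    ``freezing_temp_C`` entries count as unfrozen droplets.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty droplet table")
    for col in REQUIRED_EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if "volume_L" not in df.columns and "diameter_um" not in df.columns:
        raise ValueError(f"{path}: need a 'volume_L' or 'diameter_um' column")

    raw = df["freezing_temp_C"]
    temps = pd.to_numeric(raw, errors="coerce")
    bad = temps.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.where(bad)[0][0]) + 2  # 1-based, + header line
        raise ValueError(
            f"{path}: non-numeric freezing_temp_C {raw[bad].iloc[0]!r} at line {row}"
        )
    df = df.assign(freezing_temp_C=temps)

    if "volume_L" in df.columns:
        vol = pd.to_numeric(df["volume_L"])
    else:
        d_m = pd.to_numeric(df["diameter_um"]) * 1e-6
        vol = math.pi / 6.0 * d_m**3 * 1e3  # m^3 -> L

    assays = []
    for (sample, factor), grp in df.groupby(["sample_id", "dilution_factor"], sort=True):
        if sample not in conditions:
            raise ValueError(f"{path}: no conditions given for sample {sample!r}")
        cond_in = conditions[sample]
        v = float(vol[grp.index].iloc[0])
        cond = AssayConditions(
            c_m=float(cond_in["c_m_g_per_L"]),
            droplet_volume_l=v,
            molar_mass=float(cond_in["molar_mass_g_per_mol"]),
            dilution_factor=float(factor),
        )
        frozen = grp["freezing_temp_C"].dropna().to_numpy()
        assays.append(
            FreezingAssay(
                conditions=cond,
                freezing_temperatures_c=frozen,
                n_unfrozen=int(grp["freezing_temp_C"].isna().sum()),
                instrument=str(grp["instrument"].iloc[0]) if "instrument" in grp else "",
            )
        )
    return assays


def write_droplet_table(
    path,
    assays: list[FreezingAssay],
    sample_id: str = "sample",
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write assays as a droplet event CSV (one row per droplet)."""
    rows = []
    droplet = 0
    for assay in assays:
        for t in assay.freezing_temperatures_c:
            rows.append((droplet, f"{t:.4f}", assay.conditions.droplet_volume_l,
                         assay.conditions.dilution_factor, sample_id))
            droplet += 1
        for _ in range(assay.n_unfrozen):
            rows.append((droplet, "", assay.conditions.droplet_volume_l,
                         assay.conditions.dilution_factor, sample_id))
            droplet += 1
    df = pd.DataFrame(
        rows, columns=["droplet_id", "freezing_temp_C", "volume_L", "dilution_factor", "sample_id"]
    )
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def write_spectrum_csv(
    path,
    spectrum: NucleationSpectrum,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    df = pd.DataFrame(
        {"temperature_C": spectrum.temperature_c, "nn_per_molecule": spectrum.nn}
    )
    with Path(path).open("w") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_spectrum_csv(path) -> NucleationSpectrum:
    df = pd.read_csv(path, comment="#")
    return NucleationSpectrum(
        df["temperature_C"].to_numpy(), df["nn_per_molecule"].to_numpy()
    )


def write_json(path, payload: dict, seed: Optional[int] = None, config: Optional[dict] = None) -> None:
    """JSON artifact with provenance embedded under ``_provenance``."""
    from . import __version__

    out = dict(payload)
    prov = {"inproice_version": __version__}
    if seed is not None:
        prov["seed"] = seed
    if config is not None:
        prov["config_hash"] = config_hash(config)
    out["_provenance"] = prov
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
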