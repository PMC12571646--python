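"""Readers and writers for the plain-text formats the pipeline speaks.

* multi-model PDB (MODEL/ENDMDL; only N/CA/C needed) via Biopython;
* the dihedral TSV dialect: frame, time_ns, chain, residue_index (1-based),
  residue_name, phi_deg, psi_deg, with literal "NA" for undefined angles;
* CD spectra CSV (wavelength_nm, mre, temperature_C, label) — one file may
  hold many temperatures;
* melt CSV (temperature_C, mre, wavelength_nm);
* shift TSV (residue_index, aa, ca_obs_ppm, ca_ref_ppm, ha_obs_ppm,
  ha_ref_ppm, j_hnha_hz), "NA" allowed anywhere.

All writers prepend a ``#`` comment block naming the columns' units; all
readers skip ``#`` lines.
"""

from __future__ import annotations

import io as _stdio
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .cd import CDSpectrum, MeltTrace
from .geometry import BackboneCoordinates
from .trajectory import DihedralEnsemble

__all__ = [
    "read_backbone_models",
    "write_backbone_models",
    "read_dihedral_tsv",
    "write_dihedral_tsv",
    "read_cd_csv",
    "write_cd_csv",
    "read_melt_csv",
    "write_melt_csv",
    "read_shift_tsv",
    "write_shift_tsv",
]

_BACKBONE_ATOMS = ("N", "CA", "C")


def read_backbone_models(path) -> list[BackboneCoordinates]:
    """Read a (multi-model) PDB into one BackboneCoordinates per model/chain.

    Only ATOM records for N, CA and C are used; for disordered (altloc)
    atoms Biopython's highest-occupancy conformer is kept.  A polymer
    residue missing any backbone atom is an error naming the residue.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("input", str(path))

    models: list[BackboneCoordinates] = []
    for model in structure:
        for chain in model:
            names, n_xyz, ca_xyz, c_xyz = [], [], [], []
            for residue in chain:
                if residue.id[0] != " ":  # skip waters / heteroatoms
                    continue
                coords = {}
                for atom_name in _BACKBONE_ATOMS:
                    if atom_name not in residue:
                        raise ValueError(
                            f"residue {residue.get_resname()} {residue.id[1]} of chain "
                            f"{chain.id} (model {model.id}) lacks backbone atom {atom_name}"
                        )
                    coords[atom_name] = residue[atom_name].get_coord()
                names.append(residue.get_resname())
                n_xyz.append(coords["N"])
                ca_xyz.append(coords["CA"])
                c_xyz.append(coords["C"])
            if not names:
                continue
            models.append(
                BackboneCoordinates(
                    chain_id=str(chain.id),
                    residue_names=names,
                    n=np.array(n_xyz),
                    ca=np.array(ca_xyz),
                    c=np.array(c_xyz),
                    model_index=int(model.id),
                )
            )
    if not models:
        raise ValueError(f"no polymer chains with backbone atoms found in {path}")
    return models


def write_backbone_models(path, models: list[BackboneCoordinates]) -> None:
    """Write backbone-only coordinates as a multi-model PDB."""
    by_model: dict[int, list[BackboneCoordinates]] = {}
    for m in models:
        by_model.setdefault(m.model_index, []).append(m)

    lines = []
    for model_index in sorted(by_model):
        lines.append(f"MODEL     {model_index + 1:4d}")
        serial = 1
        for m in by_model[model_index]:
            for i, resname in enumerate(m.residue_names):
                for atom_name, xyz in (("N", m.n[i]), ("CA", m.ca[i]), ("C", m.c[i])):
                    name_field = f" {atom_name:<3s}"
                    lines.append(
                        f"ATOM  {serial:5d} {name_field}{resname:>4s} "
                        f"{m.chain_id[:1]}{i + 1:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          "
                        f"{atom_name[0]:>2s}"
                    )
                    serial += 1
            lines.append("TER")
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# dihedral TSV

_DIHEDRAL_HEADER = (
    "# dihedral table: phi_deg/psi_deg in degrees, (-180, 180], NA = undefined\n"
    "# time_ns in nanoseconds; residue_index is 1-based\n"
)


def write_dihedral_tsv(path, ensemble_or_df) -> None:
    df = (
        ensemble_or_df.to_dataframe()
        if isinstance(ensemble_or_df, DihedralEnsemble)
        else ensemble_or_df
    )
    buf = _stdio.StringIO()
    buf.write(_DIHEDRAL_HEADER)
    df.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_dihedral_tsv(path) -> DihedralEnsemble:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    return DihedralEnsemble.from_dataframe(df)


# ---------------------------------------------------------------------------
# CD CSV

_CD_HEADER = (
    "# CD spectra: wavelength_nm in nm, mre in deg*cm^2*dmol^-1, temperature_C in C\n"
)


def write_cd_csv(path, spectra: list[CDSpectrum]) -> None:
    frames = [
        pd.DataFrame(
            {
                "wavelength_nm": s.wavelengths,
                "mre": s.mre,
                "temperature_C": s.temperature,
                "label": s.label,
            }
        )
        for s in spectra
    ]
    buf = _stdio.StringIO()
    buf.write(_CD_HEADER)
    pd.concat(frames, ignore_index=True).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_cd_csv(path) -> list[CDSpectrum]:
    df = pd.read_csv(path, comment="#")
    spectra = []
    for (temp, label), sub in df.groupby(["temperature_C", "label"], sort=True):
        sub = sub.sort_values("wavelength_nm")
        spectra.append(
            CDSpectrum(
                wavelengths=sub["wavelength_nm"].to_numpy(dtype=float),
                mre=sub["mre"].to_numpy(dtype=float),
                temperature=float(temp),
                label=str(label),
            )
        )
    if not spectra:
        raise ValueError(f"no spectra found in {path}")
    return spectra


# ---------------------------------------------------------------------------
# melt CSV

_MELT_HEADER = (
    "# CD melt trace: temperature_C in C, mre in deg*cm^2*dmol^-1, wavelength_nm in nm\n"
)


def write_melt_csv(path, trace: MeltTrace) -> None:
    df = pd.DataFrame(
        {
            "temperature_C": trace.temperatures,
            "mre": trace.mre,
            "wavelength_nm": trace.wavelength,
        }
    )
    buf = _stdio.StringIO()
    buf.write(_MELT_HEADER)
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_melt_csv(path) -> MeltTrace:
    df = pd.read_csv(path, comment="#").sort_values("temperature_C")
    wavelengths = df["wavelength_nm"].unique()
    if len(wavelengths) != 1:
        raise ValueError("melt CSV must hold a single wavelength")
    return MeltTrace(
        temperatures=df["temperature_C"].to_numpy(dtype=float),
        mre=df["mre"].to_numpy(dtype=float),
        wavelength=float(wavelengths[0]),
    )


# ---------------------------------------------------------------------------
# shift TSV

_SHIFT_HEADER = (
    "# chemical-shift table: *_ppm in ppm (DSS-referenced), j_hnha_hz in Hz, "
    "NA = not measured\n"
)


def write_shift_tsv(path, table: pd.DataFrame) -> None:
    buf = _stdio.StringIO()
    buf.write(_SHIFT_HEADER)
    table.to_csv(buf, sep="\t", index=False, na_rep="NA", float_format="%.4f")
    Path(path).write_text(buf.getvalue())


def read_shift_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if "residue_index" not in df.columns:
        raise ValueError("shift TSV lacks a residue_index column")
    return df
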