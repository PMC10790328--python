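"""Readers and writers for the package's plain-text interchange formats.

Everything is CSV with explicit headers (floats at 6 significant digits so
reports diff cleanly), FASTA for sequences, and PDB for residue-track output.
The HDX reader accepts the DynamX-style state-data column layout
(Protein,Start,End,Sequence,State,Exposure_min,Replicate,Uptake_Da).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingFit
from .nativems import PeakList

__all__ = [
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_mole_fractions_csv",
    "write_mole_fractions_csv",
    "write_fit_report_csv",
    "read_hdx_state_csv",
    "write_hdx_state_csv",
    "write_table_csv",
    "read_fasta",
    "write_bfactor_pdb",
]

_HDX_COLUMNS = {
    "protein": "protein",
    "start": "start",
    "end": "end",
    "sequence": "sequence",
    "state": "state",
    "exposure_min": "exposure_min",
    "exposure": "exposure_min",
    "replicate": "replicate",
    "uptake_da": "uptake_da",
    "uptake": "uptake_da",
}


def _format_floats(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
    return out


def write_table_csv(df: pd.DataFrame, path) -> None:
    """Write any result table with 6-significant-digit floats."""
    _format_floats(df).to_csv(path, index=False)


def read_peaklist_csv(path, label: str | None = None, replicate: int | None = None) -> PeakList:
    """Read an ``mz,intensity`` peak-list CSV; a header line is optional."""
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    has_header = any(c.isalpha() for c in first.split(",")[0])
    df = pd.read_csv(path, header=0 if has_header else None, names=None if has_header else ["mz", "intensity"])
    df.columns = [str(c).strip().lower() for c in df.columns]
    return PeakList(
        df["mz"].to_numpy(float),
        df["intensity"].to_numpy(float),
        label=label or path.stem,
        replicate=replicate,
    )


def write_peaklist_csv(peaks: PeakList, path) -> None:
    write_table_csv(pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}), path)


def read_mole_fractions_csv(path) -> pd.DataFrame:
    """Read a ``lipid_conc_uM,replicate,x0..xn`` mole-fraction table."""
    df = pd.read_csv(path)
    frac_cols = [c for c in df.columns if c.startswith("x")]
    if "lipid_conc_uM" not in df.columns or not frac_cols:
        raise ValueError(f"{path}: expected columns lipid_conc_uM, x0..xn")
    sums = df[frac_cols].sum(axis=1)
    # 6-significant-digit CSV rounding perturbs sums by up to a few 1e-6
    if np.any(np.abs(sums - 1.0) > 1e-4):
        raise ValueError(f"{path}: mole-fraction rows must sum to 1")
    df[frac_cols] = df[frac_cols].div(sums, axis=0)  # restore exact normalisation
    return df


def write_mole_fractions_csv(table: pd.DataFrame, path) -> None:
    write_table_csv(table, path)


def write_fit_report_csv(fit: BindingFit, path) -> None:
    """Fit report: one row per binding event (site, KD_uM, SD, R2, converged)."""
    rows = []
    for i, kd in enumerate(fit.kds):
        rows.append(
            {
                "site": i + 1,
                "KD_uM": kd,
                "KD_sd_uM": fit.kd_sd[i] if fit.kd_sd is not None else np.nan,
                "R2": fit.r_squared,
                "converged": fit.converged,
                "at_bound": fit.at_bounds[i],
                "no_binding": fit.no_binding,
            }
        )
    write_table_csv(pd.DataFrame(rows), path)


def read_hdx_state_csv(path) -> pd.DataFrame:
    """Read a DynamX-style state-data CSV into the internal tidy layout."""
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HDX_COLUMNS:
            rename[col] = _HDX_COLUMNS[key]
    df = df.rename(columns=rename)
    required = ["start", "end", "sequence", "state", "exposure_min", "replicate", "uptake_da"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing HDX columns {missing}")
    return df


def write_hdx_state_csv(table: pd.DataFrame, path) -> None:
    out = table.rename(
        columns={
            "protein": "Protein",
            "start": "Start",
            "end": "End",
            "sequence": "Sequence",
            "state": "State",
            "exposure_min": "Exposure_min",
            "replicate": "Replicate",
            "uptake_da": "Uptake_Da",
        }
    )
    write_table_csv(out, path)


def read_fasta(path) -> str:
    """First record of a FASTA file as a plain string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


def write_bfactor_pdb(structure_path, out_path, track: pd.Series) -> None:
    """Write a copy of a PDB with a residue track in the B-factor column.

    Values are clamped to the fixed-width-legal [-9.99, 99.99] and rounded to
    2 decimals; residues absent from the track get B = 0.00 and occupancy 0.
    """
    import gemmi

    structure = gemmi.read_structure(str(structure_path))
    for model in structure:
        for chain in model:
            for residue in chain:
                seqid = residue.seqid.num
                value = track.get(seqid, np.nan)
                missing = pd.isna(value)
                b = 0.0 if missing else float(np.clip(round(float(value), 2), -9.99, 99.99))
                for atom in residue:
                    atom.b_iso = b
                    if missing:
                        atom.occ = 0.0
    structure.write_pdb(str(out_path))
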