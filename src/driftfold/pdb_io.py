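"""FASTA and Calpha-trace PDB input/output.

The model is Calpha-level, so structures are written as one CA ATOM
record per residue (chain A, occupancy 1.00), with HELIX/SHEET records
mirroring the secondary-structure annotation.  Reading goes through
Biopython's PDB parser and extracts the CA coordinates of the first
model/chain encountered.
"""

from __future__ import annotations

import io
import warnings
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .ss_rules import SecondaryStructureAnnotation

__all__ = ["read_fasta", "read_ca_coordinates", "write_ca_pdb", "write_trajectory_pdb"]


def read_fasta(path: str) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a single- or multi-record FASTA file."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path!r}")
    return records


def read_ca_coordinates(path: str) -> np.ndarray:
    """(n, 3) CA coordinates (Angstrom) of the first model/chain with CAs."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("ref", path)
    for model in structure:
        for chain in model:
            coords = [
                res["CA"].coord for res in chain if "CA" in res
            ]
            if coords:
                return np.asarray(coords, dtype=float)
    raise ValueError(f"no CA atoms found in {path!r}")


def _format_atom(serial: int, resname: str, resseq: int, xyz: np.ndarray) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  CA  {resname:>3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _model_lines(
    coords_nm: np.ndarray, sequence: str | None, start_serial: int = 1
) -> list[str]:
    lines = []
    for i, xyz in enumerate(np.asarray(coords_nm) * 10.0):  # nm -> Angstrom
        resname = _AA3.get(sequence[i], "UNK") if sequence else "GLY"
        lines.append(_format_atom(start_serial + i, resname, i + 1, xyz))
    return lines


def write_ca_pdb(
    path: str,
    coords_nm: np.ndarray,
    sequence: str | None = None,
    annotation: SecondaryStructureAnnotation | None = None,
) -> None:
    """Write a Calpha-only PDB file (coordinates given in nm)."""
    lines = ["REMARK   1 CALPHA TRACE WRITTEN BY DRIFTFOLD"]
    if annotation is not None:
        h_id = e_id = 0
        for start, end, kind in annotation.regions:
            s, e = start + 1, end + 1
            rs = _AA3.get(sequence[start], "UNK") if sequence else "GLY"
            re_ = _AA3.get(sequence[end], "UNK") if sequence else "GLY"
            if kind == "H":
                h_id += 1
                lines.append(
                    f"HELIX  {h_id:3d} {h_id:3d} {rs} A {s:4d}  {re_} A {e:4d}  1"
                    f"{'':30s}{e - s + 1:6d}"
                )
            else:
                e_id += 1
                lines.append(
                    f"SHEET  {e_id:3d} S{e_id:2d} 1 {rs} A{s:4d}  {re_} A{e:4d}  0"
                )
    lines += _model_lines(coords_nm, sequence)
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_trajectory_pdb(
    path: str, frames: Sequence[np.ndarray], sequence: str | None = None
) -> None:
    """Multi-MODEL Calpha trajectory (one MODEL per stored frame, nm input)."""
    lines = []
    for m, coords in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:4d}")
        lines += _model_lines(coords, sequence)
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
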