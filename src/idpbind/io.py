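"""Readers and writers for the plain-text formats the package exchanges.

FASTA sequences (Biopython), multi-model PDB ensembles (Biopython, MODEL/
ENDMDL-delimited), plain-text XYZ trajectories, and TSV tables for profiles,
titrations and contact maps.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .charge import ProteinSequence, RNASequence
from .exceptions import InputError
from .geometry import ConformationalEnsemble

__all__ = [
    "read_fasta_protein",
    "read_fasta_rna",
    "read_multimodel_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_titration_tsv",
    "write_contact_map_tsv",
    "write_json",
]


def read_fasta_protein(path) -> ProteinSequence:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise InputError(f"no FASTA record in {path}")
    return ProteinSequence(str(rec.seq), name=rec.id)


def read_fasta_rna(path) -> RNASequence:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"), None)
    if rec is None:
        raise InputError(f"no FASTA record in {path}")
    return RNASequence(str(rec.seq).replace("T", "U"), name=rec.id)


def read_multimodel_pdb(path, atom_name: str | None = None
                        ) -> ConformationalEnsemble:
    """Each MODEL becomes a frame; optionally keep only ``atom_name`` atoms
    (e.g. "CA" or "C1'"), else all atoms in file order."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    frames, labels = [], None
    for model in structure:
        coords, model_labels = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom_name is not None and atom.get_name() != atom_name:
                        continue
                    coords.append(atom.coord)
                    model_labels.append(
                        f"{res.id[1]} {res.get_resname().strip()} {atom.get_name()}"
                    )
        if not coords:
            raise InputError(f"model without matching atoms in {path}")
        frames.append(np.asarray(coords, float))
        labels = labels or model_labels
    if not frames:
        raise InputError(f"no models found in {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise InputError("models carry different bead counts")
    return ConformationalEnsemble(coords=np.stack(frames), labels=labels)


def read_xyz_trajectory(path) -> ConformationalEnsemble:
    """Concatenated-frame XYZ: per frame a bead count, a comment line, then
    ``label x y z`` rows; frame sizes are validated for consistency."""
    frames, labels = [], None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as e:
            raise InputError(f"expected a bead count at line {i + 1}") from e
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise InputError("truncated XYZ frame")
        coords, frame_labels = [], []
        for row in block:
            parts = row.split()
            if len(parts) < 4:
                raise InputError(f"malformed XYZ row: {row!r}")
            frame_labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if labels is None:
            labels = frame_labels
        elif frame_labels != labels:
            raise InputError("inconsistent bead labels across XYZ frames")
        frames.append(np.asarray(coords))
        i += 2 + n
    if not frames:
        raise InputError(f"no frames found in {path}")
    return ConformationalEnsemble(coords=np.stack(frames), labels=labels)


def write_xyz_trajectory(ensemble: ConformationalEnsemble, path,
                         comment: str = "") -> None:
    with open(path, "w") as fh:
        for frame in ensemble.coords:
            fh.write(f"{ensemble.n_beads}\n{comment}\n")
            for label, (x, y, z) in zip(ensemble.labels, frame):
                fh.write(f"{label.split()[0]} {x:.4f} {y:.4f} {z:.4f}\n")


def read_titration_tsv(path, m_total: float, kind: str = "anisotropy"):
    """TSV with columns (ligand_total_uM, observable) → TitrationSeries."""
    from .binding import TitrationSeries

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError("titration TSV needs two columns")
    return TitrationSeries(ligand_totals=df.iloc[:, 0].to_numpy(float),
                           m_total=m_total,
                           observable=df.iloc[:, 1].to_numpy(float),
                           kind=kind)


def write_contact_map_tsv(contact_map, path) -> None:
    """Long-format TSV: residue_i, bead_j, frequency."""
    freq = contact_map.frequencies
    ii, jj = np.meshgrid(np.arange(1, freq.shape[0] + 1),
                         np.arange(1, freq.shape[1] + 1), indexing="ij")
    df = pd.DataFrame({"residue_i": ii.ravel(), "bead_j": jj.ravel(),
                       "frequency": freq.ravel()})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
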