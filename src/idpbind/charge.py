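"""Sequence-level charge analytics for protein/RNA coacervation stoichiometry.

Formal charges follow the coarse-grained convention used for highly charged
disordered proteins near neutral pH: Arg and Lys carry +1, Asp and Glu carry
-1, His/Cys/Tyr and the chain termini are neutral (the simulated construct is
capped), and every ribonucleotide carries -1 from its phosphate.  The
net-charge-per-residue (NCPR) profile is the sliding-window mean of those
per-residue charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlphabetError, ParameterError, UndefinedStoichiometryError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
RNA_BASES = "ACGU"

#: formal per-residue charges at pH 7.5 (termini neutral)
RESIDUE_CHARGE = {aa: 0 for aa in AMINO_ACIDS}
RESIDUE_CHARGE.update({"K": 1, "R": 1, "D": -1, "E": -1})

__all__ = [
    "ProteinSequence",
    "RNASequence",
    "ChargeProfile",
    "net_charge",
    "per_residue_charges",
    "ncpr_profile",
    "charge_match_ratio",
]


def _validate(residues: str, alphabet: str) -> None:
    if not residues:
        raise AlphabetError("", 1, alphabet)
    for i, ch in enumerate(residues, start=1):
        if ch not in alphabet:
            raise AlphabetError(ch, i, alphabet)


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter amino-acid sequence over the 20-letter alphabet."""

    residues: str
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "residues", "".join(self.residues.split()).upper())
        _validate(self.residues, AMINO_ACIDS)

    def __len__(self) -> int:
        return len(self.residues)

    def __add__(self, other: "ProteinSequence") -> "ProteinSequence":
        return ProteinSequence(self.residues + other.residues, name=self.name)


@dataclass(frozen=True)
class RNASequence:
    """Ribonucleotide sequence over {A, C, G, U}."""

    nucleotides: str
    name: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "nucleotides", "".join(self.nucleotides.split()).upper()
        )
        _validate(self.nucleotides, RNA_BASES)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __add__(self, other: "RNASequence") -> "RNASequence":
        return RNASequence(self.nucleotides + other.nucleotides, name=self.name)


@dataclass(frozen=True)
class ChargeProfile:
    """Sliding-window net charge per residue, one value per position."""

    window: int
    positions: np.ndarray = field(repr=False)  # 1-based
    values: np.ndarray = field(repr=False)

    def to_tsv(self, path) -> None:
        arr = np.column_stack([self.positions, self.values])
        np.savetxt(path, arr, fmt=["%d", "%.6f"], delimiter="\t",
                   header="position\tncpr", comments="")


def per_residue_charges(seq: ProteinSequence | RNASequence) -> np.ndarray:
    """Formal charge of each monomer (protein: K/R +1, D/E -1; RNA: all -1)."""
    if isinstance(seq, RNASequence):
        return np.full(len(seq), -1.0)
    return np.array([RESIDUE_CHARGE[aa] for aa in seq.residues], dtype=float)


def net_charge(seq: ProteinSequence | RNASequence, ph: float = 7.5) -> int:
    """Integer formal net charge of a sequence.

    The charge rule is the fixed-charge assignment defined at pH 7.5; ``ph``
    is validated to lie in [0, 14] but does not alter the rule (no pKa
    titration model is included).
    """
    if not 0.0 <= ph <= 14.0:
        raise ParameterError(f"pH must lie in [0, 14], got {ph}")
    return int(round(per_residue_charges(seq).sum()))


def ncpr_profile(seq: ProteinSequence, window: int = 5) -> ChargeProfile:
    """Net charge per residue in a sliding window centred at each position.

    Edge positions use the truncated window, so the profile covers every
    residue of the sequence.
    """
    n = len(seq)
    if window % 2 == 0 or window < 1 or window > n:
        raise ParameterError(
            f"window must be odd and within [1, {n}], got {window}"
        )
    charges = per_residue_charges(seq)
    half = window // 2
    values = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        values[i] = charges[lo:hi].mean()
    return ChargeProfile(window=window, positions=np.arange(1, n + 1),
                         values=values)


def charge_match_ratio(protein: ProteinSequence, rna: RNASequence) -> float:
    """Protein:RNA molar ratio at which total formal charges balance.

    Defined only for a positively charged protein and (necessarily negative)
    RNA; returns |q_RNA| / q_protein.
    """
    qp = net_charge(protein)
    qr = net_charge(rna)
    if qp <= 0 or qr >= 0:
        raise UndefinedStoichiometryError(
            f"charge matching needs protein charge > 0 and RNA charge < 0, "
            f"got {qp} and {qr}"
        )
    return abs(qr) / qp
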