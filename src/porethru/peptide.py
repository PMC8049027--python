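"""Peptide sequences and the simple charge model used by the electrodiffusion analysis.

Protamine (Ptm) is a 32-residue, arginine-rich polycation.  The translocation
analysis treats it as a rigid point charge whose effective valence equals the
count of charged side chains: +1 per Arg/Lys, -1 per Asp/Glu, termini ignored
by default.  For salmine-type protamine this gives +21 e, which is neutralised
in solution by divalent sulfate counterions — ceil(21/2) = 11 of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Packaged protamine fixture (salmine A1; 32 aa, 21 Arg, net +21 e).
PTM_FASTA = Path(__file__).parent / "data" / "ptm_salmine.fasta"


@dataclass(frozen=True)
class PeptideRecord:
    """A named amino-acid sequence (upper-case one-letter codes)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"peptide {self.name!r}: empty sequence")
        for pos, ch in enumerate(seq, start=1):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"peptide {self.name!r}: illegal residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChargeModel:
    """Side-chain counting charge model.

    Only fully charged side chains at neutral pH are counted; His and the
    termini are excluded by default (``include_termini=True`` adds +1 for the
    N-terminus and -1 for the C-terminus, net zero for a free peptide).
    ``counterion_valence`` is the signed charge of the mobile counterion used
    for stoichiometry, -2 for sulfate.
    """

    basic_residues: frozenset[str] = frozenset({"R", "K"})
    acidic_residues: frozenset[str] = frozenset({"D", "E"})
    include_termini: bool = False
    counterion_valence: int = -2

    def __post_init__(self) -> None:
        object.__setattr__(self, "basic_residues", frozenset(self.basic_residues))
        object.__setattr__(self, "acidic_residues", frozenset(self.acidic_residues))
        if self.basic_residues & self.acidic_residues:
            raise ValueError("basic and acidic residue sets must be disjoint")
        if self.counterion_valence == 0:
            raise ValueError("counterion valence must be nonzero")


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide FASTA file into a list of :class:`PeptideRecord`.

    Sequences are upper-cased; whitespace and line breaks are stripped by the
    FASTA parser.  Raises ``FileNotFoundError`` for a missing file and
    ``ValueError`` for an empty file or an illegal residue (with its position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [
        PeptideRecord(name=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"empty file: no FASTA entries in {path}")
    return records


def load_ptm() -> PeptideRecord:
    """The packaged protamine fixture."""
    return read_fasta(PTM_FASTA)[0]


def net_charge(peptide: PeptideRecord, model: ChargeModel | None = None) -> int:
    """Net charge in e units under the side-chain counting model."""
    model = model or ChargeModel()
    q = sum(
        (ch in model.basic_residues) - (ch in model.acidic_residues)
        for ch in peptide.sequence
    )
    if model.include_termini:
        q += 1 - 1  # +1 amino terminus, -1 carboxy terminus: net zero
    return q


def residue_count(peptide: PeptideRecord, residue: str) -> int:
    """Occurrences of a one-letter residue code in the sequence."""
    residue = residue.upper()
    if len(residue) != 1 or residue not in AMINO_ACIDS:
        raise ValueError(f"invalid residue code {residue!r}")
    return peptide.sequence.count(residue)


def counterion_stoichiometry(peptide_charge: int, counterion_valence: int) -> int:
    """Minimum number of counterions needed to neutralise the peptide charge.

    ``ceil(|q| / |z_counterion|)``; e.g. (+21, -2) -> 11 sulfates.
    """
    if counterion_valence == 0:
        raise ValueError("counterion valence must be nonzero")
    if peptide_charge == 0:
        return 0
    if peptide_charge * counterion_valence > 0:
        raise ValueError(
            "counterion valence must be opposite in sign to the peptide charge"
        )
    return math.ceil(abs(peptide_charge) / abs(counterion_valence))


def molecular_mass(peptide: PeptideRecord, monoisotopic: bool = False) -> float:
    """Free-base peptide mass in Da (convenience; excludes any counterions)."""
    return molecular_weight(
        peptide.sequence, seq_type="protein", monoisotopic=monoisotopic
    )


def peptide_report(peptide: PeptideRecord, model: ChargeModel | None = None) -> dict:
    """JSON-ready summary: length, Arg count, net charge, counterion count."""
    model = model or ChargeModel()
    q = net_charge(peptide, model)
    return {
        "name": peptide.name,
        "length": len(peptide),
        "arg_count": residue_count(peptide, "R"),
        "net_charge_e": q,
        "counterion_valence_e": model.counterion_valence,
        "counterion_count": counterion_stoichiometry(q, model.counterion_valence)
        if q != 0
        else 0,
        "mass_da": round(molecular_mass(peptide), 2),
    }
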