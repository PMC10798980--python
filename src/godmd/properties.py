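"""Residue-level bead properties: masses, charges and hydropathy classes.

Masses come from Biopython's average amino-acid weights, so a chain of bead
masses always sums back to the peptide average molecular mass (minus one
water).  Charges follow the standard neutral-pH convention (Asp/Glu −1,
Lys/Arg +1, His neutral by default) and the hydrophobic class is the
positive half of the Kyte–Doolittle hydropathy scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1, protein_weights
from Bio.SeqUtils import molecular_weight

from .constants import WATER_MASS

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Residues with a positive Kyte–Doolittle hydropathy index.
KD_HYDROPHOBIC = set("ACFILMV")

HYDRO_HYDROPHOBIC = "hydrophobic"
HYDRO_POLAR = "polar"
HYDRO_CATION = "charged+"
HYDRO_ANION = "charged-"
HYDRO_CLASSES = (HYDRO_HYDROPHOBIC, HYDRO_POLAR, HYDRO_CATION, HYDRO_ANION)

THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: Average residue mass (free amino acid minus one water), Da.
RESIDUE_MASS = {aa: protein_weights[aa] - WATER_MASS for aa in VALID_AA}


@dataclass(frozen=True)
class SequenceRecord:
    """A named one-letter amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        for pos, letter in enumerate(self.sequence, start=1):
            if letter not in VALID_AA:
                raise ValueError(
                    f"invalid amino-acid letter {letter!r} at position {pos} "
                    f"of sequence {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def residue_charge(aa: str, histidine_charge: float = 0.0) -> float:
    """Formal charge of a residue at neutral pH."""
    if aa in "DE":
        return -1.0
    if aa in "KR":
        return 1.0
    if aa == "H":
        return histidine_charge
    return 0.0


def residue_hydro_class(aa: str, histidine_charge: float = 0.0) -> str:
    q = residue_charge(aa, histidine_charge)
    if q > 0:
        return HYDRO_CATION
    if q < 0:
        return HYDRO_ANION
    if aa in KD_HYDROPHOBIC:
        return HYDRO_HYDROPHOBIC
    return HYDRO_POLAR


def peptide_average_mass(seq: SequenceRecord | str) -> float:
    """Average molecular mass of an unmodified linear peptide in Da.

    Sum of average residue masses plus one water; no terminal amidation or
    disulfide correction.
    """
    record = seq if isinstance(seq, SequenceRecord) else SequenceRecord("seq", seq)
    if len(record) == 0:
        raise ValueError("empty sequence")
    return molecular_weight(record.sequence, seq_type="protein", monoisotopic=False)


def one_letter(residue_name: str) -> str:
    """Normalise a residue name (1- or 3-letter) to its one-letter code."""
    name = residue_name.strip().upper()
    if len(name) == 1:
        if name not in VALID_AA:
            raise ValueError(f"unknown residue code {residue_name!r}")
        return name
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    raise ValueError(f"unknown residue code {residue_name!r}")


def assign_bead_properties(
    structure,
    sequences: dict[str, SequenceRecord] | None = None,
    *,
    histidine_charge: float = 0.0,
    hard_radius: float = 2.0,
) -> pd.DataFrame:
    """Per-bead property table (mass, charge, hydropathy class, hard radius).

    Parameters
    ----------
    structure:
        A :class:`~godmd.structures.CoarseStructure`.
    sequences:
        Optional map chain id → :class:`SequenceRecord`.  When given, each
        chain's sequence must match its residue count and overrides the
        residue names stored on the structure.
    histidine_charge:
        Formal charge assigned to His (0 at neutral pH by default).
    hard_radius:
        Excluded-volume radius per bead in Å (Cα scheme default 2.0, so two
        beads exclude each other below 4 Å).

    In the backbone-only scheme each bead carries the whole residue's average
    mass; in the two-bead scheme the backbone bead carries a glycine-like
    backbone share and the sidechain bead the remainder.
    """
    letters: list[str] = []
    if sequences is not None:
        per_chain_count: dict[str, int] = {}
        for cid, res in zip(structure.chain_ids, structure.residue_index):
            per_chain_count[cid] = max(per_chain_count.get(cid, 0), int(res))
        for cid, rec in sequences.items():
            if cid in per_chain_count and per_chain_count[cid] != len(rec):
                raise ValueError(
                    f"sequence length {len(rec)} does not match residue count "
                    f"{per_chain_count[cid]} of chain {cid!r}"
                )
    for i in range(structure.n_beads):
        cid = structure.chain_ids[i]
        if sequences is not None and cid in sequences:
            letters.append(sequences[cid].sequence[structure.residue_index[i] - 1])
        else:
            letters.append(one_letter(structure.residue_names[i]))

    backbone_share = RESIDUE_MASS["G"]
    masses = []
    for i, aa in enumerate(letters):
        full = RESIDUE_MASS[aa]
        if structure.bead_kinds[i] == "sidechain":
            masses.append(max(full - backbone_share, 1.0))
        elif _has_sidechain_bead(structure, i):
            masses.append(backbone_share)
        else:
            masses.append(full)

    return pd.DataFrame(
        {
            "chain_id": list(structure.chain_ids),
            "residue_index": structure.residue_index,
            "residue_letter": letters,
            "bead_kind": list(structure.bead_kinds),
            "mass": masses,
            "charge": [residue_charge(a, histidine_charge) for a in letters],
            "hydro_class": [residue_hydro_class(a, histidine_charge) for a in letters],
            "hard_radius": [hard_radius] * structure.n_beads,
        }
    )


def _has_sidechain_bead(structure, i: int) -> bool:
    """True if bead i (a backbone bead) shares its residue with a sidechain bead."""
    cid = structure.chain_ids[i]
    res = structure.residue_index[i]
    for j in range(max(0, i - 2), min(structure.n_beads, i + 3)):
        if (
            j != i
            and structure.chain_ids[j] == cid
            and structure.residue_index[j] == res
            and structure.bead_kinds[j] == "sidechain"
        ):
            return True
    return False


#: The 42-residue amyloid-beta peptide, as used for all ligand species.
ABETA42 = SequenceRecord("Abeta42", "DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA")

#: Human alpha-synuclein, 140 residues.
ALPHA_SYNUCLEIN = SequenceRecord(
    "alpha-synuclein",
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYVGSKTKEGVVHGVATVAEKTKEQ"
    "VTNVGGAVVTGVTAVAQKTVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDPDNEA"
    "YEMPSEEGYQDYEPEA",
)
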