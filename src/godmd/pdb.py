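"""Coarse-grain standard PDB content to one or two beads per residue.

Only ATOM records of the first model are considered.  altLoc conflicts are
resolved by first occurrence; insertion codes are rejected rather than
silently renumbered.  Fixed-column parsing is done here directly because the
error contract (line numbers for malformed records, chain/residue names for
missing Cα atoms) must survive into the exceptions.
"""

from __future__ import annotations

import numpy as np

from .structures import CoarseStructure


def read_pdb_coarse(pdb_text: str, scheme: str = "backbone-only") -> CoarseStructure:
    """Parse PDB text into a :class:`CoarseStructure`.

    scheme ``backbone-only``: one bead per residue at the Cα position.
    scheme ``backbone+sidechain``: Cα plus Cβ beads (glycine gets Cα only).
    """
    if scheme not in ("backbone-only", "backbone+sidechain"):
        raise ValueError(f"unknown coarse-graining scheme {scheme!r}")

    atoms: dict[tuple[str, int], dict[str, tuple[str, np.ndarray]]] = {}
    order: list[tuple[str, int]] = []
    res_names: dict[tuple[str, int], str] = {}
    seen_altloc: set[tuple[str, int, str]] = set()
    in_first_model = True
    saw_atom = False

    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.strip() == "ENDMDL":
            in_first_model = False
        if not in_first_model or not rec.startswith("ATOM"):
            continue
        saw_atom = True
        if len(line) < 54:
            raise ValueError(f"malformed ATOM record at line {lineno}: too short")
        atom_name = line[12:16].strip()
        alt_loc = line[16]
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        try:
            res_seq = int(line[22:26])
            xyz = np.array(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
        except ValueError as exc:
            raise ValueError(f"malformed ATOM record at line {lineno}: {exc}") from exc
        icode = line[26]
        if icode.strip():
            raise ValueError(
                f"insertion code {icode!r} at chain {chain_id} residue {res_seq} "
                f"(line {lineno}) is not supported"
            )
        key = (chain_id, res_seq)
        altkey = (chain_id, res_seq, atom_name)
        if alt_loc.strip() and altkey in seen_altloc:
            continue  # keep the first altLoc occurrence
        seen_altloc.add(altkey)
        if key not in atoms:
            atoms[key] = {}
            order.append(key)
            res_names[key] = res_name
        atoms[key].setdefault(atom_name, (res_name, xyz))

    if not saw_atom:
        raise ValueError("no ATOM records found")

    chain_ids: list[str] = []
    residue_index: list[int] = []
    residue_names: list[str] = []
    bead_kinds: list[str] = []
    positions: list[np.ndarray] = []
    for chain_id, res_seq in order:
        rec_atoms = atoms[(chain_id, res_seq)]
        name = res_names[(chain_id, res_seq)]
        if "CA" not in rec_atoms:
            raise ValueError(f"missing CA atom for chain {chain_id} residue {res_seq}")
        chain_ids.append(chain_id)
        residue_index.append(res_seq)
        residue_names.append(name)
        bead_kinds.append("backbone")
        positions.append(rec_atoms["CA"][1])
        if scheme == "backbone+sidechain" and name != "GLY" and "CB" in rec_atoms:
            chain_ids.append(chain_id)
            residue_index.append(res_seq)
            residue_names.append(name)
            bead_kinds.append("sidechain")
            positions.append(rec_atoms["CB"][1])

    return CoarseStructure(
        chain_ids=chain_ids,
        residue_index=np.array(residue_index),
        residue_names=residue_names,
        bead_kinds=bead_kinds,
        positions=np.vstack(positions),
    )
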