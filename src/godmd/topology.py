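"""Build a runnable topology from a coarse structure.

The Hamiltonian mirrors the structure-based (Gō) construction used for
coarse-grained DMD: covalent geometry as infinite square wells (bonds at
±2%, next-nearest pseudo-bonds at ±5% as an angle surrogate), native
contacts as single attractive square wells of 0.4 kcal/mol (~0.67 kBT at
300 K) at ±15% of the reference distance, rigid cross-links at annotated
calcium-site residues, and class-pair non-bonded step potentials (hard
core, hydrophobic well, Debye-Hückel screened electrostatics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import KB, PN_ANGSTROM_TO_KCAL_PER_MOL, kbt
from .potentials import (
    StepPotential,
    discretize_pair_potential,
    hard_sphere,
    hydrophobic_well,
)
from .properties import (
    HYDRO_ANION,
    HYDRO_CATION,
    HYDRO_CLASSES,
    HYDRO_HYDROPHOBIC,
    SequenceRecord,
    assign_bead_properties,
)
from .structures import CoarseStructure

#: Canonical Gō contact well depth, kcal/mol (≈ 0.67 kBT at 300 K).
GO_CONTACT_ENERGY = 0.4


def go_energy_in_kbt(epsilon: float = GO_CONTACT_ENERGY, temperature: float = 300.0) -> float:
    """Express a contact energy in units of kBT at the given temperature."""
    return epsilon / kbt(temperature)


@dataclass(frozen=True)
class BondConstraint:
    """Infinite square well keeping a bead pair within [d_min, d_max]."""

    i: int
    j: int
    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("bond constraint requires 0 < d_min < d_max")


@dataclass(frozen=True)
class NativeContact:
    """Attractive square well of depth epsilon around a reference distance."""

    i: int
    j: int
    epsilon: float
    r_ref: float
    well_width: float = 0.15

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("contact energy must be positive")
        if self.r_ref <= 0:
            raise ValueError("reference distance must be positive")

    @property
    def outer_radius(self) -> float:
        return self.r_ref * (1.0 + self.well_width)

    @property
    def inner_radius(self) -> float:
        return self.r_ref * (1.0 - self.well_width)


@dataclass(frozen=True)
class ForceProtocol:
    """Constant pulling force as a discretized linear potential.

    The force is realised as parallel energy planes spaced ``delta`` along
    ``direction``; each plane crossing changes the steering energy by
    F·δ (split equally over the pulled beads by default).
    """

    magnitude_pn: float
    direction: tuple[float, float, float]
    delta: float = 0.5
    share_rule: str = "equal"

    def __post_init__(self) -> None:
        if self.magnitude_pn < 0:
            raise ValueError("force magnitude must be non-negative")
        if self.delta <= 0:
            raise ValueError("plane spacing delta must be positive")
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.share_rule not in ("equal", "single"):
            raise ValueError("share_rule must be 'equal' or 'single'")

    @property
    def energy_per_plane(self) -> float:
        """Total energy change per plane crossing, kcal/mol (before sharing)."""
        return self.magnitude_pn * PN_ANGSTROM_TO_KCAL_PER_MOL * self.delta


def build_force_protocol(
    force_pn: float, direction, delta: float = 0.5, share_rule: str = "equal"
) -> ForceProtocol:
    """Normalise the direction and wrap the constant-force parameters."""
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    return ForceProtocol(force_pn, (float(d[0]), float(d[1]), float(d[2])), delta, share_rule)


@dataclass
class Topology:
    """Everything the engine needs: per-bead properties and all interactions."""

    structure: CoarseStructure
    properties: pd.DataFrame
    bonds: list[BondConstraint]
    contacts: list[NativeContact]
    nonbonded: dict[tuple[str, str], StepPotential]
    immobilized: np.ndarray
    pulled: np.ndarray
    interface_contacts: list[NativeContact] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.immobilized = np.asarray(self.immobilized, dtype=np.int64)
        self.pulled = np.asarray(self.pulled, dtype=np.int64)
        n = self.structure.n_beads
        if np.intersect1d(self.immobilized, self.pulled).size:
            raise ValueError("immobilized and pulled bead sets overlap")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError("bond references missing beads")
        for c in self.contacts:
            if not (0 <= c.i < n and 0 <= c.j < n):
                raise ValueError("contact references missing beads")

    @property
    def n_beads(self) -> int:
        return self.structure.n_beads

    @property
    def masses(self) -> np.ndarray:
        return self.properties["mass"].to_numpy(dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return self.properties["charge"].to_numpy(dtype=float)

    def nonbonded_for(self, class_i: str, class_j: str) -> StepPotential:
        key = tuple(sorted((class_i, class_j)))
        return self.nonbonded[key]

    def mobilized(self) -> "Topology":
        """Copy with no immobilized beads (used for unrestrained binding runs)."""
        return replace(self, immobilized=np.array([], dtype=np.int64))


@dataclass(frozen=True)
class TopologyOptions:
    """Knobs of the coarse Hamiltonian (all energies kcal/mol, lengths Å)."""

    contact_energy: float = GO_CONTACT_ENERGY
    contact_well_width: float = 0.15
    contact_cutoff: float = 6.5
    min_seq_separation: int = 3
    bond_tolerance: float = 0.02
    pseudo_bond_tolerance: float = 0.05
    calcium_tolerance: float = 0.01
    hard_core: float = 4.0
    hydrophobic_depth: float = 0.75
    hydrophobic_width: float = 2.0
    electrostatic_steps: int = 4
    electrostatic_cutoff: float = 12.0
    screening_length: float = 10.0
    dielectric: float = 80.0
    histidine_charge: float = 0.0


def find_native_contacts(
    structure: CoarseStructure,
    cutoff: float = 6.5,
    min_seq_separation: int = 3,
    epsilon: float = GO_CONTACT_ENERGY,
    well_width: float = 0.15,
) -> list[NativeContact]:
    """All bead pairs within ``cutoff`` in the reference structure.

    Within a chain, pairs closer in sequence than ``min_seq_separation``
    are excluded (their geometry is carried by bonds and pseudo-bonds);
    across chains every pair inside the cutoff counts.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = cKDTree(structure.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts = []
    for i, j in sorted(map(tuple, pairs)):
        same_chain = structure.chain_ids[i] == structure.chain_ids[j]
        sep = abs(int(structure.residue_index[i]) - int(structure.residue_index[j]))
        if same_chain and sep < min_seq_separation:
            continue
        r = float(np.linalg.norm(structure.positions[i] - structure.positions[j]))
        contacts.append(NativeContact(int(i), int(j), epsilon, r, well_width))
    return contacts


def _class_potentials(options: TopologyOptions) -> dict[tuple[str, str], StepPotential]:
    table: dict[tuple[str, str], StepPotential] = {}
    hh = hydrophobic_well(options.hard_core, options.hydrophobic_depth, options.hydrophobic_width)
    plain = hard_sphere(options.hard_core)
    charge_of = {HYDRO_CATION: 1.0, HYDRO_ANION: -1.0}
    for a in HYDRO_CLASSES:
        for b in HYDRO_CLASSES:
            key = tuple(sorted((a, b)))
            if key in table:
                continue
            if a in charge_of and b in charge_of:
                table[key] = discretize_pair_potential(
                    "screened-coulomb",
                    {
                        "core": options.hard_core,
                        "q1q2": charge_of[a] * charge_of[b],
                        "screening_length": options.screening_length,
                        "dielectric": options.dielectric,
                    },
                    n_steps=options.electrostatic_steps,
                    r_max=options.electrostatic_cutoff,
                )
            elif a == HYDRO_HYDROPHOBIC and b == HYDRO_HYDROPHOBIC:
                table[key] = hh
            else:
                table[key] = plain
    return table


def build_topology(
    structure: CoarseStructure,
    sequences: dict[str, SequenceRecord] | None = None,
    options: TopologyOptions = TopologyOptions(),
) -> Topology:
    """Assemble the full topology from a structure and its sequences.

    Native contacts are detected geometrically at the contact cutoff and
    merged with any annotated pair lists (``interface``, ``inter_peptide``),
    so the annotated interface is guaranteed to be part of the Hamiltonian.
    Calcium-site beads are cross-linked pairwise within each chain.
    """
    props = assign_bead_properties(
        structure, sequences, histidine_charge=options.histidine_charge
    )
    pos = structure.positions

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(pos[i] - pos[j]))

    bonds: list[BondConstraint] = []
    for chain in structure.chains:
        idx = structure.chain_indices(chain)
        bb = [int(i) for i in idx if structure.bead_kinds[i] == "backbone"]
        for a, b in zip(bb[:-1], bb[1:]):
            r = dist(a, b)
            bonds.append(BondConstraint(a, b, r * (1 - options.bond_tolerance),
                                        r * (1 + options.bond_tolerance)))
        for a, b in zip(bb[:-2], bb[2:]):
            r = dist(a, b)
            bonds.append(BondConstraint(a, b, r * (1 - options.pseudo_bond_tolerance),
                                        r * (1 + options.pseudo_bond_tolerance)))

    ca = structure.annotations.get("calcium_sites", np.array([], dtype=np.int64))
    for chain in structure.chains:
        beads = [int(i) for i in ca if structure.chain_ids[i] == chain]
        for a_pos in range(len(beads)):
            for b_pos in range(a_pos + 1, len(beads)):
                a, b = beads[a_pos], beads[b_pos]
                r = dist(a, b)
                bonds.append(BondConstraint(a, b, r * (1 - options.calcium_tolerance),
                                            r * (1 + options.calcium_tolerance)))

    contacts = find_native_contacts(
        structure,
        cutoff=options.contact_cutoff,
        min_seq_separation=options.min_seq_separation,
        epsilon=options.contact_energy,
        well_width=options.contact_well_width,
    )
    have = {(c.i, c.j) for c in contacts}
    for name in ("interface", "inter_peptide", "domain_swap"):
        for a, b in structure.pair_annotations.get(name, []):
            key = (min(a, b), max(a, b))
            if key not in have:
                contacts.append(
                    NativeContact(key[0], key[1], options.contact_energy,
                                  dist(*key), options.contact_well_width)
                )
                have.add(key)
    contacts.sort(key=lambda c: (c.i, c.j))

    dimer_chains = set()
    for name in ("immobilized_domain", "flexible_domain"):
        for i in structure.annotations.get(name, []):
            dimer_chains.add(structure.chain_ids[int(i)])
    if not dimer_chains:
        dimer_chains = set(structure.chains[:2])
    interface = [
        c
        for c in contacts
        if structure.chain_ids[c.i] != structure.chain_ids[c.j]
        and structure.chain_ids[c.i] in dimer_chains
        and structure.chain_ids[c.j] in dimer_chains
    ]

    return Topology(
        structure=structure,
        properties=props,
        bonds=bonds,
        contacts=contacts,
        nonbonded=_class_potentials(options),
        immobilized=structure.annotations.get("immobilized_domain", np.array([], dtype=np.int64)),
        pulled=structure.annotations.get("flexible_domain", np.array([], dtype=np.int64)),
        interface_contacts=interface,
    )
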