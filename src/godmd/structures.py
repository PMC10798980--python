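"""Synthetic coarse-grained structures: toy dimer, amyloid-like ligands, placement.

The toy dimer emulates a strand-swapped cadherin EC1 trans dimer at one bead
per residue: two compact serpentine sheets facing each other, joined by a
small, explicit set of interface contact pairs, a fraction of which lie in
the N-terminal segments of both chains (the "domain swap"), plus rigid
cross-links at designated calcium-site residues.  Ligands come in three
classes that differ in conformational rigidity: a flexible extended monomer
(no intra-chain native contacts), a compact oligomer globule (dense intra
contacts), and a rigid multi-chain seed stack with inter-peptide contacts —
mirroring an amyloid monomer, oligomer and fibril seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .properties import residue_charge

#: Distance between consecutive backbone beads (Cα–Cα), Å.
CA_SPACING = 3.8

#: Cutoff used by the builders when realising/auditing native contacts, Å.
BUILDER_CONTACT_CUTOFF = 6.5

#: Minimum sequence separation for an intra-chain native contact.
BUILDER_MIN_SEQ_SEP = 3

BeadKind = Literal["backbone", "sidechain"]


@dataclass
class CoarseStructure:
    """A coarse-grained assembly: one or two beads per residue.

    ``annotations`` holds named bead-index sets (``interface``,
    ``domain_swap``, ``calcium_sites``, ``immobilized_domain``,
    ``flexible_domain``, ``ligand`` ...), ``pair_annotations`` named
    bead-index pairs consumed by the topology builder.
    """

    chain_ids: list[str]
    residue_index: np.ndarray
    residue_names: list[str]
    bead_kinds: list[str]
    positions: np.ndarray
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    pair_annotations: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    box_edge: float | None = None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.annotations = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.annotations.items()
        }

    @property
    def n_beads(self) -> int:
        return len(self.chain_ids)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c)
        return list(seen)

    def chain_indices(self, chain_id: str) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.chain_ids) if c == chain_id], dtype=np.int64
        )

    def validate(self, min_pair_distance: float = 1.0) -> None:
        """Check all structural invariants; raise ``ValueError`` on violation."""
        n = self.n_beads
        if self.positions.shape != (n, 3):
            raise ValueError("positions shape does not match bead count")
        for chain in self.chains:
            idx = self.chain_indices(chain)
            res = self.residue_index[idx]
            bb = [i for i in idx if self.bead_kinds[i] == "backbone"]
            bb_res = self.residue_index[bb]
            if np.any(np.diff(bb_res) <= 0):
                raise ValueError(f"residue_index not strictly increasing in chain {chain!r}")
            if np.any(np.diff(res) < 0):
                raise ValueError(f"residue_index decreases in chain {chain!r}")
            for a, b in zip(bb[:-1], bb[1:]):
                d = float(np.linalg.norm(self.positions[a] - self.positions[b]))
                if not (2.0 <= d <= 6.0):
                    raise ValueError(
                        f"consecutive backbone beads {a},{b} of chain {chain!r} "
                        f"separated by {d:.2f} Å (allowed 2.0–6.0)"
                    )
        if n >= 2:
            tree = cKDTree(self.positions)
            pairs = tree.query_pairs(min_pair_distance, output_type="ndarray")
            if len(pairs):
                i, j = pairs[0]
                raise ValueError(
                    f"beads {i} and {j} closer than {min_pair_distance} Å"
                )
        for name, idx in self.annotations.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"annotation {name!r} references missing beads")
        for name, pairs_ in self.pair_annotations.items():
            for a, b in pairs_:
                if not (0 <= a < n and 0 <= b < n):
                    raise ValueError(f"pair annotation {name!r} references missing beads")


@dataclass(frozen=True)
class LigandSpec:
    """Recipe for one amyloid-like ligand class."""

    kind: Literal["monomer", "oligomer", "seed"]
    n_residues_per_chain: int
    n_chains: int = 1
    intra_contact_density: float = 0.0
    inter_peptide_contact_energy: float = 0.4
    net_charge_sign: Literal["negative", "positive", "neutral"] = "negative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("monomer", "oligomer", "seed"):
            raise ValueError(f"unknown ligand kind {self.kind!r}")
        if self.kind != "seed" and self.n_chains != 1:
            raise ValueError("n_chains must be 1 for monomer/oligomer ligands")
        if self.kind == "monomer" and self.intra_contact_density != 0.0:
            raise ValueError("monomer ligands have intra_contact_density 0")
        if not 0.0 <= self.intra_contact_density <= 1.0:
            raise ValueError("intra_contact_density must lie in [0, 1]")
        if self.n_residues_per_chain < 2:
            raise ValueError("need at least 2 residues per chain")


def default_ligand_specs(seed: int = 0) -> dict[str, LigandSpec]:
    """The three study ligand classes at desk scale.

    Sizes mirror the relative scale of an amyloid monomer, a small oligomer
    and a four-chain fibril seed while keeping the whole system small enough
    to run many replicas; all species carry net negative charge, as the
    amyloid-beta peptide does at neutral pH.
    """
    return {
        "monomer": LigandSpec("monomer", 12, seed=seed),
        "oligomer": LigandSpec("oligomer", 16, intra_contact_density=0.8, seed=seed),
        "seed": LigandSpec("seed", 8, n_chains=4, seed=seed),
    }


# ---------------------------------------------------------------------------
# sequence patterns


def _pattern_sequence(n: int, charge_positions: dict[int, str]) -> str:
    """Alternating hydrophobic/polar backbone with charges at given 0-based slots."""
    letters = []
    for i in range(n):
        if i in charge_positions:
            letters.append(charge_positions[i])
        elif i % 2 == 0:
            letters.append("L")
        else:
            letters.append("S")
    return "".join(letters)


def _ligand_sequence(n: int, sign: str) -> str:
    n_charged = max(1, n // 6)
    slots = np.linspace(1, n - 2, n_charged).round().astype(int) if n > 2 else [0]
    if sign == "negative":
        charges = {int(s): "D" for s in slots}
    elif sign == "positive":
        charges = {int(s): "K" for s in slots}
    else:
        charges = {}
        for k, s in enumerate(slots):
            charges[int(s)] = "D" if k % 2 else "K"
        if len(slots) % 2:  # unpaired charge would break neutrality
            charges.pop(int(slots[-1]))
    # amyloidogenic peptides are strongly hydrophobic: two of every three
    # non-charged residues are aliphatic
    letters = []
    for i in range(n):
        if i in charges:
            letters.append(charges[i])
        elif i % 3 == 2:
            letters.append("S")
        else:
            letters.append("L")
    seq = "".join(letters)
    total = sum(residue_charge(a) for a in seq)
    want = {"negative": -1, "positive": 1, "neutral": 0}[sign]
    if np.sign(total) != want:
        raise ValueError(f"could not realise net charge sign {sign!r} for n={n}")
    return seq


def _dimer_sequence(n: int, interface_slots: set[int]) -> str:
    """Dimer chain sequence: hydrophobic interface, charged patches elsewhere.

    Cationic (K) and anionic (D) residues are placed on a regular period so
    the dimer surface shows both charge signs, as the cadherin EC1 surface
    does (cationic turn regions next to acidic calcium-binding stretches).
    """
    flank = {
        i + d for i in interface_slots for d in (-1, 1) if 0 <= i + d < n
    } - interface_slots
    letters = []
    for i in range(n):
        if i in interface_slots:
            letters.append("V")
        elif i in flank:
            letters.append("A")  # hydrophobic shoulders of the interface strip
        elif i % 5 == 2:
            letters.append("K")
        elif i % 5 == 4:
            letters.append("D")
        elif i % 2 == 0:
            letters.append("S")
        else:
            letters.append("T")
    return "".join(letters)


# ---------------------------------------------------------------------------
# generators


def _serpentine(n: int, row_len: int, spacing: float, row_gap: float) -> np.ndarray:
    """Planar serpentine of n beads: rows of row_len, adjacent rows reversed."""
    pos = np.zeros((n, 3))
    for i in range(n):
        row, col = divmod(i, row_len)
        x = col if row % 2 == 0 else row_len - 1 - col
        pos[i] = (x * spacing, row * row_gap, 0.0)
    return pos


def generate_toy_dimer(
    n_per_chain: int,
    n_interface_contacts: int,
    swap_fraction: float,
    calcium_site_indices: list[int] | None = None,
    seed: int = 0,
    *,
    interface_separation: float = 6.0,
    sheet_gap: float = 10.5,
    jitter: float = 0.1,
) -> CoarseStructure:
    """Build the two-chain toy dimer with an annotated swapped interface.

    Two compact serpentine sheets (chains A, B) face each other across
    ``sheet_gap``; exactly ``n_interface_contacts`` opposed bead pairs are
    pushed together to ``interface_separation`` (inside the contact cutoff)
    and annotated as the interface.  ``round(swap_fraction × n)`` of those
    pairs are drawn from both chains' N-terminal thirds and annotated
    ``domain_swap``.  Chain A is annotated as the immobilized domain, chain B
    as the flexible one.
    """
    if n_per_chain < 10:
        raise ValueError("n_per_chain must be at least 10")
    if n_interface_contacts < 1:
        raise ValueError("need at least one interface contact")
    if n_interface_contacts > n_per_chain:
        raise ValueError(
            f"infeasible contact count: {n_interface_contacts} contacts need "
            f"{n_interface_contacts} distinct residues but chains have {n_per_chain}"
        )
    n_swap = int(round(swap_fraction * n_interface_contacts))
    nterm = max(1, n_per_chain // 3)
    if n_swap > nterm:
        raise ValueError(
            f"infeasible swap count: {n_swap} domain-swap pairs exceed the "
            f"N-terminal segment of {nterm} residues"
        )
    rng = np.random.default_rng(seed)
    row_len = max(4, int(np.ceil(np.sqrt(n_per_chain))) + 1)

    base = _serpentine(n_per_chain, row_len, CA_SPACING, 5.0)
    pos_a = base.copy()
    pos_b = base.copy()
    pos_b[:, 2] += sheet_gap

    # the interface is one contiguous N-terminal-anchored band, mimicking a
    # localized strand-swap interface; the C-terminal end of the groove stays
    # open (no cross-chain contacts there)
    swap_sel = np.arange(n_swap)
    n_rest = n_interface_contacts - n_swap
    if n_rest > n_per_chain - nterm:
        raise ValueError(
            "infeasible contact count: not enough non-N-terminal residues "
            "for the requested non-swap interface pairs"
        )
    rest_sel = np.arange(n_swap, n_interface_contacts)
    contact_res = np.concatenate([swap_sel, rest_sel]).astype(int)

    push = (sheet_gap - interface_separation) / 2.0
    pos_a[contact_res, 2] += push
    pos_b[contact_res, 2] -= push

    pos_a += rng.uniform(-jitter, jitter, size=pos_a.shape)
    pos_b += rng.uniform(-jitter, jitter, size=pos_b.shape)

    seq = _dimer_sequence(n_per_chain, set(int(i) for i in contact_res))
    n = n_per_chain
    chain_ids = ["A"] * n + ["B"] * n
    residue_index = np.concatenate([np.arange(1, n + 1)] * 2)
    residue_names = list(seq) * 2
    bead_kinds = ["backbone"] * (2 * n)
    positions = np.vstack([pos_a, pos_b])

    iface_pairs = [(int(i), int(i) + n) for i in contact_res]
    swap_pairs = [(int(i), int(i) + n) for i in swap_sel]
    calcium = []
    if calcium_site_indices:
        kept = sorted({int(r) for r in calcium_site_indices if 1 <= r <= n})
        for r in kept:
            calcium.extend([r - 1, r - 1 + n])

    structure = CoarseStructure(
        chain_ids=chain_ids,
        residue_index=residue_index,
        residue_names=residue_names,
        bead_kinds=bead_kinds,
        positions=positions,
        annotations={
            "interface": np.unique([b for p in iface_pairs for b in p]),
            "domain_swap": np.unique([b for p in swap_pairs for b in p]),
            "calcium_sites": np.array(calcium, dtype=np.int64),
            "immobilized_domain": np.arange(n),
            "flexible_domain": np.arange(n, 2 * n),
        },
        pair_annotations={"interface": iface_pairs, "domain_swap": swap_pairs},
    )
    structure.validate()
    return structure


def _count_intra_contacts(
    pos: np.ndarray, cutoff: float = BUILDER_CONTACT_CUTOFF, min_sep: int = BUILDER_MIN_SEQ_SEP
) -> int:
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if not len(pairs):
        return 0
    return int(np.sum(np.abs(pairs[:, 0] - pairs[:, 1]) >= min_sep))


def _snake_block(
    n: int, row_len: int, rows: int, layers: int, spacing: float
) -> np.ndarray:
    """Boustrophedon walk through a 3D grid: every consecutive pair adjacent."""
    cells: list[tuple[int, int, int]] = []
    xdir = 1
    for l in range(layers):
        row_iter = range(rows) if l % 2 == 0 else range(rows - 1, -1, -1)
        for r in row_iter:
            cols = range(row_len) if xdir == 1 else range(row_len - 1, -1, -1)
            for c in cols:
                cells.append((c, r, l))
            xdir = -xdir
            if len(cells) >= n:
                break
        if len(cells) >= n:
            break
    pos = np.array(cells[:n], dtype=float) * spacing
    return pos


def _extended_chain(n: int, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * CA_SPACING
    pos[:, 1:] += rng.uniform(-jitter, jitter, size=(n, 2))
    return pos


def generate_ligand(spec: LigandSpec) -> CoarseStructure:
    """Realise one ligand class as a coarse structure.

    monomer → extended flexible chain, zero intra-chain native contacts;
    oligomer → compact block whose realised intra-contact count (at the
    builder cutoff) lies within ±20% of ``intra_contact_density × n``;
    seed → ``n_chains`` extended chains stacked at cross-β spacing with
    annotated inter-peptide contact pairs between adjacent chains.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues_per_chain
    seq = _ligand_sequence(n, spec.net_charge_sign)

    if spec.kind == "monomer":
        pos = _extended_chain(n, rng)
        chains = [("L1", pos)]
        pairs: list[tuple[int, int]] = []
    elif spec.kind == "seed":
        chains = []
        for k in range(spec.n_chains):
            pos = _extended_chain(n, rng, jitter=0.15)
            pos[:, 1] += k * 4.8  # cross-beta stacking distance
            chains.append((f"L{k + 1}", pos))
        pairs = [
            (k * n + i, (k + 1) * n + i)
            for k in range(spec.n_chains - 1)
            for i in range(n)
        ]
    else:  # oligomer
        target = spec.intra_contact_density * n
        best: tuple[float, np.ndarray] | None = None
        spacing = 5.5
        for row_len in range(2, n + 1):
            for n_layers in (1, 2, 3):
                rows = int(np.ceil(n / (row_len * n_layers)))
                pos = _snake_block(n, row_len, rows, n_layers, spacing)
                cnt = _count_intra_contacts(pos)
                err = abs(cnt - target)
                if best is None or err < best[0]:
                    best = (err, pos)
        assert best is not None
        pos = best[1] + rng.uniform(-0.2, 0.2, size=(n, 3))
        realized = _count_intra_contacts(pos)
        if target > 0 and not (0.8 * target <= realized <= 1.2 * target):
            raise ValueError(
                f"intra-contact density unreachable: target {target:.1f} contacts, "
                f"best realisable {realized}"
            )
        chains = [("L1", pos)]
        pairs = []

    chain_ids: list[str] = []
    residue_index: list[int] = []
    for cid, _ in chains:
        chain_ids.extend([cid] * n)
        residue_index.extend(range(1, n + 1))
    positions = np.vstack([p for _, p in chains])

    structure = CoarseStructure(
        chain_ids=chain_ids,
        residue_index=np.array(residue_index),
        residue_names=list(seq) * len(chains),
        bead_kinds=["backbone"] * (n * len(chains)),
        positions=positions,
        annotations={"ligand": np.arange(n * len(chains))},
        pair_annotations={"inter_peptide": pairs} if pairs else {},
    )
    structure.validate()
    return structure


def combined_diameter(*structures: CoarseStructure) -> float:
    pos = np.vstack([s.positions for s in structures])
    return float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))


def place_components(
    dimer: CoarseStructure,
    ligand: CoarseStructure | None,
    min_separation: float = 12.0,
    box_edge: float | None = None,
    seed: int = 0,
    *,
    max_separation: float | None = None,
    max_attempts: int = 10000,
) -> CoarseStructure:
    """Drop a randomly oriented ligand near the dimer inside a reflecting box.

    The dimer is centred in the box; the ligand is given a uniformly random
    orientation and a uniformly random centroid, rejected until every
    inter-component bead distance is at least ``min_separation`` (and never
    below the 1 Å hard floor) with all beads inside the box.  When
    ``max_separation`` is given, the closest approach must also not exceed
    it, which keeps the ligand within an encounter shell of the dimer.
    """
    rng = np.random.default_rng(seed)
    if box_edge is None:
        parts = [dimer] if ligand is None else [dimer, ligand]
        box_edge = 4.0 * combined_diameter(*parts)

    dimer_pos = dimer.positions - dimer.positions.mean(axis=0) + box_edge / 2.0
    margin = 1.0
    if np.any(dimer_pos < margin) or np.any(dimer_pos > box_edge - margin):
        raise ValueError("box too small to admit the dimer")

    if ligand is None:
        out = _concat(dimer, None, dimer_pos, None)
        out.box_edge = box_edge
        return out

    lig_local = ligand.positions - ligand.positions.mean(axis=0)
    tree = cKDTree(dimer_pos)
    floor = max(min_separation, 1.0)
    for _ in range(max_attempts):
        rot = Rotation.random(rng=rng)
        centroid = rng.uniform(margin, box_edge - margin, size=3)
        lig_pos = rot.apply(lig_local) + centroid
        if np.any(lig_pos < margin) or np.any(lig_pos > box_edge - margin):
            continue
        dmin, _ = tree.query(lig_pos, k=1)
        closest = dmin.min()
        if closest >= floor and (max_separation is None or closest <= max_separation):
            out = _concat(dimer, ligand, dimer_pos, lig_pos)
            out.box_edge = box_edge
            out.validate()
            return out
    raise RuntimeError(
        f"could not place ligand after {max_attempts} attempts; "
        "try a larger box_edge or smaller min_separation"
    )


def _concat(
    dimer: CoarseStructure,
    ligand: CoarseStructure | None,
    dimer_pos: np.ndarray,
    lig_pos: np.ndarray | None,
) -> CoarseStructure:
    chain_ids = list(dimer.chain_ids)
    residue_index = [dimer.residue_index]
    residue_names = list(dimer.residue_names)
    bead_kinds = list(dimer.bead_kinds)
    positions = [dimer_pos]
    annotations = {k: v.copy() for k, v in dimer.annotations.items()}
    pair_annotations = {k: list(v) for k, v in dimer.pair_annotations.items()}
    if ligand is not None:
        off = dimer.n_beads
        chain_ids += list(ligand.chain_ids)
        residue_index.append(ligand.residue_index)
        residue_names += list(ligand.residue_names)
        bead_kinds += list(ligand.bead_kinds)
        positions.append(lig_pos)
        for k, v in ligand.annotations.items():
            annotations[k] = v + off
        for k, v in ligand.pair_annotations.items():
            pair_annotations[k] = [(a + off, b + off) for a, b in v]
    return CoarseStructure(
        chain_ids=chain_ids,
        residue_index=np.concatenate(residue_index),
        residue_names=residue_names,
        bead_kinds=bead_kinds,
        positions=np.vstack(positions),
        annotations=annotations,
        pair_annotations=pair_annotations,
    )
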