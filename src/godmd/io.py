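"""Plain-text serialization: extended XYZ, TSV energy logs, JSON topologies.

Structures go to extended XYZ with the one-letter residue code in the
element column and chain/residue metadata on the comment line; annotations
travel in a JSON sidecar.  Step potentials export as two-column TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory
from .potentials import StepPotential
from .properties import one_letter
from .structures import CoarseStructure
from .topology import Topology


def _comment_line(structure: CoarseStructure, time: float | None = None) -> str:
    meta = {
        "chains": "".join(structure.chain_ids),
        "residues": ",".join(str(int(r)) for r in structure.residue_index),
        "kinds": "".join("B" if k == "backbone" else "S" for k in structure.bead_kinds),
    }
    if time is not None:
        meta["time"] = round(float(time), 6)
    return json.dumps(meta)


def write_xyz(structure: CoarseStructure, path: str | Path) -> Path:
    """Write a single-frame extended XYZ plus a .json annotation sidecar."""
    path = Path(path)
    lines = [str(structure.n_beads), _comment_line(structure)]
    for i in range(structure.n_beads):
        code = one_letter(structure.residue_names[i])
        x, y, z = structure.positions[i]
        lines.append(f"{code} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "annotations": {k: v.tolist() for k, v in structure.annotations.items()},
                "pair_annotations": {
                    k: [list(p) for p in v] for k, v in structure.pair_annotations.items()
                },
                "box_edge": structure.box_edge,
            },
            indent=1,
        )
    )
    return path


def read_xyz(path: str | Path) -> CoarseStructure:
    """Read a structure written by :func:`write_xyz` (sidecar optional)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    n = int(lines[0])
    meta = json.loads(lines[1])
    chains = list(meta["chains"])
    residues = np.array([int(x) for x in meta["residues"].split(",")])
    kinds = ["backbone" if k == "B" else "sidechain" for k in meta["kinds"]]
    names = []
    pos = np.zeros((n, 3))
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        names.append(parts[0])
        pos[i] = [float(x) for x in parts[1:4]]
    annotations = {}
    pair_annotations = {}
    box_edge = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        extra = json.loads(sidecar.read_text())
        annotations = {k: np.array(v, dtype=np.int64) for k, v in extra["annotations"].items()}
        pair_annotations = {
            k: [tuple(p) for p in v] for k, v in extra["pair_annotations"].items()
        }
        box_edge = extra.get("box_edge")
    return CoarseStructure(
        chain_ids=chains,
        residue_index=residues,
        residue_names=names,
        bead_kinds=kinds,
        positions=pos,
        annotations=annotations,
        pair_annotations=pair_annotations,
        box_edge=box_edge,
    )


def write_trajectory_xyz(
    traj: Trajectory, structure: CoarseStructure, path: str | Path
) -> Path:
    """Multi-frame extended XYZ (one block per sampled frame)."""
    path = Path(path)
    codes = [one_letter(r) for r in structure.residue_names]
    blocks = []
    for f in range(traj.n_frames):
        blocks.append(str(structure.n_beads))
        blocks.append(_comment_line(structure, time=traj.times[f]))
        for i in range(structure.n_beads):
            x, y, z = traj.positions[f, i]
            blocks.append(f"{codes[i]} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(blocks) + "\n")
    return path


def write_energy_log(traj: Trajectory, path: str | Path) -> Path:
    """TSV energy ledger: time, kinetic, potential, steering, total."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time": traj.times,
            "kinetic": traj.kinetic,
            "potential": traj.potential,
            "steering": traj.steering,
            "total": traj.total_energy,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_step_potential(sp: StepPotential, path: str | Path) -> Path:
    """Two-column TSV (radius, energy level inside that radius)."""
    path = Path(path)
    df = pd.DataFrame({"radius": sp.radii, "energy": sp.energies})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def topology_to_dict(topology: Topology) -> dict:
    """JSON-serializable topology description (documented schema)."""
    props = topology.properties
    return {
        "n_beads": topology.n_beads,
        "beads": {
            "chain_id": props["chain_id"].tolist(),
            "residue_index": props["residue_index"].tolist(),
            "mass": props["mass"].round(4).tolist(),
            "charge": props["charge"].tolist(),
            "hydro_class": props["hydro_class"].tolist(),
            "hard_radius": props["hard_radius"].tolist(),
        },
        "bonds": [
            {"i": b.i, "j": b.j, "d_min": round(b.d_min, 6), "d_max": round(b.d_max, 6)}
            for b in topology.bonds
        ],
        "contacts": [
            {
                "i": c.i,
                "j": c.j,
                "epsilon": c.epsilon,
                "r_ref": round(c.r_ref, 6),
                "well_width": c.well_width,
            }
            for c in topology.contacts
        ],
        "nonbonded": {
            f"{a}|{b}": {"radii": list(sp.radii), "energies": [
                None if not np.isfinite(e) else e for e in sp.energies
            ]}
            for (a, b), sp in topology.nonbonded.items()
        },
        "immobilized": topology.immobilized.tolist(),
        "pulled": topology.pulled.tolist(),
        "interface_contacts": [[c.i, c.j] for c in topology.interface_contacts],
    }


def write_topology_json(topology: Topology, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(topology_to_dict(topology), indent=1))
    return path
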