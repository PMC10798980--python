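"""Trajectory readouts: interface-contact survival, first dissociation times
with censoring, binding-frequency maps, RMSF and interaction-class breakdowns.

Dissociation follows the Hamiltonian: an interface contact "survives" in a
frame while the pair sits within its own well outer radius, and the first
dissociation time is the first sampled frame with zero surviving contacts.
Runs that never reach zero are censored at the run duration and enter the
campaign means at that value, matching the convention of plotting fully
associated runs at the full simulation length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import reduced_to_ns
from .engine import Trajectory
from .topology import NativeContact, Topology


@dataclass
class ContactSeries:
    """Surviving interface-contact counts per sampled frame."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.times) != len(self.counts):
            raise ValueError("times and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")


@dataclass(frozen=True)
class DissociationRecord:
    """First dissociation time of one replica, censored at run duration."""

    force: float  # pN
    replicate: int
    dissociation_time: float  # same unit as the series times (ns in campaigns)
    censored: bool

    def __post_init__(self) -> None:
        if self.dissociation_time < 0:
            raise ValueError("dissociation time must be non-negative")


@dataclass
class BindingFrequencyMap:
    """Per-residue contact frequency with the partner group, in [0, 1]."""

    residues: np.ndarray  # (R,) residue labels "chain:index"
    frequency: np.ndarray  # (R,) fractions
    window: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residues, "frequency": self.frequency})


@dataclass
class RMSFProfile:
    """Root-mean-square positional fluctuation per selected bead, Å."""

    bead_indices: np.ndarray
    rmsf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bead": self.bead_indices, "rmsf": self.rmsf})


# ---------------------------------------------------------------------------


def contact_count_series(
    traj: Trajectory,
    interface_contacts: list[NativeContact],
    outer_radii: np.ndarray | None = None,
) -> ContactSeries:
    """Count interface pairs within their well outer radius in each frame."""
    if not interface_contacts:
        raise ValueError("no interface contacts given")
    ii = np.array([c.i for c in interface_contacts])
    jj = np.array([c.j for c in interface_contacts])
    if outer_radii is None:
        outer_radii = np.array([c.outer_radius for c in interface_contacts])
    d = np.linalg.norm(
        traj.positions[:, ii, :] - traj.positions[:, jj, :], axis=2
    )
    counts = (d <= outer_radii[None, :]).sum(axis=1)
    return ContactSeries(traj.times, counts)


def first_dissociation_time(
    series: ContactSeries, duration: float, force: float = 0.0, replicate: int = 0
) -> DissociationRecord:
    """Time of the first zero-contact frame; censored at ``duration`` if none."""
    if len(series.times) == 0:
        raise ValueError("empty contact series")
    zero = np.nonzero(series.counts == 0)[0]
    if len(zero):
        return DissociationRecord(force, replicate, float(series.times[zero[0]]), False)
    return DissociationRecord(force, replicate, float(duration), True)


def _window_slice(n_frames: int, window_fraction: float) -> slice:
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    start = int(np.ceil(n_frames * (1.0 - window_fraction)))
    if start >= n_frames:
        raise ValueError("analysis window contains no frames")
    return slice(start, n_frames)


def binding_frequency(
    traj: Trajectory,
    structure,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 6.5,
    window_fraction: float = 0.4,
) -> BindingFrequencyMap:
    """Fraction of window frames in which each group-A residue touches group B.

    A residue counts as bound in a frame when any of its beads lies within
    ``cutoff`` (default 6.5 Å, i.e. 0.65 nm) of any group-B bead.  The
    symmetric call with the groups swapped gives the partner-side profile.
    """
    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    win = _window_slice(traj.n_frames, window_fraction)
    pos = traj.positions[win]
    d = np.linalg.norm(
        pos[:, group_a, None, :] - pos[:, None, group_b, :], axis=3
    )  # (F, A, B)
    touched = (d <= cutoff).any(axis=2)  # (F, A)

    labels = np.array(
        [f"{structure.chain_ids[i]}:{structure.residue_index[i]}" for i in group_a]
    )
    per_res: dict[str, np.ndarray] = {}
    for k, lab in enumerate(labels):
        per_res.setdefault(lab, np.zeros(touched.shape[0], dtype=bool))
        per_res[lab] |= touched[:, k]
    residues = np.array(list(per_res))
    freq = np.array([per_res[lab].mean() for lab in residues])
    return BindingFrequencyMap(residues, freq, window=f"last {window_fraction:.0%} of frames")


def rmsf(
    traj: Trajectory,
    selection: np.ndarray,
    window_fraction: float = 0.4,
    align_to: str = "none",
    align_selection: np.ndarray | None = None,
) -> RMSFProfile:
    """Per-bead RMSF about the window-mean position after optional alignment.

    ``align_to='none'`` uses raw coordinates (valid when a reference domain
    is immobilized); ``'kabsch'`` superposes every window frame onto the
    first window frame by optimal rigid rotation+translation over
    ``align_selection`` (default: the analysis selection).
    """
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise ValueError("empty selection")
    win = _window_slice(traj.n_frames, window_fraction)
    pos = traj.positions[win][:, selection, :].copy()
    if pos.shape[0] < 2:
        raise ValueError("RMSF needs at least two frames in the window")

    if align_to == "kabsch":
        fit_sel = selection if align_selection is None else np.asarray(align_selection)
        fit = traj.positions[win][:, fit_sel, :]
        ref = fit[0] - fit[0].mean(axis=0)
        for f in range(pos.shape[0]):
            mob = fit[f]
            mob_c = mob.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, mob - mob_c)
            pos[f] = rot.apply(pos[f] - mob_c) + fit[0].mean(axis=0)
    elif align_to == "immobilized-frame":
        pass  # immobilized beads pin the frame; nothing to do
    elif align_to != "none":
        raise ValueError(f"unknown alignment mode {align_to!r}")

    mean = pos.mean(axis=0)
    fluct = np.sqrt(((pos - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(selection, fluct)


def interaction_class_breakdown(
    traj: Trajectory,
    topology: Topology,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 6.5,
    window_fraction: float = 0.4,
) -> pd.DataFrame:
    """Fraction of inter-group bead contacts per unordered hydropathy-class pair.

    Counts every (group A bead, group B bead) pair within ``cutoff`` over the
    window frames and attributes it to the unordered pair of the beads'
    classes; fractions sum to 1 whenever any contact exists.
    """
    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    win = _window_slice(traj.n_frames, window_fraction)
    pos = traj.positions[win]
    classes = topology.properties["hydro_class"].tolist()
    d = np.linalg.norm(pos[:, group_a, None, :] - pos[:, None, group_b, :], axis=3)
    hits = d <= cutoff  # (F, A, B)
    counts: dict[tuple[str, str], int] = {}
    fa, aa, bb = np.nonzero(hits)
    for ka, kb in zip(aa, bb):
        key = tuple(sorted((classes[group_a[ka]], classes[group_b[kb]])))
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {"class_a": k[0], "class_b": k[1], "count": v,
         "fraction": v / total if total else 0.0}
        for k, v in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "count", "fraction"])


def aggregate_campaign(records: list[DissociationRecord]) -> pd.DataFrame:
    """Per-force summary of a steered campaign (violin-plot source data).

    Censored replicas enter the mean at the run duration; the association
    fraction is the share of replicas that never dissociated.
    """
    if not records:
        raise ValueError("no dissociation records")
    rows = []
    by_force: dict[float, list[DissociationRecord]] = {}
    for r in records:
        by_force.setdefault(r.force, []).append(r)
    for force in sorted(by_force):
        recs = by_force[force]
        vals = np.array([r.dissociation_time for r in recs])
        rows.append(
            {
                "force_pn": force,
                "n": len(recs),
                "mean_dissociation_time": vals.mean(),
                "median_dissociation_time": float(np.median(vals)),
                "association_fraction": np.mean([r.censored for r in recs]),
                "values": vals.tolist(),
            }
        )
    return pd.DataFrame(rows)


def kaplan_meier_mean(records: list[DissociationRecord]) -> float:
    """Restricted mean dissociation time honouring censoring (optional view)."""
    from lifelines import KaplanMeierFitter

    t = [r.dissociation_time for r in records]
    e = [not r.censored for r in records]
    km = KaplanMeierFitter().fit(t, event_observed=e)
    from lifelines.utils import restricted_mean_survival_time

    return float(restricted_mean_survival_time(km, t=max(t)))
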