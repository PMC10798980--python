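"""End-to-end campaigns: unforced binding replicas and the steered force grid.

A campaign config fixes the system (toy dimer + ligand class), the replica
counts and durations, the engine parameters and the analysis window, all
under one master seed.  Per-replica seeds follow a documented counter
scheme — seed = master + campaign_offset + 10000·condition + replica — so
conditions can run in any order and reruns are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    BindingFrequencyMap,
    DissociationRecord,
    aggregate_campaign,
    binding_frequency,
    contact_count_series,
    first_dissociation_time,
    interaction_class_breakdown,
    rmsf,
)
from .constants import ns_to_reduced, reduced_to_ns
from .engine import SimConfig, Trajectory, run
from .structures import (
    CoarseStructure,
    LigandSpec,
    default_ligand_specs,
    generate_ligand,
    generate_toy_dimer,
    place_components,
)
from .topology import Topology, TopologyOptions, build_force_protocol, build_topology

_BINDING_OFFSET = 1_000_000
_STEERED_OFFSET = 2_000_000


@dataclass(frozen=True)
class DimerSpec:
    n_per_chain: int = 20
    n_interface_contacts: int = 14
    swap_fraction: float = 0.4
    calcium_sites: tuple[int, ...] = (3, 9)


@dataclass(frozen=True)
class CampaignConfig:
    """Study conditions for one two-campaign run.

    Durations are in nanoseconds and converted to reduced time internally.
    ``ligands`` names the conditions; "none" is the ligand-free control.
    """

    dimer: DimerSpec = DimerSpec()
    ligands: tuple[str, ...] = ("none", "monomer", "oligomer", "seed")
    binding_replicas: int = 10
    binding_duration_ns: float = 0.15
    steered_replicas: int = 10
    steered_duration_ns: float = 0.15
    force_grid_pn: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0)
    sampling_interval_ns: float = 0.002
    temperature: float = 300.0
    thermostat_rate: float = 0.1
    box_edge: float = 50.0
    min_separation: float = 12.0
    max_separation: float = 16.0
    binding_cutoff: float = 6.5
    window_fraction: float = 0.4
    master_seed: int = 0
    label: str = "desk"

    def __post_init__(self) -> None:
        grid = np.asarray(self.force_grid_pn, dtype=float)
        if len(grid) == 0 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("force grid must be non-negative and strictly increasing")
        if self.binding_replicas < 1 or self.steered_replicas < 1:
            raise ValueError("replica counts must be >= 1")
        for name in self.ligands:
            if name not in ("none", "monomer", "oligomer", "seed"):
                raise ValueError(f"unknown ligand condition {name!r}")


def desk_scale(master_seed: int = 0) -> CampaignConfig:
    """Desk-scale preset: the full pipeline runs in minutes on one CPU."""
    return CampaignConfig(master_seed=master_seed)


def full_scale(master_seed: int = 0) -> CampaignConfig:
    """The printed campaign settings: 40×50 ns binding; 0–60 pN in 10 pN
    steps, 70×100 ns each.  Validates and reports; not meant for desk runs."""
    return CampaignConfig(
        dimer=DimerSpec(n_per_chain=100, n_interface_contacts=12, swap_fraction=0.5),
        binding_replicas=40,
        binding_duration_ns=50.0,
        steered_replicas=70,
        steered_duration_ns=100.0,
        force_grid_pn=(0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
        sampling_interval_ns=0.1,
        box_edge=150.0,
        master_seed=master_seed,
        label="full-scale",
    )


def campaign_total_time(config: CampaignConfig, campaign: str) -> float:
    """Aggregate simulated time per ligand condition, in microseconds."""
    if campaign == "binding":
        return config.binding_replicas * config.binding_duration_ns * 1e-3
    if campaign == "steered":
        return (
            len(config.force_grid_pn)
            * config.steered_replicas
            * config.steered_duration_ns
            * 1e-3
        )
    raise ValueError(f"unknown campaign {campaign!r}")


# ---------------------------------------------------------------------------
# system construction


def build_system(
    config: CampaignConfig, ligand_kind: str, placement_seed: int | None = None
) -> tuple[CoarseStructure, Topology]:
    """Dimer (+ placed ligand) and its topology for one condition.

    ``placement_seed`` overrides the pose seed (default: derived from the
    master seed); replicas of a condition share one placed system and
    differ by their initial velocities and thermostat streams.
    """
    dimer = generate_toy_dimer(
        config.dimer.n_per_chain,
        config.dimer.n_interface_contacts,
        config.dimer.swap_fraction,
        list(config.dimer.calcium_sites),
        seed=config.master_seed,
    )
    ligand = None
    if ligand_kind != "none":
        spec = default_ligand_specs(seed=config.master_seed)[ligand_kind]
        ligand = generate_ligand(spec)
    placed = place_components(
        dimer,
        ligand,
        min_separation=config.min_separation,
        box_edge=config.box_edge,
        seed=config.master_seed + 17 if placement_seed is None else placement_seed,
        max_separation=config.max_separation,
    )
    topo = build_topology(placed)
    return placed, topo


def pulling_direction(structure: CoarseStructure) -> np.ndarray:
    """Unit vector from the immobilized domain centroid toward the flexible one."""
    imm = structure.annotations["immobilized_domain"]
    flex = structure.annotations["flexible_domain"]
    d = structure.positions[flex].mean(axis=0) - structure.positions[imm].mean(axis=0)
    return d / np.linalg.norm(d)


def _sim_config(config: CampaignConfig, duration_ns: float, seed: int) -> SimConfig:
    return SimConfig(
        temperature=config.temperature,
        thermostat_rate=config.thermostat_rate,
        duration=ns_to_reduced(duration_ns),
        sampling_interval=ns_to_reduced(config.sampling_interval_ns),
        rng_seed=seed,
        box_edge=config.box_edge,
    )


# ---------------------------------------------------------------------------
# campaigns


@dataclass
class ConditionBindingResult:
    ligand: str
    trajectories: list[Trajectory]
    dimer_profile: BindingFrequencyMap | None
    ligand_profile: BindingFrequencyMap | None
    class_breakdown: pd.DataFrame | None
    failures: list[str] = field(default_factory=list)


@dataclass
class BindingCampaignResult:
    config: CampaignConfig
    conditions: dict[str, ConditionBindingResult]
    seeds: dict[str, list[int]]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, cond in self.conditions.items():
            mean_freq = (
                float(np.mean(cond.dimer_profile.frequency))
                if cond.dimer_profile is not None
                else np.nan
            )
            rows.append(
                {
                    "ligand": name,
                    "n_replicas": len(cond.trajectories),
                    "n_failures": len(cond.failures),
                    "mean_dimer_binding_frequency": mean_freq,
                }
            )
        return pd.DataFrame(rows)


def _average_maps(maps: list[BindingFrequencyMap]) -> BindingFrequencyMap | None:
    maps = [m for m in maps if m is not None]
    if not maps:
        return None
    freq = np.mean([m.frequency for m in maps], axis=0)
    return BindingFrequencyMap(maps[0].residues, freq, window=maps[0].window)


def run_binding_campaign(config: CampaignConfig) -> BindingCampaignResult:
    """Unforced binding replicas for every configured ligand condition.

    Computes both directions of the binding-frequency profile and the
    hydropathy-class contact breakdown over the analysis window; a failed
    replica is recorded and the campaign continues.
    """
    conditions: dict[str, ConditionBindingResult] = {}
    seeds: dict[str, list[int]] = {}
    for c, name in enumerate(config.ligands):
        structure, topo = build_system(config, name)
        dimer_sel = np.concatenate(
            [
                structure.annotations["immobilized_domain"],
                structure.annotations["flexible_domain"],
            ]
        )
        ligand_sel = structure.annotations.get("ligand", np.array([], dtype=np.int64))
        topo_run = topo.mobilized()
        trajectories: list[Trajectory] = []
        failures: list[str] = []
        cond_seeds: list[int] = []
        for r in range(config.binding_replicas):
            seed = config.master_seed + _BINDING_OFFSET + 10_000 * c + r
            cond_seeds.append(seed)
            try:
                traj = run(topo_run, _sim_config(config, config.binding_duration_ns, seed))
                trajectories.append(traj)
            except (RuntimeError, ValueError) as exc:
                failures.append(f"replica {r}: {exc}")
        dimer_maps, ligand_maps, breakdowns = [], [], []
        if len(ligand_sel):
            for traj in trajectories:
                dimer_maps.append(
                    binding_frequency(
                        traj, structure, dimer_sel, ligand_sel,
                        cutoff=config.binding_cutoff,
                        window_fraction=config.window_fraction,
                    )
                )
                ligand_maps.append(
                    binding_frequency(
                        traj, structure, ligand_sel, dimer_sel,
                        cutoff=config.binding_cutoff,
                        window_fraction=config.window_fraction,
                    )
                )
                breakdowns.append(
                    interaction_class_breakdown(
                        traj, topo, dimer_sel, ligand_sel,
                        cutoff=config.binding_cutoff,
                        window_fraction=config.window_fraction,
                    )
                )
        breakdown = None
        if breakdowns:
            allb = pd.concat(breakdowns)
            breakdown = (
                allb.groupby(["class_a", "class_b"], as_index=False)["count"].sum()
            )
            total = breakdown["count"].sum()
            breakdown["fraction"] = breakdown["count"] / total if total else 0.0
        conditions[name] = ConditionBindingResult(
            ligand=name,
            trajectories=trajectories,
            dimer_profile=_average_maps(dimer_maps),
            ligand_profile=_average_maps(ligand_maps),
            class_breakdown=breakdown,
            failures=failures,
        )
        seeds[name] = cond_seeds
    return BindingCampaignResult(config=config, conditions=conditions, seeds=seeds)


@dataclass
class SteeredCampaignResult:
    config: CampaignConfig
    records: pd.DataFrame  # long format: ligand, force_pn, replicate, time_ns, censored
    summaries: dict[str, pd.DataFrame]
    rmsf_profiles: dict[str, pd.DataFrame]
    failures: list[str]
    seeds: dict[str, list[int]]

    def early_dissociation_fraction(
        self, ligand: str, force_pn: float, threshold_ns: float
    ) -> float:
        sel = self.records[
            (self.records["ligand"] == ligand) & (self.records["force_pn"] == force_pn)
        ]
        if not len(sel):
            raise ValueError(f"no records for {ligand!r} at {force_pn} pN")
        return float((sel["dissociation_time_ns"] < threshold_ns).mean())


def run_steered_campaign(config: CampaignConfig) -> SteeredCampaignResult:
    """Constant-force pulling over the force grid for every ligand condition.

    One EC1-like domain is immobilized, the other pulled along the dimer
    axis; each replica yields a censored first dissociation time.  The
    flexible-domain RMSF is computed from the zero-force runs (alignment-free
    because the partner domain is pinned).
    """
    rows = []
    failures: list[str] = []
    summaries: dict[str, pd.DataFrame] = {}
    rmsf_profiles: dict[str, pd.DataFrame] = {}
    seeds: dict[str, list[int]] = {}
    for c, name in enumerate(config.ligands):
        structure, topo = build_system(config, name)
        direction = pulling_direction(structure)
        flex = structure.annotations["flexible_domain"]
        cond_records: list[DissociationRecord] = []
        cond_seeds: list[int] = []
        rmsf_acc: list[np.ndarray] = []
        for f_idx, force in enumerate(config.force_grid_pn):
            protocol = build_force_protocol(force, direction) if force > 0 else None
            for r in range(config.steered_replicas):
                seed = (
                    config.master_seed
                    + _STEERED_OFFSET
                    + 10_000 * (c * len(config.force_grid_pn) + f_idx)
                    + r
                )
                cond_seeds.append(seed)
                try:
                    traj = run(
                        topo,
                        _sim_config(config, config.steered_duration_ns, seed),
                        protocol,
                    )
                except (RuntimeError, ValueError) as exc:
                    failures.append(f"{name} F={force} replica {r}: {exc}")
                    continue
                series = contact_count_series(traj, topo.interface_contacts)
                series.times = reduced_to_ns(series.times)
                rec = first_dissociation_time(
                    series, config.steered_duration_ns, force=force, replicate=r
                )
                cond_records.append(rec)
                rows.append(
                    {
                        "ligand": name,
                        "force_pn": force,
                        "replicate": r,
                        "dissociation_time_ns": rec.dissociation_time,
                        "censored": rec.censored,
                    }
                )
                if force == 0:
                    prof = rmsf(
                        traj, flex, window_fraction=config.window_fraction,
                        align_to="none",
                    )
                    rmsf_acc.append(prof.rmsf)
        if cond_records:
            summaries[name] = aggregate_campaign(cond_records)
        if rmsf_acc:
            rmsf_profiles[name] = pd.DataFrame(
                {"bead": flex, "rmsf": np.mean(rmsf_acc, axis=0)}
            )
        seeds[name] = cond_seeds
    records = pd.DataFrame(
        rows, columns=["ligand", "force_pn", "replicate", "dissociation_time_ns", "censored"]
    )
    return SteeredCampaignResult(
        config=config,
        records=records,
        summaries=summaries,
        rmsf_profiles=rmsf_profiles,
        failures=failures,
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# reports


@dataclass
class CampaignReport:
    manifest: list[str]
    aggregate_time_us: float
    config: dict
    seeds: dict[str, list[int]]

    def validate(self, base: Path) -> None:
        for rel in self.manifest:
            if not (base / rel).exists():
                raise FileNotFoundError(f"report references missing file {rel}")


def write_binding_report(result: BindingCampaignResult, outdir: str | Path) -> CampaignReport:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, cond in result.conditions.items():
        if cond.dimer_profile is not None:
            p = f"binding_frequency_dimer_{name}.tsv"
            cond.dimer_profile.to_frame().to_csv(outdir / p, sep="\t", index=False)
            manifest.append(p)
            p = f"binding_frequency_ligand_{name}.tsv"
            cond.ligand_profile.to_frame().to_csv(outdir / p, sep="\t", index=False)
            manifest.append(p)
        if cond.class_breakdown is not None:
            p = f"class_breakdown_{name}.tsv"
            cond.class_breakdown.to_csv(outdir / p, sep="\t", index=False)
            manifest.append(p)
    report = CampaignReport(
        manifest=manifest,
        aggregate_time_us=campaign_total_time(result.config, "binding"),
        config=asdict(result.config),
        seeds=result.seeds,
    )
    (outdir / "binding_report.json").write_text(json.dumps(asdict(report), indent=1))
    report.validate(outdir)
    return report


def write_steered_report(result: SteeredCampaignResult, outdir: str | Path) -> CampaignReport:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = ["dissociation_records.tsv"]
    result.records.to_csv(outdir / "dissociation_records.tsv", sep="\t", index=False)
    for name, summ in result.summaries.items():
        p = f"force_summary_{name}.tsv"
        summ.drop(columns=["values"]).to_csv(outdir / p, sep="\t", index=False)
        manifest.append(p)
    for name, prof in result.rmsf_profiles.items():
        p = f"rmsf_flexible_{name}.tsv"
        prof.to_csv(outdir / p, sep="\t", index=False)
        manifest.append(p)
    report = CampaignReport(
        manifest=manifest,
        aggregate_time_us=campaign_total_time(result.config, "steered"),
        config=asdict(result.config),
        seeds=result.seeds,
    )
    (outdir / "steered_report.json").write_text(json.dumps(asdict(report), indent=1))
    report.validate(outdir)
    return report
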