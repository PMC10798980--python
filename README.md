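# godmd

Coarse-grained, event-driven discrete molecular dynamics (DMD) of a
strand-swapped adhesion dimer under amyloid-like ligand binding and constant
pulling force.

## The problem

Amyloid-β species disrupt the adherens junctions of brain endothelia by
engaging the extracellular EC1 domains of VE-cadherin, whose *trans* dimer
(a strand-swapped interface stabilised by calcium sites) holds apposing
cells together.  Simulation studies of this system ask three quantitative
questions: where on the dimer do amyloid monomers, oligomers and fibril
seeds bind (binding-frequency maps); how does each species change the
dimer's mechanical stability under piconewton-scale force (censored first
dissociation times over a force grid); and how does binding change the
flexibility of the unconstrained domain (RMSF).

`godmd` implements that entire pipeline at desk scale, on synthetic
coarse-grained systems its own generator produces: one bead per residue, a
Gō-model Hamiltonian (native contacts of **0.4 kcal/mol ≈ 0.67 kBT** at
300 K, rigid calcium-site cross-links, bond and pseudo-bond wells),
class-based non-bonded step potentials (hard core, hydrophobic wells,
Debye–Hückel screened electrostatics), an exact event-driven propagator
with an Anderson thermostat, and constant-force steering realised as a
discretized linear potential.  Ligands come in three rigidity classes —
flexible monomer, compact oligomer, rigid multi-chain seed — mirroring the
amyloid species.

## The core method

Between events every bead moves ballistically.  For a pair occupying region
*q* of its step potential, the next shell crossing solves
|**r** + **v**t| = R; at the crossing with step height ΔU the radial
component of the relative velocity rescales as

    v_r' = sign(v_r) · sqrt(v_r² − 2ΔU/μ)   if ½μv_r² > ΔU   (cross)
    v_r' = −v_r                              otherwise         (reflect)

which conserves energy exactly per event (the engine's drift is at the
10⁻¹³ kcal/mol level over 10⁵ events).  Constant force F on the pulled
domain becomes energy planes spaced δ along the pulling direction, each
crossing worth F·δ (1 pN·Å = 0.014393 kcal/mol), split equally over the
pulled beads.  Reduced units are Å, Da and kcal/mol, so one reduced time
unit is √(Da·Å²/(kcal/mol)) ≈ 48.89 fs.  The first dissociation time of a
replica is the first sampled frame in which zero interface contacts remain
(pair inside its own well outer radius); replicas that never reach zero are
censored at the run duration and enter campaign means at that value.

## A worked example

```bash
python examples/03_single_trajectory.py
```

prints, on this machine:

```
NVE: 17538 events, max energy drift 3.80e-13 kcal/mol
thermostatted: kinetic temperature 305 K (target 300 K)
```

The first line shows exact energy conservation of the event-driven
propagator in an unforced, unthermostatted run — DMD has no integration
error, only floating-point rounding.  The second shows the Anderson
thermostat holding the mobile beads' kinetic temperature at the 300 K
study temperature.  `examples/04_steered_unbinding.py` pulls the flexible
domain at 20 pN and prints the surviving interface-contact count frame by
frame with the resulting (possibly censored) dissociation time, and
`examples/05_campaigns_and_readouts.py` runs miniature binding and steered
campaigns end to end, printing binding-frequency maps, the
hydropathy-class contact breakdown and per-force dissociation summaries.

A thin CLI wraps the campaign layer (`godmd generate`, `godmd run-binding`,
`godmd run-steered`, `godmd analyze`, `godmd report`); configs are YAML
mirrors of `CampaignConfig`, and `godmd report --preset full` validates
the full-scale campaign settings (40×50 ns binding = 2.0 μs; 0–60 pN in
10 pN steps, 70×100 ns each = 49 μs) without running them.

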