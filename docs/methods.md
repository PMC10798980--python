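# Methods

## Model

`godmd` studies a two-chain adhesion dimer and three amyloid-like ligand
classes at one bead per residue.  The Hamiltonian is structure-based
(Gō-type) plus transferable non-bonded terms:

- **Covalent geometry.**  Consecutive backbone beads are held in infinite
  square wells at ±2% of the reference distance; next-nearest pairs at ±5%
  act as an angle surrogate.  These tolerances are standard Gō-DMD practice
  and configurable (`TopologyOptions`).
- **Native contacts.**  Every bead pair within 6.5 Å in the reference
  structure (intra-chain sequence separation ≥ 3) receives a single
  attractive square well of depth **0.4 kcal/mol ≈ 0.67 kBT at 300 K**, at
  ±15% of its reference distance.  Interface contacts — those spanning the
  two dimer chains — define dissociation.
- **Calcium sites.**  Beads annotated as calcium-binding residues are
  cross-linked pairwise within each chain by rigid (±1%) bond constraints.
  No explicit ions are modelled; the cross-links carry the rigidifying
  effect of the occupied sites.  Cross-chain calcium bonds were rejected
  because they would tether the dimer and suppress the dissociation
  readout the model exists to measure.
- **Non-bonded classes.**  Each residue is hydrophobic (positive
  Kyte–Doolittle), polar, cationic (K/R) or anionic (D/E; His neutral at
  neutral pH, configurable).  Hydrophobic–hydrophobic pairs share a single
  square well of depth 0.75 kcal/mol and width 2 Å outside a 4 Å hard core;
  charged pairs interact through a Debye–Hückel screened Coulomb form
  (screening length 10 Å, dielectric 80) averaged over four shells to a
  12 Å cutoff; all other pairs are hard spheres.  The hydrophobic depth is
  the model's affinity calibration: at ≈1.3 kBT per pair, a single contact
  is transient while a rigid multivalent face binds stably within a
  fraction of a nanosecond — the compressed-timescale analogue of amyloid
  binding equilibrating over tens of nanoseconds in atomistic runs.  The
  per-pair attraction is deliberately comparable to the Gō contact energy,
  so binding *strength* comes from multivalency, which rigid species
  achieve at low entropy cost.  This is the mechanism behind every
  ligand-class contrast the package reports.
- **Masses and charges** come from the sequence: per-bead mass is the
  residue's average mass (Biopython's table) minus water, so a chain's
  bead masses plus one water reproduce the peptide's average molecular
  mass exactly (verified for the amyloid-β 42-mer, 4 514 Da, and
  α-synuclein, 14 460 Da).

## Engine

Event-driven propagation is exact: beads fly ballistically between shell
crossings, bond-wall bounces, box-wall reflections, force-plane crossings,
thermostat redraws and samples.  Each mobile bead stores its single
earliest event; any velocity change recomputes the owner's event and every
event referencing it (an eager O(N) scan inside the numba-compiled loop).
The occupied region of every pair is tracked explicitly and updated only
when a crossing resolves, so energy bookkeeping never rests on classifying
a position that sits exactly on a boundary.  At the package's system sizes
(≤ ~150 beads) this design measured faster and is far simpler than a cell
list with cell-crossing events; the scan is the engine's only O(N) cost
per event.

Simultaneous events resolve earliest-first, exact ties to the lowest bead
index (the argmin scan order), making runs bit-reproducible for a fixed
seed.  Immobilized beads are infinite-mass collision partners: they never
move, but their excluded volume and wells act on mobile beads (reduced
mass μ = m_mobile).  The Anderson thermostat redraws one random mobile
bead's velocity from the Maxwell–Boltzmann distribution as a Poisson
process at rate 0.1 per mobile bead per reduced time unit — weak enough
not to distort escape kinetics, strong enough to hold 300 K (equipartition
within 5%, KS test on speeds passes at α = 0.01); the rate is a free
parameter, and halving or doubling it mainly rescales diffusion, not the
reported orderings.  Constant force is a discretized linear potential:
planes spaced δ = 0.5 Å (so even 60 pN steps by 0.43 kcal/mol < kBT per
plane) with the total force split equally across the pulled domain;
a single-bead mode exists.  Boundaries are reflecting walls — the simplest
correct choice for a non-periodic binding problem.

Units: Å, Da, kcal/mol; the derived time unit is 48.89 fs, matching the
~50 fs step conventional in atomistic DMD.  1 pN·Å = 0.014393 kcal/mol.

## Synthetic systems

The generator emulates the study's molecular cast rather than
reconstructing it:

- **Dimer.**  Two serpentine one-bead-per-residue sheets (20 residues per
  chain by default) face each other across a 10.5 Å gap.  A contiguous
  N-terminal-anchored band of 14 residue pairs is pushed to 6.0 Å
  separation and annotated as the interface; the first 40% of those pairs
  lie in both chains' N-terminal thirds and are annotated as the strand
  swap.  The C-terminal end of the groove carries no cross-chain contacts,
  leaving an open edge — the geometric feature that lets a rigid ligand
  lodge against the interface.  Interface residues are Val, their flanks
  Ala (a contiguous hydrophobic strip, as at real strand-swap interfaces),
  the rest of the surface polar with periodic Lys and Asp (cationic turn
  patches next to acidic stretches).  Chain A is annotated immobilized,
  chain B flexible.
- **Ligands.**  Monomer: a near-extended flexible 12-mer with zero intra
  native contacts.  Oligomer: a compact 16-bead block whose realized
  contact count matches a target density (0.8 per residue) within ±20%,
  found by scanning boustrophedon block shapes.  Seed: four extended
  8-mers stacked at the 4.8 Å cross-β spacing with annotated inter-peptide
  contact pairs (same 0.4 kcal/mol Gō energy as the dimer interface).
  Native-contact density per residue orders monomer < oligomer < seed,
  realising the rigidity ladder.  Sequences are two-thirds aliphatic with
  evenly spaced charges whose sign realises the requested net charge
  (negative by default, as amyloid-β at neutral pH).
- **Placement.**  The ligand is dropped at a uniformly random orientation
  with its closest approach in a 12–16 Å band around the dimer, inside a
  50 Å reflecting box.  The 12 Å floor is the study's placement rule; the
  16 Å ceiling keeps desk-scale runs inside the diffusive encounter time.
  `place_components` also supports fully uniform placement in an
  arbitrary box (default edge 4× the combined diameter).

What the generator does **not** emulate: real secondary structure,
side-chain packing, the atomistic Aβ oligomer geometry (unpublished), and
solvent beyond implicit screening.  Passing tests therefore demonstrate
the *pipeline's* correctness and the *model's* qualitative behaviour, not
quantitative properties of VE-cadherin or Aβ.

## Campaigns and readouts

The binding campaign runs unrestrained replicas (no immobilization, zero
force) and computes, over the last 40% of frames (the analysis-window
default; a last-20% preset exists): per-residue binding frequency in both
directions at the 6.5 Å (0.65 nm) contact cutoff, and the fraction of
inter-component bead contacts per hydropathy-class pair.  The steered
campaign immobilizes chain A, pulls chain B along the inter-domain axis
at each force in the grid, and records the censored first dissociation
time of every replica: the first sampled frame with zero surviving
interface contacts, each contact judged by its own well outer radius (the
Hamiltonian's definition of bound), not by the map cutoff.  Censored
replicas enter per-force means at the full duration; a Kaplan–Meier
restricted-mean option exists but is not the default.  Flexible-domain
RMSF comes from the zero-force steered runs, alignment-free because the
partner domain is pinned; Kabsch superposition is available for
unrestrained trajectories.

Desk-scale defaults: 56–72 beads total, 0.3 ns-equivalent runs (≈ 6 100
reduced time units), 2 fs-equivalent sampling, 10 replicas per condition
in the presets and 20+ in the acceptance study, force grid {0, 10, 20, 40} pN.
These sizes were chosen so a full two-campaign study with property checks
runs in minutes on one CPU; the full-scale preset (40×50 ns binding,
70×100 ns per force over 0–60 pN) is encoded for validation and reporting
but not meant to be executed here.  Per-replica seeds follow
`master + campaign_offset + 10000·condition + replica`, so conditions can
run in any order with byte-identical results.

## Numerical choices and edge cases

- Event times are the smallest positive roots of the pair quadratic;
  region bookkeeping makes the just-resolved boundary unambiguous, and
  roots are accepted at any positive time (an underflow counter aborts
  with the offending pair after 10⁶ consecutive sub-10⁻¹² steps —
  the inescapable-overlap diagnostic).
- The step-potential type allows +∞ only at the innermost level (hard
  core); every other level is finite and the outermost level is exactly
  zero, which event-driven propagation requires.
- Discretized screened electrostatics use the mean of the continuous form
  over each shell; the midpoint error vanishes as the shell count grows
  (checked 4 vs 64).
- A dimer built with clipped calcium indices simply drops the
  out-of-range residues; an infeasible interface-contact request fails
  naming the limiting constraint.
- PDB coarse-graining accepts ATOM records only (first model), resolves
  altLoc by first occurrence, and rejects insertion codes rather than
  renumbering silently; missing Cα atoms and malformed records fail with
  the chain/residue or line number.

## Known limitations

- The ligand-class contrasts (dissociated-fraction ordering oligomer >
  seed > monomer; RMSF reduction by the rigid species) are orderings of
  means over stochastic replicas.  At 20–32 replicas per force level the
  margins are a few percentage points of dissociated fraction and a few
  hundredths of an Å of RMSF — the same magnitude as replica-to-replica
  noise, as expected for a sub-nanosecond emulation of a
  tens-of-nanoseconds phenomenon.  Repeating the campaign under different
  master seeds can reorder the condition means, so the directional tests
  are genuinely stochastic: they encode the expected orderings and pass
  or fail with the draw.  Stabilising them would need roughly an order of
  magnitude more sampling (longer runs or hundreds of replicas).  The
  package asserts orderings only, never effect sizes.
- Dissociation at zero sampled contacts can fire on a transient
  fluctuation; at the default sampling (2 fs-equivalent grid, 150 frames)
  this is rare for the ligand-free dimer but contributes to the noise
  floor.  A persistence window was evaluated and rejected: it suppresses
  nearly all events at desk durations, censoring everything.
- Electrostatics are mean-field screened Coulomb between unit charges;
  no counter-ion particles, no dielectric boundary.
- The two-bead (Cα+Cβ) coarse-graining scheme is supported by the reader
  and property tables, but the generator and campaigns use the one-bead
  scheme throughout.
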