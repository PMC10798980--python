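"""Discretize the non-bonded interactions into event-driven step potentials.

Shows the screened-electrostatic shells and the canonical contact energy in
thermal units (0.4 kcal/mol is about two-thirds of kBT at 300 K, so single
native contacts break and reform constantly at room temperature).
"""

from godmd import GO_CONTACT_ENERGY, discretize_pair_potential, go_energy_in_kbt

sp = discretize_pair_potential(
    "screened-coulomb",
    {"core": 4.0, "q1q2": 1.0, "screening_length": 10.0},
    n_steps=4,
    r_max=12.0,
)
print("screened-coulomb (+1,+1), 4 shells to 12 A:")
for k in range(1, sp.n_shells):
    print(f"  {sp.radii[k - 1]:5.1f} - {sp.radii[k]:5.1f} A : "
          f"{sp.energies[k]:+.4f} kcal/mol")
print("  beyond %.1f A : 0 (finite range, required by event-driven propagation)"
      % sp.outer_radius)

print(f"\nGo contact energy: {GO_CONTACT_ENERGY} kcal/mol "
      f"= {go_energy_in_kbt():.3f} kBT at 300 K")
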