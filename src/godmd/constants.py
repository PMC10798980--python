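"""Physical constants and reduced units.

The engine works in reduced units: length in Å, energy in kcal/mol and mass
in Da.  The derived time unit is sqrt(Da·Å²/(kcal/mol)) ≈ 48.89 fs, so one
reduced time unit is close to the 50 fs step quoted for all-atom DMD codes.
"""

from __future__ import annotations

import math

#: Boltzmann constant, kcal/(mol·K).
KB = 0.0019872041

#: Average water mass added to a sum of residue masses to obtain a peptide
#: mass, Da (matches the average-isotope table used for residue masses).
WATER_MASS = 18.0153

#: One reduced time unit expressed in femtoseconds.
TIME_UNIT_FS = math.sqrt(1.66053906660e-27 * 1e-20 / (4184.0 / 6.02214076e23)) * 1e15

#: Conversion factor: (pN · Å) → kcal/mol.
PN_ANGSTROM_TO_KCAL_PER_MOL = 1e-22 * 6.02214076e23 / 4184.0

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_KCAL_ANGSTROM = 332.0637

#: Sentinel used for hard-core (infinite) energy levels.
HARD_CORE_ENERGY = math.inf


def kbt(temperature: float) -> float:
    """Thermal energy kB·T in kcal/mol."""
    return KB * temperature


def ns_to_reduced(ns: float) -> float:
    """Convert a duration in nanoseconds to reduced time units."""
    return ns * 1e6 / TIME_UNIT_FS


def reduced_to_ns(tau: float) -> float:
    """Convert reduced time units to nanoseconds."""
    return tau * TIME_UNIT_FS / 1e6


def force_pn_to_reduced(force_pn: float) -> float:
    """Convert a force in pN to kcal/(mol·Å)."""
    return force_pn * PN_ANGSTROM_TO_KCAL_PER_MOL
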