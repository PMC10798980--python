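"""Discretized pairwise step potentials for event-driven dynamics.

A :class:`StepPotential` is an ordered list of shell radii with one energy
level per inter-shell region: ``energies[0]`` is the level inside the first
radius (``+inf`` for a hard core), ``energies[k]`` the level between
``radii[k-1]`` and ``radii[k]``, and the potential is identically zero
beyond the last radius — a finite interaction range, which event-driven
propagation requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import COULOMB_KCAL_ANGSTROM, HARD_CORE_ENERGY


@dataclass(frozen=True)
class StepPotential:
    """Piecewise-constant pairwise potential.

    ``outer_bounded=True`` marks an infinite outer wall at the last radius
    (used for bond-like wells the pair can never leave).
    """

    radii: tuple[float, ...]
    energies: tuple[float, ...]
    outer_bounded: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if len(r) == 0:
            raise ValueError("need at least one shell radius")
        if len(e) != len(r):
            raise ValueError("len(energies) must equal len(radii)")
        if np.any(np.diff(r) <= 0) or r[0] <= 0:
            raise ValueError("shell radii must be positive and strictly increasing")
        if not np.all(np.isfinite(e[1:])):
            raise ValueError("only the innermost level (hard core) may be infinite")
        if np.any(np.isnan(e)):
            raise ValueError("energies must not be NaN")

    @property
    def n_shells(self) -> int:
        return len(self.radii)

    @property
    def outer_radius(self) -> float:
        return self.radii[-1]

    def energy_at(self, r: float) -> float:
        """Energy level occupied at separation r (0 beyond the last radius)."""
        for k, radius in enumerate(self.radii):
            if r < radius:
                return self.energies[k]
        if self.outer_bounded:
            raise ValueError("separation outside an outer-bounded well")
        return 0.0

    def region_of(self, r: float) -> int:
        """Index of the region occupied at separation r (n_shells = outside)."""
        return int(np.searchsorted(np.asarray(self.radii), r, side="right"))


def hard_sphere(core: float) -> StepPotential:
    return StepPotential((core,), (HARD_CORE_ENERGY,))


def hydrophobic_well(core: float, depth: float, width: float) -> StepPotential:
    """Hard core plus one attractive square well of the given depth/width."""
    return StepPotential((core, core + width), (HARD_CORE_ENERGY, -depth))


def screened_coulomb_energy(
    r: float, q1q2: float, screening_length: float, dielectric: float = 80.0
) -> float:
    """Debye-Hückel screened Coulomb interaction in kcal/mol."""
    return (
        COULOMB_KCAL_ANGSTROM
        * q1q2
        * np.exp(-r / screening_length)
        / (dielectric * r)
    )


def discretize_pair_potential(
    form: str,
    params: dict,
    n_steps: int = 4,
    r_max: float = 12.0,
) -> StepPotential:
    """Discretize a continuous pair interaction into shells.

    Shell energies are the mean of the continuous form over each shell; the
    level beyond ``r_max`` is exactly zero.  Supported forms:

    ``hard-sphere``       params: core
    ``hydrophobic-well``  params: core, depth, width
    ``screened-coulomb``  params: core, q1q2, screening_length, dielectric
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    core = float(params.get("core", 4.0))

    if form == "hard-sphere":
        return hard_sphere(core)
    if form == "hydrophobic-well":
        return hydrophobic_well(core, float(params["depth"]), float(params["width"]))
    if form == "screened-coulomb":
        lam = float(params["screening_length"])
        if lam <= 0:
            raise ValueError("screening length must be positive")
        q1q2 = float(params["q1q2"])
        eps = float(params.get("dielectric", 80.0))
        if r_max <= core:
            raise ValueError("r_max must exceed the hard core")
        edges = np.linspace(core, r_max, n_steps + 1)
        levels = [HARD_CORE_ENERGY]
        for lo, hi in zip(edges[:-1], edges[1:]):
            integral, _ = quad(
                screened_coulomb_energy, lo, hi, args=(q1q2, lam, eps)
            )
            levels.append(integral / (hi - lo))
        return StepPotential(tuple(edges), tuple(levels))
    raise ValueError(f"unknown potential form {form!r}")
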