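"""Event-driven discrete molecular dynamics.

Between events every bead moves ballistically; events are exact crossings of
potential-step radii (cross or reflect, with energy bookkeeping), bond-well
walls, reflecting box walls, steering force planes, Anderson-thermostat
velocity redraws and trajectory samples.  Each mobile bead holds exactly one
scheduled event (its earliest); whenever a bead's velocity changes, its own
event and every event that references it are recomputed.  The occupied
region of every interacting pair is tracked explicitly and updated only
when a crossing resolves, so energy bookkeeping never depends on fragile
positional reclassification at a boundary.  The hot loop is compiled with
numba; all randomness flows from a single integer seed.

Units: Å, Da, kcal/mol; the derived time unit is ≈ 48.89 fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .constants import KB, force_pn_to_reduced
from .topology import ForceProtocol, Topology

HARD = 1e30  # infinite-energy sentinel inside the compiled loop
_TMIN = 1e-12  # event-time underflow threshold


@dataclass(frozen=True)
class SimConfig:
    """Engine parameters.

    ``duration`` and ``sampling_interval`` are in reduced time units
    (1 unit ≈ 48.89 fs); use :func:`godmd.constants.ns_to_reduced` to
    convert from nanoseconds.  ``thermostat_rate`` is velocity redraws per
    mobile bead per reduced time unit.
    """

    temperature: float = 300.0
    thermostat_rate: float = 0.1
    duration: float = 100.0
    sampling_interval: float = 10.0
    rng_seed: int = 0
    box_edge: float = 200.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 < self.sampling_interval <= self.duration:
            raise ValueError("sampling_interval must lie in (0, duration]")
        if self.thermostat_rate < 0:
            raise ValueError("thermostat_rate must be non-negative")


@dataclass
class Trajectory:
    """Sampled frames plus the energy ledger of one run."""

    times: np.ndarray  # (F,) reduced time units
    positions: np.ndarray  # (F, N, 3) Å
    velocities: np.ndarray  # (F, N, 3) Å per reduced time unit
    kinetic: np.ndarray  # (F,) kcal/mol
    potential: np.ndarray  # (F,) kcal/mol, step-potential ledger
    steering: np.ndarray  # (F,) kcal/mol, potential of the pulling planes
    n_events: int = 0
    box_edge: float = 0.0

    @property
    def total_energy(self) -> np.ndarray:
        """KE + step PE + steering potential (constant in unforced NVE)."""
        return self.kinetic + self.potential + self.steering

    @property
    def n_frames(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# public single-event primitives (pure Python; mirrored inside the jit loop)


def predict_pair_event(rel_position, rel_velocity, shell_radii, current_shell: int):
    """Earliest shell crossing for one pair, or None.

    ``current_shell`` is the occupied region index: region q lies between
    radii q-1 and q; region ``len(shell_radii)`` is outside the outermost
    radius.  Returns ``(time_to_event, target_boundary_index, direction)``
    with direction +1 (outward) or −1 (inward).
    """
    r = np.asarray(rel_position, dtype=float)
    v = np.asarray(rel_velocity, dtype=float)
    radii = np.asarray(shell_radii, dtype=float)
    d2 = float(r @ r)
    b = float(r @ v)
    v2 = float(v @ v)
    if v2 == 0.0:
        return None
    best = None
    q = current_shell
    if q >= 1 and b < 0.0:
        rin = radii[q - 1]
        disc = b * b - v2 * (d2 - rin * rin)
        if disc >= 0.0:
            t = (-b - math.sqrt(disc)) / v2
            if t > 0.0:
                best = (t, q - 1, -1)
    if q < len(radii):
        rout = radii[q]
        disc = b * b - v2 * (d2 - rout * rout)
        if disc > 0.0:
            t = (-b + math.sqrt(disc)) / v2
            if t > 0.0 and (best is None or t < best[0]):
                best = (t, q, +1)
    return best


def resolve_crossing(m_i: float, m_j: float, v_r: float, delta_u: float):
    """Outcome of a pair reaching a step of height ``delta_u``.

    ``m_j = inf`` marks an immobilized partner.  Returns
    ``(v_r_after, crossed, ledger_delta)``; tangential components of the
    relative velocity are untouched by construction.
    """
    mu = m_i if math.isinf(m_j) else m_i * m_j / (m_i + m_j)
    radial_ke = 0.5 * mu * v_r * v_r
    if delta_u >= HARD:
        return -v_r, False, 0.0
    if delta_u <= 0.0 or radial_ke > delta_u:
        sign = 1.0 if v_r >= 0 else -1.0
        return sign * math.sqrt(v_r * v_r - 2.0 * delta_u / mu), True, delta_u
    return -v_r, False, 0.0


def initialize_velocities(topology: Topology, temperature: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities; COM momentum removed; immobilized zero."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    n = topology.n_beads
    masses = topology.masses
    vel = rng.standard_normal((n, 3)) * np.sqrt(KB * temperature / masses)[:, None]
    mobile = np.ones(n, dtype=bool)
    mobile[topology.immobilized] = False
    vel[~mobile] = 0.0
    if mobile.sum() > 1:
        m = masses[mobile]
        vel[mobile] -= (m[:, None] * vel[mobile]).sum(axis=0) / m.sum()
    elif mobile.sum() == 1:
        vel[mobile] = 0.0
    return vel


# ---------------------------------------------------------------------------
# topology compilation


@dataclass
class _Compiled:
    masses: np.ndarray
    mobile: np.ndarray
    pot_id: np.ndarray  # (N, N) int32, -1 = none
    radii: np.ndarray  # (P, S) padded with -1
    nshell: np.ndarray  # (P,)
    levels: np.ndarray  # (P, S+1); levels[p, q] = energy of region q


def compile_topology(topology: Topology) -> _Compiled:
    """Flatten the topology into the arrays the jitted loop consumes."""
    n = topology.n_beads
    props = topology.properties
    masses = topology.masses.copy()
    mobile = np.ones(n, dtype=np.bool_)
    mobile[topology.immobilized] = False

    pots: list[tuple[tuple[float, ...], tuple[float, ...]]] = []
    pot_index: dict[tuple, int] = {}

    def intern(radii: tuple[float, ...], levels: tuple[float, ...]) -> int:
        key = (radii, levels)
        if key not in pot_index:
            pot_index[key] = len(pots)
            pots.append(key)
        return pot_index[key]

    pot_id = np.full((n, n), -1, dtype=np.int32)
    hard_radius = props["hard_radius"].to_numpy(dtype=float)
    classes = props["hydro_class"].tolist()

    class_pid: dict[tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((classes[i], classes[j])))
            if key not in class_pid:
                sp = topology.nonbonded_for(*key)
                radii = tuple(float(r) for r in sp.radii)
                levels = [HARD if not np.isfinite(e) else float(e) for e in sp.energies]
                levels.append(HARD if sp.outer_bounded else 0.0)
                class_pid[key] = intern(radii, tuple(levels))
            pid = class_pid[key]
            pot_id[i, j] = pot_id[j, i] = pid

    for c in topology.contacts:
        hc = hard_radius[c.i] + hard_radius[c.j]
        rin, rout = c.inner_radius, c.outer_radius
        if hc < rin:
            radii = (hc, rin, rout)
            levels = (HARD, 0.0, -c.epsilon, 0.0)
        elif hc < rout:
            radii = (hc, rout)
            levels = (HARD, -c.epsilon, 0.0)
        else:
            radii = (hc,)
            levels = (HARD, 0.0)
        pid = intern(radii, levels)
        pot_id[c.i, c.j] = pot_id[c.j, c.i] = pid

    for bnd in topology.bonds:
        pid = intern((bnd.d_min, bnd.d_max), (HARD, 0.0, HARD))
        pot_id[bnd.i, bnd.j] = pot_id[bnd.j, bnd.i] = pid

    smax = max(len(r) for r, _ in pots)
    radii_arr = np.full((len(pots), smax), -1.0)
    levels_arr = np.zeros((len(pots), smax + 1))
    nshell = np.zeros(len(pots), dtype=np.int32)
    for p, (radii, levels) in enumerate(pots):
        nshell[p] = len(radii)
        radii_arr[p, : len(radii)] = radii
        levels_arr[p, : len(levels)] = levels

    return _Compiled(masses, mobile, pot_id, radii_arr, nshell, levels_arr)


def _regions(comp: _Compiled, positions: np.ndarray) -> np.ndarray:
    """Occupied region per interacting pair, validated against hard walls."""
    n = positions.shape[0]
    region = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + 1, n):
            p = comp.pot_id[i, j]
            if p < 0:
                continue
            d = float(np.linalg.norm(positions[i] - positions[j]))
            q = int(np.searchsorted(comp.radii[p, : comp.nshell[p]], d, side="right"))
            if comp.levels[p, q] >= HARD:
                raise ValueError(
                    f"invalid state: beads {i},{j} at {d:.3f} Å occupy a "
                    "forbidden region"
                )
            region[i, j] = region[j, i] = q
    return region


def potential_energy(topology: Topology, positions: np.ndarray) -> float:
    """Step-potential energy recomputed from scratch (the ledger oracle)."""
    comp = compile_topology(topology)
    region = _regions(comp, positions)
    pe = 0.0
    n = positions.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            p = comp.pot_id[i, j]
            if p >= 0:
                pe += comp.levels[p, region[i, j]]
    return pe


# ---------------------------------------------------------------------------
# the compiled event loop


@njit(cache=True)
def _bead_event(
    i, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
    box_edge, pulled, fdir, delta, du_bead,
):
    """Earliest event for bead i at tnow: (abs_time, kind, partner, aux, dirn).

    kind 0 = pair crossing (partner, boundary index aux), 1 = box wall
    (axis aux, side dirn), 2 = force plane (travel direction dirn).
    """
    n = pos.shape[0]
    best_t = np.inf
    kind = -1
    partner = -1
    aux = -1
    dirn = 0
    xi0 = pos[i, 0] + vel[i, 0] * (tnow - tb[i])
    xi1 = pos[i, 1] + vel[i, 1] * (tnow - tb[i])
    xi2 = pos[i, 2] + vel[i, 2] * (tnow - tb[i])

    for j in range(n):
        if j == i:
            continue
        p = pot_id[i, j]
        if p < 0:
            continue
        if not mobile[j] and not mobile[i]:
            continue
        dtj = tnow - tb[j]
        rx = xi0 - (pos[j, 0] + vel[j, 0] * dtj)
        ry = xi1 - (pos[j, 1] + vel[j, 1] * dtj)
        rz = xi2 - (pos[j, 2] + vel[j, 2] * dtj)
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        d2 = rx * rx + ry * ry + rz * rz
        v2 = vx * vx + vy * vy + vz * vz
        if v2 == 0.0:
            continue
        b = rx * vx + ry * vy + rz * vz
        q = region[i, j]
        ns = nshell[p]
        if q >= 1 and b < 0.0:
            rin = radii[p, q - 1]
            disc = b * b - v2 * (d2 - rin * rin)
            if disc >= 0.0:
                t = (-b - math.sqrt(disc)) / v2
                if t > 0.0 and tnow + t < best_t:
                    best_t = tnow + t
                    kind = 0
                    partner = j
                    aux = q - 1
                    dirn = -1
        if q < ns:
            rout = radii[p, q]
            disc = b * b - v2 * (d2 - rout * rout)
            if disc > 0.0:
                t = (-b + math.sqrt(disc)) / v2
                if t > 0.0 and tnow + t < best_t:
                    best_t = tnow + t
                    kind = 0
                    partner = j
                    aux = q
                    dirn = 1

    for a in range(3):
        va = vel[i, a]
        xa = xi0 if a == 0 else (xi1 if a == 1 else xi2)
        if va > 0.0:
            t = (box_edge - xa) / va
            if t > 0.0 and tnow + t < best_t:
                best_t = tnow + t
                kind = 1
                partner = -1
                aux = a
                dirn = 1
        elif va < 0.0:
            t = -xa / va
            if t > 0.0 and tnow + t < best_t:
                best_t = tnow + t
                kind = 1
                partner = -1
                aux = a
                dirn = -1

    if du_bead > 0.0 and pulled[i]:
        vs = vel[i, 0] * fdir[0] + vel[i, 1] * fdir[1] + vel[i, 2] * fdir[2]
        if vs != 0.0:
            s = xi0 * fdir[0] + xi1 * fdir[1] + xi2 * fdir[2]
            if vs > 0.0:
                k = math.floor(s / delta + 1e-9) + 1
            else:
                k = math.ceil(s / delta - 1e-9) - 1
            t = (k * delta - s) / vs
            if t > 0.0 and tnow + t < best_t:
                best_t = tnow + t
                kind = 2
                partner = -1
                aux = 0
                dirn = 1 if vs > 0.0 else -1

    return best_t, kind, partner, aux, dirn


@njit(cache=True)
def _recompute(
    i, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
    box_edge, pulled, fdir, delta, du_bead,
    ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
):
    if not mobile[i]:
        ev_time[i] = np.inf
        ev_kind[i] = -1
        return
    t, k, p, a, d = _bead_event(
        i, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
        box_edge, pulled, fdir, delta, du_bead,
    )
    ev_time[i] = t
    ev_kind[i] = k
    ev_partner[i] = p
    ev_aux[i] = a
    ev_dirn[i] = d


@njit(cache=True)
def _run_loop(
    pos, vel, masses, mobile, pot_id, radii, nshell, levels, region,
    box_edge, pulled, fdir, delta, du_bead,
    temperature, thermo_rate, duration, samp_int, seed, pe0,
    frames, vframes, frame_times, ke_out, pe_out, steer_out,
):
    np.random.seed(seed)
    n = pos.shape[0]
    tb = np.zeros(n)
    ev_time = np.full(n, np.inf)
    ev_kind = np.full(n, -1, dtype=np.int32)
    ev_partner = np.full(n, -1, dtype=np.int32)
    ev_aux = np.full(n, -1, dtype=np.int32)
    ev_dirn = np.zeros(n, dtype=np.int32)

    mobile_idx = np.where(mobile)[0]
    n_mobile = len(mobile_idx)
    kbt = 0.0019872041 * temperature

    for i in range(n):
        _recompute(
            i, pos, vel, tb, 0.0, mobile, pot_id, radii, nshell, region,
            box_edge, pulled, fdir, delta, du_bead,
            ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
        )

    pe = pe0
    steer = 0.0
    tnow = 0.0
    n_events = 0
    underflow = 0
    fail_i = -1
    fail_j = -1
    status = 0

    if thermo_rate > 0.0 and n_mobile > 0:
        next_thermo = np.random.exponential(1.0 / (thermo_rate * n_mobile))
    else:
        next_thermo = np.inf

    frame = 0
    for i in range(n):
        for a in range(3):
            frames[frame, i, a] = pos[i, a]
            vframes[frame, i, a] = vel[i, a]
    frame_times[frame] = 0.0
    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    ke_out[frame] = ke
    pe_out[frame] = pe
    steer_out[frame] = steer
    frame += 1
    next_sample = samp_int

    while True:
        imin = -1
        tmin = np.inf
        for i in range(n):
            if ev_time[i] < tmin:
                tmin = ev_time[i]
                imin = i

        tnext = tmin if tmin < next_thermo else next_thermo
        do_sample = next_sample <= tnext and next_sample <= duration + 1e-12
        if do_sample:
            tnow = next_sample
            for i in range(n):
                for a in range(3):
                    pos[i, a] += vel[i, a] * (tnow - tb[i])
                tb[i] = tnow
                for a in range(3):
                    frames[frame, i, a] = pos[i, a]
                    vframes[frame, i, a] = vel[i, a]
            frame_times[frame] = tnow
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                )
            ke_out[frame] = ke
            pe_out[frame] = pe
            steer_out[frame] = steer
            frame += 1
            next_sample += samp_int
            if tnow >= duration - 1e-12:
                break
            continue
        if tnext > duration:
            break

        if next_thermo <= tmin:
            tnow = next_thermo
            k = mobile_idx[np.random.randint(0, n_mobile)]
            for a in range(3):
                pos[k, a] += vel[k, a] * (tnow - tb[k])
            tb[k] = tnow
            sigma = math.sqrt(kbt / masses[k])
            for a in range(3):
                vel[k, a] = np.random.normal(0.0, sigma)
            _recompute(
                k, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
                box_edge, pulled, fdir, delta, du_bead,
                ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
            )
            for j in range(n):
                if j != k and ev_kind[j] == 0 and ev_partner[j] == k:
                    _recompute(
                        j, pos, vel, tb, tnow, mobile, pot_id, radii, nshell,
                        region, box_edge, pulled, fdir, delta, du_bead,
                        ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
                    )
            next_thermo += np.random.exponential(1.0 / (thermo_rate * n_mobile))
            continue

        i = imin
        if tmin - tnow < _TMIN:
            underflow += 1
            if underflow > 1000000:
                status = 1
                fail_i = i
                fail_j = ev_partner[i]
                break
        else:
            underflow = 0
        tnow = tmin
        n_events += 1
        kind = ev_kind[i]
        j = ev_partner[i]
        for a in range(3):
            pos[i, a] += vel[i, a] * (tnow - tb[i])
        tb[i] = tnow

        if kind == 0:
            p = pot_id[i, j]
            for a in range(3):
                pos[j, a] += vel[j, a] * (tnow - tb[j])
            tb[j] = tnow
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            d = math.sqrt(rx * rx + ry * ry + rz * rz)
            nx = rx / d
            ny = ry / d
            nz = rz / d
            vr = (
                (vel[i, 0] - vel[j, 0]) * nx
                + (vel[i, 1] - vel[j, 1]) * ny
                + (vel[i, 2] - vel[j, 2]) * nz
            )
            q = region[i, j]
            if ev_dirn[i] > 0:
                q_new = q + 1
            else:
                q_new = q - 1
            du = levels[p, q_new] - levels[p, q]
            if mobile[i] and mobile[j]:
                mu = masses[i] * masses[j] / (masses[i] + masses[j])
            elif mobile[i]:
                mu = masses[i]
            else:
                mu = masses[j]
            rke = 0.5 * mu * vr * vr
            if du >= HARD or (du > 0.0 and rke <= du):
                vr_new = -vr  # reflect
            else:
                sgn = 1.0 if vr >= 0.0 else -1.0
                vr_new = sgn * math.sqrt(vr * vr - 2.0 * du / mu)
                pe += du
                region[i, j] = q_new
                region[j, i] = q_new
            dvr = vr_new - vr
            if mobile[i] and mobile[j]:
                fi = mu / masses[i]
                fj = mu / masses[j]
                vel[i, 0] += fi * dvr * nx
                vel[i, 1] += fi * dvr * ny
                vel[i, 2] += fi * dvr * nz
                vel[j, 0] -= fj * dvr * nx
                vel[j, 1] -= fj * dvr * ny
                vel[j, 2] -= fj * dvr * nz
            elif mobile[i]:
                vel[i, 0] += dvr * nx
                vel[i, 1] += dvr * ny
                vel[i, 2] += dvr * nz
            else:
                vel[j, 0] -= dvr * nx
                vel[j, 1] -= dvr * ny
                vel[j, 2] -= dvr * nz
        elif kind == 1:
            a = ev_aux[i]
            vel[i, a] = -vel[i, a]
        elif kind == 2:
            vs = vel[i, 0] * fdir[0] + vel[i, 1] * fdir[1] + vel[i, 2] * fdir[2]
            if ev_dirn[i] > 0:
                vs_new = math.sqrt(vs * vs + 2.0 * du_bead / masses[i])
                steer -= du_bead
            else:
                if 0.5 * masses[i] * vs * vs > du_bead:
                    vs_new = -math.sqrt(vs * vs - 2.0 * du_bead / masses[i])
                    steer += du_bead
                else:
                    vs_new = -vs
            dvs = vs_new - vs
            vel[i, 0] += dvs * fdir[0]
            vel[i, 1] += dvs * fdir[1]
            vel[i, 2] += dvs * fdir[2]
        else:
            break

        _recompute(
            i, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
            box_edge, pulled, fdir, delta, du_bead,
            ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
        )
        if kind == 0 and j >= 0:
            _recompute(
                j, pos, vel, tb, tnow, mobile, pot_id, radii, nshell, region,
                box_edge, pulled, fdir, delta, du_bead,
                ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
            )
        for k2 in range(n):
            if k2 != i and k2 != j and ev_kind[k2] == 0 and (
                ev_partner[k2] == i or ev_partner[k2] == j
            ):
                _recompute(
                    k2, pos, vel, tb, tnow, mobile, pot_id, radii, nshell,
                    region, box_edge, pulled, fdir, delta, du_bead,
                    ev_time, ev_kind, ev_partner, ev_aux, ev_dirn,
                )

    return n_events, frame, status, fail_i, fail_j


def run(
    topology: Topology,
    config: SimConfig,
    protocol: ForceProtocol | None = None,
    velocities: np.ndarray | None = None,
) -> Trajectory:
    """Run one DMD trajectory; fully reproducible for a fixed config seed."""
    comp = compile_topology(topology)
    n = topology.n_beads
    pos = topology.structure.positions.copy()
    box_edge = config.box_edge
    if np.any(pos < 0) or np.any(pos > box_edge):
        raise ValueError("initial positions outside the reflecting box")

    if velocities is None:
        velocities = initialize_velocities(topology, config.temperature, config.rng_seed)
    vel = np.asarray(velocities, dtype=float).copy()
    vel[~comp.mobile] = 0.0

    pulled = np.zeros(n, dtype=np.bool_)
    fdir = np.zeros(3)
    delta = 1.0
    du_bead = 0.0
    if protocol is not None and protocol.magnitude_pn > 0:
        sel = topology.pulled
        if len(sel) == 0:
            raise ValueError("force protocol given but no pulled beads in topology")
        if protocol.share_rule == "single":
            sel = sel[:1]
        pulled[sel] = True
        fdir = np.asarray(protocol.direction, dtype=float)
        delta = protocol.delta
        f_total = force_pn_to_reduced(protocol.magnitude_pn)
        du_bead = f_total * delta / pulled.sum()

    region = _regions(comp, pos)
    pe0 = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            p = comp.pot_id[i, j]
            if p >= 0:
                pe0 += comp.levels[p, region[i, j]]

    n_frames = int(math.floor(config.duration / config.sampling_interval + 1e-9)) + 1
    frames = np.zeros((n_frames + 1, n, 3))
    vframes = np.zeros((n_frames + 1, n, 3))
    frame_times = np.zeros(n_frames + 1)
    ke_out = np.zeros(n_frames + 1)
    pe_out = np.zeros(n_frames + 1)
    steer_out = np.zeros(n_frames + 1)

    n_events, n_filled, status, fi, fj = _run_loop(
        pos, vel, comp.masses, comp.mobile, comp.pot_id, comp.radii,
        comp.nshell, comp.levels, region, box_edge, pulled, fdir, delta,
        du_bead, config.temperature, config.thermostat_rate, config.duration,
        config.sampling_interval, int(config.rng_seed) & 0x7FFFFFFF, pe0,
        frames, vframes, frame_times, ke_out, pe_out, steer_out,
    )
    if status == 1:
        raise RuntimeError(
            f"event-time underflow: beads {fi} and {fj} appear inescapably overlapped"
        )
    return Trajectory(
        times=frame_times[:n_filled].copy(),
        positions=frames[:n_filled].copy(),
        velocities=vframes[:n_filled].copy(),
        kinetic=ke_out[:n_filled].copy(),
        potential=pe_out[:n_filled].copy(),
        steering=steer_out[:n_filled].copy(),
        n_events=int(n_events),
        box_edge=box_edge,
    )


def run_replicas(
    topology: Topology,
    config: SimConfig,
    protocol: ForceProtocol | None,
    n_replicas: int,
    base_seed: int,
) -> list[Trajectory]:
    """Independent replicas: replica k is seeded with base_seed + k."""
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    out = []
    for k in range(n_replicas):
        cfg = replace(config, rng_seed=base_seed + k)
        out.append(run(topology, cfg, protocol))
    return out
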