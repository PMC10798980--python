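"""Event-driven engine: single-event primitives, conservation laws,
thermostat statistics, oracle equivalence and force-driven escape kinetics."""

import math

import numpy as np
import pytest
from scipy import stats

from godmd.constants import KB, kbt
from godmd.engine import (
    SimConfig,
    compile_topology,
    initialize_velocities,
    potential_energy,
    predict_pair_event,
    resolve_crossing,
    run,
    run_replicas,
)
from godmd.structures import CoarseStructure
from godmd.topology import TopologyOptions, build_force_protocol, build_topology


def free_beads(positions, residues=None, center=100.0, ligand_beads=()):
    """Beads on separate chains (no bonds), centred in a large box.

    ``ligand_beads`` marks a subset as the second component, so its pairs
    with the rest feel the transferable (attractive) non-bonded terms.
    """
    pos = np.asarray(positions, dtype=float)
    n = len(pos)
    residues = residues or ["L"] * n
    annotations = {}
    if len(ligand_beads):
        annotations["ligand"] = np.asarray(ligand_beads, dtype=int)
    return CoarseStructure(
        chain_ids=[chr(ord("A") + i) for i in range(n)],
        residue_index=np.ones(n, dtype=int),
        residue_names=list(residues),
        bead_kinds=["backbone"] * n,
        positions=pos - pos.mean(axis=0) + center,
        annotations=annotations,
    )


def two_domain_pair(separation=6.0, center=100.0):
    """One immobilized bead (chain A) and one mobile bead (chain B)."""
    s = free_beads([[0.0, 0, 0], [separation, 0, 0]], center=center)
    s.annotations = {
        "immobilized_domain": np.array([0]),
        "flexible_domain": np.array([1]),
    }
    return s


class TestPredictPairEvent:
    def test_head_on_approach(self):
        out = predict_pair_event([4.0, 0, 0], [-2.0, 0, 0], [2.0], current_shell=1)
        t, boundary, dirn = out
        assert t == pytest.approx(1.0)
        assert (boundary, dirn) == (0, -1)

    def test_receding_exit_through_outer_shell(self):
        out = predict_pair_event([3.0, 0, 0], [2.0, 0, 0], [5.0], current_shell=0)
        t, boundary, dirn = out
        assert t == pytest.approx(1.0)
        assert (boundary, dirn) == (0, +1)

    def test_motion_never_reaches_shell(self):
        out = predict_pair_event([4.0, 0, 0], [0.0, 2.0, 0], [2.0], current_shell=1)
        assert out is None  # closest approach 4 > 2

    def test_zero_relative_velocity(self):
        assert predict_pair_event([4.0, 0, 0], [0, 0, 0], [2.0], 1) is None

    def test_oblique_case_matches_bisection_oracle(self):
        """Impact parameter 1.5, shell 2 is missed; outer shell 5 is hit."""
        r0 = np.array([4.0, 0.0, 0.0])
        b_impact = 1.5
        v = np.array([-math.sqrt(1 - (b_impact / 4.0) ** 2), b_impact / 4.0, 0.0])
        radii = [2.0, 5.0]
        out = predict_pair_event(r0, v, radii, current_shell=1)
        t_pred, boundary, dirn = out
        # oracle: march at dt = 1e-4, bracket the crossing, bisect
        dt = 1e-4
        t = 0.0
        target = radii[boundary]
        side = np.linalg.norm(r0) - target
        while t < 60.0:
            t += dt
            d = np.linalg.norm(r0 + v * t)
            if (d - target) * side < 0:
                lo, hi = t - dt, t
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    if (np.linalg.norm(r0 + v * mid) - target) * side < 0:
                        hi = mid
                    else:
                        lo = mid
                t = 0.5 * (lo + hi)
                break
        assert t_pred == pytest.approx(t, abs=1e-6)


class TestResolveCrossing:
    def test_crossing_pays_the_step(self):
        # radial KE 1.0 against a step of 0.5 -> crosses with KE 0.5
        mu = 2.0
        v_r = -1.0  # inward, radial KE = 0.5*2*1 = 1.0
        v_after, crossed, ledger = resolve_crossing(4.0, 4.0, v_r, 0.5)
        assert crossed and ledger == 0.5
        assert 0.5 * mu * v_after**2 == pytest.approx(0.5)
        assert v_after < 0  # keeps direction

    def test_insufficient_energy_reflects(self):
        v_after, crossed, ledger = resolve_crossing(4.0, 4.0, -0.5477225575, 0.5)
        # radial KE = 0.3 < 0.5
        assert not crossed and ledger == 0.0
        assert v_after == pytest.approx(0.5477225575)

    def test_falling_into_contact_well_gains_canonical_energy(self):
        # equal masses, head-on, dropping into a 0.4 kcal/mol well
        m = 2.0
        mu = 1.0
        v_r = -1.0
        v_after, crossed, _ = resolve_crossing(m, m, v_r, -0.4)
        assert crossed
        assert 0.5 * mu * v_after**2 == pytest.approx(0.5 * mu * v_r**2 + 0.4)

    def test_hard_core_always_reflects(self):
        v_after, crossed, _ = resolve_crossing(4.0, math.inf, -3.0, math.inf)
        assert not crossed and v_after == 3.0


class TestInitializeVelocities:
    def test_single_mobile_bead_is_at_rest_after_com_removal(self):
        s = free_beads([[0, 0, 0]])
        topo = build_topology(s)
        v = initialize_velocities(topo, 300.0, 1)
        np.testing.assert_array_equal(v, 0.0)

    def test_equipartition_of_draw(self):
        rng_pos = np.random.default_rng(0).uniform(40, 160, size=(1000, 3))
        s = CoarseStructure(
            chain_ids=[f"C{i}" for i in range(1000)],
            residue_index=np.ones(1000, dtype=int),
            residue_names=["A"] * 1000,
            bead_kinds=["backbone"] * 1000,
            positions=rng_pos,
        )
        topo = build_topology(s)
        v = initialize_velocities(topo, 300.0, 2)
        ke = 0.5 * (topo.masses[:, None] * v**2).sum()
        per_dof = ke / (3 * 1000)
        assert per_dof == pytest.approx(0.5 * KB * 300.0, rel=0.05)

    def test_fully_immobilized_system_is_static(self):
        s = two_domain_pair()
        s.annotations["immobilized_domain"] = np.array([0, 1])
        s.annotations["flexible_domain"] = np.array([], dtype=int)
        topo = build_topology(s)
        v = initialize_velocities(topo, 300.0, 3)
        np.testing.assert_array_equal(v, 0.0)


class TestConservationAndStatistics:
    @pytest.fixture(scope="class")
    def mobile_dimer_topology(self, centered):
        return build_topology(centered).mobilized()

    def test_nve_energy_conservation(self, mobile_dimer_topology):
        cfg = SimConfig(
            duration=2500.0, sampling_interval=25.0, thermostat_rate=0.0,
            rng_seed=4, box_edge=80.0,
        )
        traj = run(mobile_dimer_topology, cfg)
        assert traj.n_events > 100_000
        drift = np.abs(traj.total_energy - traj.total_energy[0]).max()
        assert drift <= 1e-6

    def test_energy_ledger_matches_from_scratch_recomputation(self, mobile_dimer_topology):
        cfg = SimConfig(
            duration=300.0, sampling_interval=300.0, thermostat_rate=0.1,
            rng_seed=5, box_edge=80.0,
        )
        traj = run(mobile_dimer_topology, cfg)
        scratch = potential_energy(mobile_dimer_topology, traj.positions[-1])
        assert traj.potential[-1] == pytest.approx(scratch, abs=1e-9)

    @pytest.fixture(scope="class")
    def thermostatted(self, mobile_dimer_topology):
        cfg = SimConfig(
            duration=4000.0, sampling_interval=5.0, thermostat_rate=0.1,
            rng_seed=6, box_edge=80.0,
        )
        return run(mobile_dimer_topology, cfg)

    def test_equipartition_under_thermostat(self, mobile_dimer_topology, thermostatted):
        traj = thermostatted
        half = traj.n_frames // 2
        n = mobile_dimer_topology.n_beads
        per_dof = traj.kinetic[half:].mean() / (3 * n)
        assert per_dof == pytest.approx(0.5 * KB * 300.0, rel=0.05)

    def test_speed_distribution_is_maxwell_boltzmann(self, mobile_dimer_topology, thermostatted):
        traj = thermostatted
        half = traj.n_frames // 2
        m = mobile_dimer_topology.masses
        speeds = np.linalg.norm(traj.velocities[half:], axis=2)
        x = (speeds * np.sqrt(m / kbt(300.0))[None, :]).ravel()
        ks = stats.kstest(x, stats.chi(3).cdf)
        assert ks.pvalue > 0.01

    def test_hard_core_never_violated(self, mobile_dimer_topology, thermostatted):
        comp = compile_topology(mobile_dimer_topology)
        hard = 4.0 - 1e-9
        for frame in thermostatted.positions[:: max(1, thermostatted.n_frames // 50)]:
            d = np.linalg.norm(frame[:, None] - frame[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            bonded = np.zeros_like(d, dtype=bool)
            for b in mobile_dimer_topology.bonds:
                bonded[b.i, b.j] = bonded[b.j, b.i] = True
            for c in mobile_dimer_topology.contacts:
                bonded[c.i, c.j] = bonded[c.j, c.i] = True
            assert d[~bonded].min() >= hard

    def test_bonds_stay_within_walls(self, mobile_dimer_topology, thermostatted):
        tol = 1e-9
        for b in mobile_dimer_topology.bonds:
            d = np.linalg.norm(
                thermostatted.positions[:, b.i] - thermostatted.positions[:, b.j],
                axis=1,
            )
            assert d.min() >= b.d_min - tol
            assert d.max() <= b.d_max + tol


class TestTrappedPair:
    def test_pair_below_well_depth_never_separates(self):
        s = free_beads([[0, 0, 0], [5.0, 0, 0]], ligand_beads=[1])  # in the L-L well [4, 6)
        topo = build_topology(s)
        # tiny kinetic energy, far below the 0.6 kcal/mol well depth
        vel = np.array([[0.01, 0.005, 0.0], [-0.01, -0.005, 0.0]])
        cfg = SimConfig(
            duration=5000.0, sampling_interval=10.0, thermostat_rate=0.0,
            rng_seed=0, box_edge=200.0,
        )
        traj = run(topo, cfg, velocities=vel)
        d = np.linalg.norm(traj.positions[:, 0] - traj.positions[:, 1], axis=1)
        assert d.max() < 6.0


class TestOracleEquivalence:
    def brute_force(self, pos0, vel0, masses, pairs, t_end, dt=0.01):
        """Small-timestep propagation with bisected boundary crossings.

        ``pairs`` maps (i, j) -> (radii, levels) with levels[q] the energy of
        region q; purely positional detection, no event queue.
        """
        pos = pos0.copy()
        vel = vel0.copy()
        region = {}
        for (i, j), (radii, levels) in pairs.items():
            d = np.linalg.norm(pos[i] - pos[j])
            region[(i, j)] = int(np.searchsorted(radii, d))
        t = 0.0
        while t < t_end - 1e-12:
            step = min(dt, t_end - t)
            # find earliest crossing within the step by bisection per pair
            best = None
            for (i, j), (radii, levels) in pairs.items():
                q = region[(i, j)]
                r_rel = pos[i] - pos[j]
                v_rel = vel[i] - vel[j]

                def dist(tt):
                    return np.linalg.norm(r_rel + v_rel * tt)

                for boundary, dirn in ((q - 1, -1), (q, +1)):
                    if boundary < 0 or boundary >= len(radii):
                        continue
                    target = radii[boundary]
                    f0 = dist(0.0) - target
                    f1 = dist(step) - target
                    if f0 == 0.0 or f0 * f1 > 0:
                        continue
                    lo, hi = 0.0, step
                    for _ in range(80):
                        mid = 0.5 * (lo + hi)
                        if (dist(mid) - target) * f0 > 0:
                            lo = mid
                        else:
                            hi = mid
                    tc = 0.5 * (lo + hi)
                    if best is None or tc < best[0]:
                        best = (tc, i, j, boundary, dirn)
            if best is None:
                pos += vel * step
                t += step
                continue
            tc, i, j, boundary, dirn = best
            pos += vel * tc
            t += tc
            radii, levels = pairs[(i, j)]
            q = region[(i, j)]
            q_new = q + dirn
            du = levels[q_new] - levels[q]
            n_hat = (pos[i] - pos[j]) / np.linalg.norm(pos[i] - pos[j])
            v_r = (vel[i] - vel[j]) @ n_hat
            mu = masses[i] * masses[j] / (masses[i] + masses[j])
            if math.isinf(du) or (du > 0 and 0.5 * mu * v_r**2 <= du):
                v_r_new = -v_r
            else:
                v_r_new = math.copysign(math.sqrt(v_r**2 - 2 * du / mu), v_r)
                region[(i, j)] = q_new
            dvr = v_r_new - v_r
            vel[i] += (mu / masses[i]) * dvr * n_hat
            vel[j] -= (mu / masses[j]) * dvr * n_hat
            # step just past the boundary so it is not re-detected
            pos += vel * 1e-7
            t += 1e-7
        return pos

    def test_three_bead_trajectory_matches_brute_force(self):
        s = free_beads([[0.0, 0, 0], [5.0, 0, 0], [2.5, 4.5, 0]], ligand_beads=[2])
        topo = build_topology(s)
        vel = np.array(
            [[0.06, 0.025, 0.0], [-0.05, 0.035, 0.012], [-0.012, -0.06, -0.012]]
        )
        vel -= vel.mean(axis=0)
        duration = 1200.0
        cfg = SimConfig(
            duration=duration, sampling_interval=duration, thermostat_rate=0.0,
            rng_seed=0, box_edge=200.0,
        )
        traj = run(topo, cfg, velocities=vel)
        assert traj.n_events >= 20

        comp = compile_topology(topo)
        pairs = {}
        for i in range(3):
            for j in range(i + 1, 3):
                p = comp.pot_id[i, j]
                radii = comp.radii[p, : comp.nshell[p]]
                levels = [
                    math.inf if lv >= 1e29 else lv
                    for lv in comp.levels[p, : comp.nshell[p] + 1]
                ]
                pairs[(i, j)] = (radii, levels)
        pos0 = topo.structure.positions.copy()
        final = self.brute_force(pos0, vel.copy(), comp.masses, pairs, duration)
        np.testing.assert_allclose(traj.positions[-1], final, atol=1e-4)


class TestSteeringAndImmobilization:
    def test_immobilized_domain_never_moves(self, centered):
        topo = build_topology(centered)
        cfg = SimConfig(
            duration=500.0, sampling_interval=25.0, thermostat_rate=0.1,
            rng_seed=7, box_edge=80.0,
        )
        proto = build_force_protocol(20.0, (0, 0, 1))
        traj = run(topo, cfg, proto)
        imm = topo.immobilized
        for f in range(traj.n_frames):
            np.testing.assert_array_equal(
                traj.positions[f, imm], traj.positions[0, imm]
            )

    def test_total_energy_conserved_with_force_no_thermostat(self):
        s = two_domain_pair(separation=6.0)
        topo = build_topology(
            s, options=TopologyOptions(contact_energy=1.5, contact_well_width=0.5,
                                       contact_cutoff=7.0)
        )
        proto = build_force_protocol(30.0, (1, 0, 0))
        vel = np.zeros((2, 3))
        vel[1] = [0.05, 0.01, 0.0]
        cfg = SimConfig(
            duration=1500.0, sampling_interval=15.0, thermostat_rate=0.0,
            rng_seed=0, box_edge=200.0,
        )
        traj = run(topo, cfg, proto, velocities=vel)
        drift = np.abs(traj.total_energy - traj.total_energy[0]).max()
        assert drift <= 1e-8

    def test_replica_reproducibility(self, centered):
        topo = build_topology(centered)
        cfg = SimConfig(
            duration=100.0, sampling_interval=10.0, thermostat_rate=0.1,
            rng_seed=0, box_edge=80.0,
        )
        a = run_replicas(topo, cfg, None, 2, base_seed=42)
        b = run_replicas(topo, cfg, None, 2, base_seed=42)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)
        assert not np.array_equal(a[0].positions, a[1].positions)
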