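"""Run one event-driven trajectory of the dimer and check its physics.

Prints the event count, the exact energy conservation of an unforced,
unthermostatted run, and the kinetic temperature under the Anderson
thermostat (should sit at the 300 K target).
"""

import numpy as np

from godmd import KB, SimConfig, build_topology, generate_toy_dimer, run

dimer = generate_toy_dimer(20, 14, 0.4, [3, 9], seed=1)
dimer.positions += 40.0 - dimer.positions.mean(axis=0)
topo = build_topology(dimer).mobilized()

nve = run(topo, SimConfig(duration=500.0, sampling_interval=50.0,
                          thermostat_rate=0.0, rng_seed=2, box_edge=80.0))
drift = np.abs(nve.total_energy - nve.total_energy[0]).max()
print(f"NVE: {nve.n_events} events, max energy drift {drift:.2e} kcal/mol")

nvt = run(topo, SimConfig(duration=1000.0, sampling_interval=10.0,
                          thermostat_rate=0.1, rng_seed=3, box_edge=80.0))
half = nvt.n_frames // 2
t_kin = nvt.kinetic[half:].mean() / (3 * topo.n_beads) / (0.5 * KB)
print(f"thermostatted: kinetic temperature {t_kin:.0f} K (target 300 K)")
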