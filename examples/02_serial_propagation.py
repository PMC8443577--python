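"""Serial propagation of the consortium under the three growth scenarios.

Starting from equal thirds of cooperator A, cooperator B and cheater, the
population is repeatedly emulsified at lambda = 0.15, grown, and pooled.
Whether the cheater wins depends entirely on cooperation-independent
background growth: none (dependent) -> cooperators win; equal background
for everyone (costless) -> slow cooperator enrichment; cheaper background
for the cheater (costly) -> the cheater takes over.
"""

import numpy as np

from dropcoop import OccupancyModel, PopulationState, propagate, scenario_preset

occ = OccupancyModel(lam=0.15)
start = PopulationState(np.array([1 / 3, 1 / 3, 1 / 3]))

for name in ("dependent", "costless_background", "costly_background"):
    consortium, params = scenario_preset(name)
    traj = propagate(start, 6, occ, consortium, params)
    cheater = traj.fractions_matrix()[:, 2]
    print(f"{name:22s} cheater fraction per round: "
          + " ".join(f"{x:.3f}" for x in cheater))

# dependent:           cheater collapses toward 0 within a few rounds
# costless_background:  cheater declines, but much more slowly
# costly_background:    cheater rises toward fixation despite paying nothing
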