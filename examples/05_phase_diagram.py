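"""Cost/benefit phase diagram: cheater fraction after 40 propagations.

The benefit of cooperation is the fraction of the droplet carrying capacity
only reachable with a cooperator pair; the cost is the percentage by which
cooperators' independent growth trails the cheater's. Each cell starts at
50% cooperator A, 1% cooperator B, 49% cheater and is propagated 40 times
at lambda = 2.
"""

import numpy as np

from dropcoop import PhaseDiagramSpec, run_phase_diagram

spec = PhaseDiagramSpec(
    benefit_grid=np.linspace(0, 1, 6),
    cost_grid=np.linspace(0, 100, 6),
)
df = run_phase_diagram(spec)
piv = df.pivot(
    index="cost_percent", columns="benefit_fraction", values="final_cheater_fraction"
)
print("final cheater fraction (rows: cost %, columns: benefit fraction)")
print(piv.round(2).to_string())

# Corners: high benefit + low cost -> cooperators sweep (bottom right ~0);
# low benefit + high cost -> cheater fixes (top left ~1); low benefit + low
# cost -> stable coexistence at an intermediate cheater fraction.
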