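"""Simulate the ground-truth network and infer causal flow at rest.

Three Roessler coordinates (subnetwork X) drive 100 tanh rate units
(subnetwork Y) with no feedback.  Cross-mapping should therefore reconstruct
the driver from a driven unit far better than the reverse: high CF in column
x1 / row y4, low CF in column y4 / row x1.
"""

import numpy as np

from causalflow import SimulatorParams, compute_cf_matrix, simulate_network

params = SimulatorParams(seed=1)  # 103 units, 200 time units post-transient
ts = simulate_network(params)
print(f"simulated {ts.n_units} units x {ts.n_samples} samples (dt={ts.dt})")

sub = ts.subset(["x1", "x2", "x3", "y4", "y20", "y50"]).bin(0.1)
cf = compute_cf_matrix(sub, d=8, tau=8)

np.set_printoptions(precision=2, suppress=True)
print("\nCF matrix (rows=targets/reconstructors, cols=sources):")
print(cf.unit_ids)
print(cf.values)

i_y4, i_x1 = sub.unit_ids.index("y4"), sub.unit_ids.index("x1")
print(f"\nF[y4 <- x1] (reconstruct driver from driven unit): {cf.values[i_y4, i_x1]:.3f}")
print(f"F[x1 <- y4] (reverse direction):                    {cf.values[i_x1, i_y4]:.3f}")
print(
    "\nThe first number is the Fisher-z cross-map skill of the true causal\n"
    "direction and should clearly exceed the second; within-X entries are\n"
    "much larger still because the three driver coordinates are mutually\n"
    "near-deterministic."
)
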