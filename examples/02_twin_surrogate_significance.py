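"""Assign significance to causal-flow entries with twin surrogates.

Twin surrogates re-thread the reconstructor's trajectory through phase-space
twins, preserving its attractor while breaking its temporal alignment with
any source.  A CF entry is significant when the empirical cross-map skill
ranks high enough above the surrogate ensemble's skills (one-sided add-one
empirical p-value below alpha).
"""

import numpy as np

from causalflow import SimulatorParams, cf_significance, compute_cf_matrix, simulate_network

ts = simulate_network(SimulatorParams(seed=1))
sub = ts.subset(["x1", "x3", "y4"]).bin(0.1)
cf = compute_cf_matrix(sub, d=8, tau=8)
out = cf_significance(sub, cf, n_surrogates=99, alpha=0.05, seed=1)

print("units:", out.unit_ids)
print("CF (Fisher z):")
print(np.round(out.values, 2))
print("surrogate p-values:")
print(np.round(out.pvals, 2))
print("significant at alpha=0.05:")
print(out.sig_mask.astype(int))
print(
    "\nExpected pattern: the two driver coordinates (x1, x3) reconstruct each\n"
    "other significantly in both directions; reconstruction of the driver\n"
    "from the driven unit y4 beats the surrogates when the coupling is\n"
    "strong enough, while the reverse direction never does."
)
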