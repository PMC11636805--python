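"""Pulse-perturb single units and measure interventional connectivity.

IC quantifies the effect of stimulating source j on target i as the KS
statistic between the target's window-summed activity before pulse onset vs
after pulse offset, across trials.  Stimulating a driver coordinate shifts
the driven units; stimulating a driven unit leaves the driver untouched.
"""

import numpy as np

from causalflow import (
    PerturbationSession,
    SimulatorParams,
    compute_ic_matrix,
    make_trial_onsets,
    run_perturbation_session,
)
from causalflow.evaluation import gini

params = SimulatorParams(duration=330.0, transient=20.0, seed=2)
units = ["x1", "x2", "x3", "y4", "y20", "y50"]
sessions = []
for k, unit in enumerate(["x1", "y20"]):
    onsets = make_trial_onsets(20, record_duration=310.0, seed=10 + k)
    sess = PerturbationSession(stimulated_unit=unit, trial_onsets=onsets, pulse_strength=10.0)
    rec = run_perturbation_session(params, sess)
    sess.recording = rec.subset(units)
    sessions.append(sess)

ic = compute_ic_matrix(sessions, alpha=0.05, n_perms=499, seed=0)
np.set_printoptions(precision=2, suppress=True)
print("units:", ic.unit_ids)
print("IC (KS statistic; columns = stimulated sources x1, y20):")
print(ic.values)
print("significant effects:")
print(ic.sig_mask.astype(int))

s_x1 = ic.values[:, 0]
print(f"\nGini of the x1 perturbation vector: {gini(s_x1[np.isfinite(s_x1)]):.2f}")
print(
    "\nStimulating x1 (a driver coordinate) perturbs both the other driver\n"
    "coordinates and the rate units; stimulating y20 shows no significant\n"
    "effect on any x row — the network has no feedback from Y to X.  A large\n"
    "Gini coefficient means the perturbation touches targets unevenly\n"
    "(hierarchical effect), a small one means a uniform effect."
)
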