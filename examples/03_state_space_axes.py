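"""Fit the PCA state space and read off the Initiation/Selection axes.

Condition-averaged Z rates (500 ms around Center Out, contra then ipsi) are
stacked into the population matrix R (502 x N), PCA is computed by SVD, and
two behaviorally-anchored axes are defined in the 10-D score space:
Initiation (Go-cue mean -> 0, Center-Out mean -> 1) and Selection
(ipsi mean -> -1, contra mean -> +1).
"""

import numpy as np

import gpstop as g
from gpstop.params import params_to_dict
from gpstop.pipeline import AnalysisConfig, _mask, prepare_session
from gpstop.statespace import project_alignment

task = g.TaskParams(n_go_trials=130, n_stop_trials=30, iti_range=(1.0, 2.0))
pop = g.PopulationParams(n_neurons=60)
cfg = AnalysisConfig(seed=3, generator=params_to_dict(task, g.RaceParams(), pop),
                     n_shuffles=300)
sd = prepare_session(cfg)

ve = sd.model.variance_explained
print(f"population matrix R: {sd.pm.R.shape[0]} x {sd.pm.R.shape[1]} "
      f"({sd.pm.n_time} timepoints x 2 conditions)")
print(f"variance explained, PC1-3: {ve[0]:.2f}, {ve[1]:.2f}, {ve[2]:.2f} "
      f"(cumulative {ve[:3].sum():.2f})")

ax = sd.axes
print("axis anchors (scaled): "
      f"Go cue -> {ax.initiation_coord(ax.a0):.3f}, "
      f"Center Out -> {ax.initiation_coord(ax.a1):.3f}, "
      f"ipsi mean -> {ax.selection_coord(ax.m_ipsi):.3f}, "
      f"contra mean -> {ax.selection_coord(ax.m_contra):.3f}")

go = sd.tensors["go_cue"]
for cond in ("no_stop", "maybe_stop_contra"):
    m = _mask(sd.df, go, condition=cond)
    traj = project_alignment(go, sd.model, m, ax)
    i0 = int(np.argmin(np.abs(traj.times)))
    print(f"state at Go cue [{cond}]: initiation={traj.initiation[i0]:+.2f}, "
          f"selection={traj.selection[i0]:+.2f}  (n={traj.n_trials} trials)")
# Under proactive inhibition the Go-cue state sits below 0 on the Initiation
# Axis (farther from movement onset) and on the ipsi side of the Selection
# Axis (biased against the contra action that might need cancelling).
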