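"""LIF network: grouped parameters and array-valued monitors.

A population of leaky integrate-and-fire neurons with random inhibitory
delta synapses is simulated for three coupling strengths.  The synaptic
parameters live in their own 'syn' subgroup; each run stores the spike
monitor and neuron 0's voltage trace.
"""

import tempfile, os

from trajkit import load_trajectory
from trajkit.experiments import run_lif_experiment

tmp = tempfile.mkdtemp()
filename = os.path.join(tmp, "lif.h5")

env, outcomes = run_lif_experiment(filename=filename,
                                   weights=(0.0, -0.1, -1.0))
env.close()

traj = load_trajectory(filename)
for i, nspikes in outcomes:
    traj.current_run_index = i
    spmon = traj["results.runs.crun.spmon"]
    vtrace = traj["results.runs.crun.vtrace"]
    print(f"run {i}: w = {traj['syn.w']:+.1f}  ->  {nspikes:4d} spikes, "
          f"mean V of neuron 0 = {vtrace.mean():.3f}")
traj.current_run_index = -1
# stronger inhibition (more negative w) lowers the population spike count
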