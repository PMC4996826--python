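"""Bookkeeping features: merging same-space trajectories and resuming.

Two cellular-automata trajectories over different rule sets are merged
into one (with duplicate points skipped); then a half-finished experiment
is resumed so that only the incomplete runs execute.
"""

import tempfile, os, logging

from trajkit import Environment, load_trajectory, store_trajectory
from trajkit.experiments import run_ca_experiment

tmp = tempfile.mkdtemp()

env_a, _ = run_ca_experiment(filename=os.path.join(tmp, "a.h5"),
                             rules=[10, 30, 90], ncells=40, steps=30)
env_b, _ = run_ca_experiment(filename=os.path.join(tmp, "b.h5"),
                             rules=[90, 110, 184], ncells=40, steps=30)
env_a.close(); env_b.close()

a = load_trajectory(os.path.join(tmp, "a.h5"))
b = load_trajectory(os.path.join(tmp, "b.h5"))
a.merge(b, remove_duplicates=True)   # rule 90 appears in both
print(f"merged: {a.n_runs} runs")    # 3 + 3 - 1 = 5
store_trajectory(a, os.path.join(tmp, "merged.h5"))

# --- resume ---------------------------------------------------------------


def slow_model(traj):
    traj.add_result("out", traj.p * 10.0)
    return traj.p


fn = os.path.join(tmp, "resumable.h5")
env = Environment("resumable", filename=fn, log_level=logging.ERROR)
env.traj.add_parameter("p", 0.0)
env.traj.explore({"p": [float(i) for i in range(8)]})
table = list(env.traj.run_table)
env.traj.run_table = table[:5]       # pretend the process died after 5 runs
env.run(slow_model)
env.traj.run_table = table
env.storage.store_run_table(env.traj)
env.close()

loaded = load_trajectory(fn)
env2 = Environment(loaded, filename=fn, log_level=logging.ERROR)
outcomes = env2.resume(slow_model)
env2.close()
print("resumed run indices:", [i for i, _ in outcomes])  # [5, 6, 7]
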