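"""Elementary cellular automata: parallel runs and lazy reloading.

Six transition rules are explored on four worker processes; afterwards the
trajectory is recovered from disk loading only the skeleton, and each cell
pattern is pulled in on demand while iterating the runs.
"""

import tempfile, os

from trajkit import Environment, SKELETON, load_trajectory
from trajkit.models import ca_run

tmp = tempfile.mkdtemp()
filename = os.path.join(tmp, "cellular_automata.h5")

env = Environment(trajectory="cellular_automata", filename=filename,
                  multiproc=True, ncores=4)
traj = env.traj
traj.add_parameter("rule_number", 0, comment="decimal transition rule")
traj.add_parameter("ncells", 100, comment="number of cells")
traj.add_parameter("steps", 100, comment="number of time steps")
traj.add_parameter("seed", 42, comment="seed for the initial condition")
traj.explore({"rule_number": [10, 30, 90, 110, 184, 190]})
env.run(ca_run)
env.close()

# analysis phase: skeleton load + on-demand loading of each pattern
traj = load_trajectory(filename, level=SKELETON, auto_load=True)
for run in traj.iter_runs():
    pattern = traj["results.runs.crun.pattern"]
    print(f"{run}: rule {traj.rule_number:3d}, pattern {pattern.shape}, "
          f"{pattern.mean():.2f} of cells active on average")

# which runs used a rule strictly between 30 and 120?
print("rules in (30, 120) at run indices:",
      traj.find_run_indices(["rule_number"], lambda r: 30 < r < 120))
# -> [2, 3]
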