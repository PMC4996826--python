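"""Adaptive exploration: alternate run and post-processing phases.

A greedy stochastic optimizer maximizes a sixth-order polynomial.  Every
generation expands the trajectory by 200 points sampled around the best
point so far, runs them, and records the generation's best.  Automatic
storing is off; the trajectory is stored manually once at the end.
"""

import tempfile, os, logging

from trajkit import Environment
from trajkit.models import greedy_optimize, objective

tmp = tempfile.mkdtemp()
env = Environment(trajectory="stochastic_optimization",
                  filename=os.path.join(tmp, "optimization.h5"),
                  automatic_storing=False, log_level=logging.ERROR)
env.traj.add_parameter("x", 0.0, comment="point at which to evaluate")

best_x, best_val = greedy_optimize(env, ngen=30, popsize=200, sigma=0.5,
                                   seed=42)
env.close()

print(f"total runs: {env.traj.n_runs}")          # 30 x 200 = 6000
print(f"best point: x = {best_x:.4f}")
print(f"best value: f(x) = {best_val:.1f}")
print(f"value at the start point:   f(0) = {objective(0.0):.1f}")
# the best value can only improve from generation to generation
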