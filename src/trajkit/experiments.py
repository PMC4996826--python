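"""Ready-made experiments wiring the bundled models into environments.

Each function builds a trajectory, declares the model's parameters,
installs the exploration, executes the runs and (when a filename is given)
persists the result — the boilerplate a user would otherwise write in a
driver script.  They return the environment plus whatever the run phase
produced, so callers can post-process or inspect further.
"""

from __future__ import annotations

import logging
from typing import Any, Sequence

from . import models
from .runner import Environment
from .tree import cartesian_product

#: exploration used by the automaton experiment (six named rules)
CA_RULES = [10, 30, 90, 110, 184, 190]


def run_multiply_experiment(filename: str | None = None,
                            trajectory: str = "multiply",
                            x_values: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
                            y_values: Sequence[float] = (6.0, 7.0, 8.0),
                            multiproc: bool = False, ncores: int = 1,
                            automatic_storing: bool = True,
                            log_dir: str | None = None,
                            log_level: int = logging.WARNING,
                            ) -> tuple[Environment, list[tuple[int, Any]]]:
    """Explore z = x·y over the Cartesian product of the two value lists.

    With the defaults this evokes the model twelve times, on the points
    (1.0, 6.0), (2.0, 6.0), …, (4.0, 8.0) — x cycles fastest.
    """
    env = Environment(trajectory=trajectory, filename=filename,
                      multiproc=multiproc, ncores=ncores,
                      automatic_storing=automatic_storing,
                      log_dir=log_dir, log_level=log_level)
    traj = env.traj
    traj.add_parameter("x", 1.0, comment="I am the first dimension!")
    traj.add_parameter("y", 1.0, comment="I am the second dimension!")
    traj.explore(cartesian_product({"x": list(x_values),
                                    "y": list(y_values)}))
    outcomes = env.run(models.multiply)
    return env, outcomes


def run_ca_experiment(filename: str | None = None,
                      trajectory: str = "cellular_automata",
                      rules: Sequence[int] = tuple(CA_RULES),
                      ncells: int = 100, steps: int = 100, seed: int = 42,
                      multiproc: bool = False, ncores: int = 1,
                      automatic_storing: bool = True,
                      log_dir: str | None = None,
                      log_level: int = logging.WARNING,
                      ) -> tuple[Environment, list[tuple[int, Any]]]:
    """Simulate elementary cellular automata for several transition rules.

    One single run per rule number; each run stores the full (steps ×
    ncells) cell pattern as its result.
    """
    env = Environment(trajectory=trajectory, filename=filename,
                      multiproc=multiproc, ncores=ncores,
                      automatic_storing=automatic_storing,
                      log_dir=log_dir, log_level=log_level)
    traj = env.traj
    traj.add_parameter("rule_number", 0,
                       comment="decimal representation of the transition rule")
    traj.add_parameter("ncells", ncells, comment="number of cells n")
    traj.add_parameter("steps", steps, comment="number of time steps k")
    traj.add_parameter("seed", seed,
                       comment="seed for the random initial condition")
    traj.explore({"rule_number": list(rules)})
    outcomes = env.run(models.ca_run)
    return env, outcomes


def run_optimizer_experiment(filename: str | None = None,
                             trajectory: str = "stochastic_optimization",
                             ngen: int = 30, popsize: int = 200,
                             sigma: float = 0.5, seed: int = 42,
                             log_dir: str | None = None,
                             log_level: int = logging.ERROR,
                             ) -> tuple[Environment, float, float]:
    """Greedily maximize the example polynomial by adaptive exploration.

    Alternates run and post-processing phases: every generation expands the
    trajectory by ``popsize`` Gaussian samples (width ``sigma``) around the
    best point, so the final run table holds ``ngen × popsize`` runs.
    Automatic storing is off; the result is stored manually at the end.
    Returns ``(env, best_x, best_val)``.
    """
    env = Environment(trajectory=trajectory, filename=filename,
                      automatic_storing=False,
                      log_dir=log_dir, log_level=log_level)
    traj = env.traj
    traj.add_parameter("x", 0.0, comment="point at which to evaluate")
    traj.add_parameter("ngen", ngen, comment="number of generations")
    traj.add_parameter("popsize", popsize, comment="points per generation")
    traj.add_parameter("sigma", sigma, comment="width of the sampling normal")
    best_x, best_val = models.greedy_optimize(env, seed=seed)
    return env, best_x, best_val


def run_lif_experiment(filename: str | None = None,
                       trajectory: str = "lif_network",
                       weights: Sequence[float] = (0.0, -0.1, -1.0),
                       n_neurons: int = 100, duration: float = 500.0,
                       seed: int = 42,
                       multiproc: bool = False, ncores: int = 1,
                       automatic_storing: bool = True,
                       log_dir: str | None = None,
                       log_level: int = logging.WARNING,
                       ) -> tuple[Environment, list[tuple[int, Any]]]:
    """Simulate the LIF network for several inhibitory coupling strengths.

    Parameters are grouped: the synaptic weight lives at ``syn.w`` and the
    connection probability at ``syn.p_conn``.  Each run stores the spike
    monitor (times and neuron indices) and neuron 0's voltage trace, and
    returns the total spike count.
    """
    defaults = models.LIFConfig()
    env = Environment(trajectory=trajectory, filename=filename,
                      multiproc=multiproc, ncores=ncores,
                      automatic_storing=automatic_storing,
                      log_dir=log_dir, log_level=log_level)
    traj = env.traj
    traj.add_parameter("n_neurons", n_neurons, comment="network size")
    traj.add_parameter("tau", defaults.tau,
                       comment="membrane time constant (ms)")
    traj.add_parameter("VT", defaults.VT, comment="spike threshold")
    traj.add_parameter("I0", defaults.I0, comment="static input")
    traj.add_parameter("syn.w", 0.0, comment="synaptic weight (w <= 0)")
    traj.add_parameter("syn.p_conn", defaults.p_conn,
                       comment="connection probability")
    traj.add_parameter("dt", defaults.dt, comment="integration step (ms)")
    traj.add_parameter("duration", duration, comment="simulated time (ms)")
    traj.add_parameter("seed", seed, comment="connectivity/initialization seed")
    traj.explore({"syn.w": [float(w) for w in weights]})
    outcomes = env.run(models.lif_run)
    return env, outcomes
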