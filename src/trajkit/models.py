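"""Bundled example models.

Four small simulations exercise every layer of the toolkit:

* :func:`multiply` — the minimal two-parameter model, z = x·y.
* elementary cellular automata — a 1-D binary lattice of *n* cells updated
  over *k* steps by one of the 256 three-cell-neighborhood transition
  rules, with periodic boundaries.
* :func:`objective` — a sixth-order polynomial maximized by a greedy
  stochastic hill climber that adaptively expands the trajectory.
* a leaky integrate-and-fire (LIF) network — plain-NumPy forward-Euler
  integration of randomly coupled inhibitory delta-synapse neurons.

Each model comes as a pure function plus a thin wrapper reading its
parameters from a trajectory and adding its results back.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# multiply
# ---------------------------------------------------------------------------

def multiply(traj) -> float:
    """z = x · y; adds z as a per-run result and returns it."""
    z = traj.x * traj.y
    traj.add_result("z", z, comment="product of x and y")
    return z


# ---------------------------------------------------------------------------
# elementary cellular automata
# ---------------------------------------------------------------------------

@dataclass
class CAConfig:
    """Configuration of one elementary cellular-automaton simulation.

    ``rule_number`` is the decimal encoding of the transition function:
    bit *b* of the rule, with b = 4·s(left) + 2·s(center) + s(right),
    is the cell's next state for that neighborhood.
    """

    rule_number: int
    ncells: int = 100
    steps: int = 100
    seed: int = 42
    initial_state: Sequence[int] | None = None

    def __post_init__(self):
        if not 0 <= self.rule_number < 256:
            raise ValueError("rule_number must lie in [0, 255]")
        if self.ncells < 3:
            raise ValueError("need at least 3 cells")
        if self.steps < 1:
            raise ValueError("need at least 1 time step")


def ca_step(state: np.ndarray, rule_number: int) -> np.ndarray:
    """Advance a binary lattice one step under the given rule.

    Boundaries are periodic: the first and last cells see each other as
    neighbors.
    """
    state = np.asarray(state)
    if not np.isin(state, (0, 1)).all():
        raise ValueError("cell states must be binary (0 or 1)")
    left = np.roll(state, 1)
    right = np.roll(state, -1)
    neighborhood = 4 * left + 2 * state + right
    return (rule_number >> neighborhood) & 1


def cellular_automaton(cfg: CAConfig) -> np.ndarray:
    """Full cell pattern: a (steps × ncells) binary matrix, row per time step.

    Row 0 is the initial condition — explicit if given, otherwise drawn
    uniformly from a generator seeded with ``cfg.seed`` (deterministic for
    a fixed seed).
    """
    if cfg.initial_state is not None:
        row = np.asarray(cfg.initial_state, dtype=np.int64)
        if row.shape != (cfg.ncells,):
            raise ValueError("initial_state length must equal ncells")
    else:
        rng = np.random.default_rng(cfg.seed)
        row = rng.integers(0, 2, cfg.ncells)
    pattern = np.empty((cfg.steps, cfg.ncells), dtype=np.int64)
    pattern[0] = row
    for t in range(1, cfg.steps):
        pattern[t] = ca_step(pattern[t - 1], cfg.rule_number)
    return pattern


def ca_run(traj) -> None:
    """Trajectory wrapper: run one automaton and store its pattern."""
    cfg = CAConfig(rule_number=traj.rule_number, ncells=traj.ncells,
                   steps=traj.steps, seed=traj.seed)
    pattern = cellular_automaton(cfg)
    traj.add_result("pattern", pattern,
                    comment="cell states of all cells at all time steps")


# ---------------------------------------------------------------------------
# stochastic optimization example
# ---------------------------------------------------------------------------

def objective(x: float) -> float:
    """The polynomial −(x+4)^6 + 5(x−10)^4 − 2(x−4)^2 + x to maximize."""
    return -(x + 4) ** 6 + 5 * (x - 10) ** 4 - 2 * (x - 4) ** 2 + x


def eval_objective(traj) -> float:
    """Trajectory wrapper: evaluate the objective at the run's x."""
    return objective(traj.x)


def greedy_optimize(env, ngen: int | None = None,
                    popsize: int | None = None,
                    sigma: float | None = None,
                    seed: int = 42) -> tuple[float, float]:
    """Greedy stochastic hill climbing by alternating runs and expansion.

    Per generation, ``popsize`` candidate points are drawn from a normal
    distribution of width ``sigma`` centered at the best point so far, the
    trajectory is expanded by them, the model runs, and the best point is
    updated from the returned values.  The per-generation best is recorded
    as a result and — because the caller typically disables automatic
    storing — everything is stored manually at the end.

    Unset arguments fall back to the trajectory parameters ``ngen``,
    ``popsize`` and ``sigma``.  Returns ``(best_x, best_val)``.
    """
    traj = env.traj
    ngen = ngen if ngen is not None else traj.ngen
    popsize = popsize if popsize is not None else traj.popsize
    sigma = sigma if sigma is not None else traj.sigma
    rng = np.random.default_rng(seed)
    best_x = float(traj["parameters.x"])
    best_val = objective(best_x)
    for gen in range(ngen):
        points = [float(v)
                  for v in best_x + sigma * rng.standard_normal(popsize)]
        traj.expand({"x": points})
        results = env.run(eval_objective)
        for index, value in results:
            if value is not None and value > best_val:
                best_val = value
                best_x = traj.get_node("parameters.x").value_at(index)
        traj.add_result(f"generations.gen_{gen:03d}",
                        best_x=float(best_x), best_val=float(best_val),
                        comment="best point after this generation")
        env.logger.info("generation %d: best f(%g) = %g",
                        gen, best_x, best_val)
    traj.add_result("final", best_x=float(best_x), best_val=float(best_val),
                    comment="overall best point")
    if env.storage is not None:
        env.store()
    return float(best_x), float(best_val)


# ---------------------------------------------------------------------------
# leaky integrate-and-fire network
# ---------------------------------------------------------------------------

@dataclass
class LIFConfig:
    """Configuration of the LIF network simulation.

    Each neuron's voltage relaxes toward the static input ``I0`` with time
    constant ``tau`` (ms); crossing the threshold ``VT`` emits a spike and
    resets the voltage to 0.  Neurons are randomly coupled with
    probability ``p_conn``; a presynaptic spike kicks each connected
    target's voltage by ``w`` (inhibitory, w ≤ 0) at the following step.
    """

    n_neurons: int = 100
    tau: float = 10.0        # membrane time constant, ms
    VT: float = 1.0          # spike threshold
    I0: float = 1.1          # static input (same units as VT)
    w: float = -0.02         # synaptic weight, <= 0
    p_conn: float = 0.1      # connection probability
    dt: float = 0.1          # integration step, ms
    duration: float = 500.0  # simulated time, ms
    seed: int = 42

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.w > 0:
            raise ValueError("only inhibitory coupling (w <= 0) is modeled")
        if not 0 <= self.p_conn <= 1:
            raise ValueError("p_conn must lie in [0, 1]")


def lif_simulate(cfg: LIFConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-Euler simulation of the randomly coupled LIF network.

    Initial voltages are uniform on [0, VT).  Spikes detected at step *t*
    are delivered to the spikers' targets at step *t+1* (no
    self-connections).  Returns ``(spike_times, spike_neurons, vtrace)``
    where ``vtrace`` is neuron 0's voltage at every step.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons
    conn = rng.random((n, n)) < cfg.p_conn  # conn[pre, post]
    np.fill_diagonal(conn, False)
    v = rng.uniform(0.0, cfg.VT, n)
    nsteps = int(round(cfg.duration / cfg.dt))
    vtrace = np.empty(nsteps, dtype=np.float64)
    spike_times: list[float] = []
    spike_neurons: list[int] = []
    spiking_prev = np.zeros(n, dtype=bool)
    alpha = cfg.dt / cfg.tau
    for t in range(nsteps):
        vtrace[t] = v[0]
        v += alpha * (cfg.I0 - v)
        if spiking_prev.any():
            v += cfg.w * conn[spiking_prev].sum(axis=0)
        spiking = v >= cfg.VT
        if spiking.any():
            now = (t + 1) * cfg.dt
            for i in np.flatnonzero(spiking):
                spike_times.append(now)
                spike_neurons.append(int(i))
            v[spiking] = 0.0
        spiking_prev = spiking
    return (np.asarray(spike_times, dtype=np.float64),
            np.asarray(spike_neurons, dtype=np.int64),
            vtrace)


def lif_run(traj) -> int:
    """Trajectory wrapper: simulate the network, store monitors, return the
    total spike count."""
    cfg = LIFConfig(
        n_neurons=traj.n_neurons, tau=traj.tau, VT=traj.VT, I0=traj.I0,
        w=traj["syn.w"], p_conn=traj["syn.p_conn"],
        dt=traj.dt, duration=traj.duration, seed=traj.seed,
    )
    times, neurons, vtrace = lif_simulate(cfg)
    traj.add_result("spmon", t=times, i=neurons,
                    comment="spike times and neuron indices")
    traj.add_result("vtrace", vtrace,
                    comment="membrane voltage of neuron 0 at every step")
    return len(times)
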