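"""The execution environment: scheduling single runs over explored points.

An :class:`Environment` wires a trajectory to a storage file and executes a
user model — any callable taking the trajectory as first argument — once
per explored parameter point, serially or on a pool of worker processes.
Runs are treated as mutually independent: a worker receives a pruned
trajectory view holding only the parameter values of its own run, and all
file writes happen in the parent process (single-writer rule).

With ``automatic_storing`` on (the default when a filename is given), each
run's result subtree is persisted immediately after the run finishes, so a
crash loses at most the run in flight; :meth:`Environment.resume` then
executes exactly the runs whose records are still pending.

A failing run does not abort its siblings: the exception is written to the
error log, the record is flagged failed, and the first failure is re-raised
(wrapped with its run index) after all remaining runs finish.
"""

from __future__ import annotations

import logging
import os
import pickle
import time
from typing import Any, Callable, Sequence

import multiprocessing as mp

from .containers import Parameter, Result
from .exceptions import NoExplorationError, RunFailedError, SerializationError
from .storage import HDF5StorageService
from .tree import GroupNode, RunRecord, Trajectory, run_name
from .typetags import TypeTagRegistry

logger = logging.getLogger(__name__)


def progress_report(completed: int, total: int,
                    mean_runtime_seconds: float) -> str:
    """One-line progress summary with a remaining-time estimate.

    The ETA is the arithmetic mean runtime of completed runs times the
    number of remaining runs.
    """
    eta = mean_runtime_seconds * (total - completed)
    return f"{completed}/{total} runs completed, ETA {eta:.1f} s"


def setup_logging(name: str, log_dir: str | None, log_level: int
                  ) -> tuple[logging.Logger, list[logging.Handler]]:
    """Create the environment logger with a full log and an error-only log.

    Returns the logger and the handlers that were attached (so they can be
    closed).  Without a ``log_dir`` only a console handler is attached.
    """
    env_logger = logging.getLogger(f"trajkit.env.{name}")
    env_logger.setLevel(logging.DEBUG)
    env_logger.propagate = False
    for h in list(env_logger.handlers):
        env_logger.removeHandler(h)
        h.close()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s")
    handlers: list[logging.Handler] = []
    console = logging.StreamHandler()
    console.setLevel(log_level)
    console.setFormatter(fmt)
    handlers.append(console)
    if log_dir is not None:
        os.makedirs(log_dir, exist_ok=True)
        main = logging.FileHandler(
            os.path.join(log_dir, f"{name}_main.log"))
        main.setLevel(log_level)
        main.setFormatter(fmt)
        handlers.append(main)
        errors = logging.FileHandler(
            os.path.join(log_dir, f"{name}_errors.log"))
        errors.setLevel(logging.ERROR)
        errors.setFormatter(fmt)
        handlers.append(errors)
    for h in handlers:
        env_logger.addHandler(h)
    return env_logger, handlers


def _worker_execute(payload: bytes) -> bytes:
    """Run one single run in a worker process from a pickled payload."""
    (model, args, kwargs, index, n_runs, traj_name,
     param_defs) = pickle.loads(payload)
    traj = Trajectory(traj_name)
    for full_name, value, comment in param_defs:
        path = full_name.split(".", 1)[1]
        traj.add_parameter(path, value, comment)
    traj.run_table = [RunRecord(i) for i in range(n_runs)]
    traj.current_run_index = index
    traj._in_run = True
    t0 = time.perf_counter()
    try:
        returned = model(traj, *args, **kwargs)
        error = None
    except Exception as exc:  # shipped back; parent applies failure policy
        returned = None
        error = f"{type(exc).__name__}: {exc}"
    runtime = time.perf_counter() - t0
    results = _collect_results(traj)
    return pickle.dumps((index, returned, runtime, results, error))


def _collect_results(traj: Trajectory) -> list[tuple[str, str, dict]]:
    """Flatten the results subtree into picklable (path, comment, items)."""
    out = []
    for full_name, node in traj.iter_nodes():
        if isinstance(node, Result):
            out.append((full_name, node.comment, node.items_dict))
    return out


class Environment:
    """Runs a model over all explored parameter points of a trajectory.

    Parameters
    ----------
    trajectory:
        A :class:`~trajkit.tree.Trajectory` or a name for a fresh one.
    filename:
        HDF5 file for automatic and manual storage; omit to keep everything
        in memory.
    multiproc, ncores:
        Execute runs on ``ncores`` worker processes instead of serially.
    automatic_storing:
        Persist each run's results right after the run (requires filename).
    log_level, log_dir:
        Console/main-log severity and directory for the two log files
        (``<name>_main.log`` and ``<name>_errors.log``).
    report_interval:
        Minimum seconds between progress log lines (0 reports every run).
    """

    def __init__(self, trajectory: Trajectory | str = "trajectory",
                 filename: str | None = None, comment: str = "",
                 multiproc: bool = False, ncores: int = 1,
                 automatic_storing: bool = True,
                 log_level: int = logging.INFO,
                 log_dir: str | None = None,
                 report_interval: float = 10.0,
                 registry: TypeTagRegistry | None = None):
        if ncores < 1:
            raise ValueError("ncores must be >= 1")
        if isinstance(trajectory, Trajectory):
            self.traj = trajectory
        else:
            self.traj = Trajectory(trajectory, comment, registry=registry)
        self.multiproc = multiproc
        self.ncores = ncores
        self.automatic_storing = automatic_storing
        self.report_interval = report_interval
        self.storage: HDF5StorageService | None = None
        if filename is not None:
            self.storage = HDF5StorageService(
                filename, registry or self.traj.registry)
            self.traj.storage = self.storage
        self.logger, self._handlers = setup_logging(
            self.traj.name, log_dir, log_level)
        self.last_outcomes: list[tuple[int, Any]] = []

    # -- lifecycle ---------------------------------------------------------

    def close(self) -> None:
        for h in self._handlers:
            self.logger.removeHandler(h)
            h.close()
        self._handlers = []

    def __enter__(self) -> "Environment":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def filename(self) -> str | None:
        return self.storage.filename if self.storage else None

    # -- execution ---------------------------------------------------------

    def run(self, model: Callable[..., Any], *args: Any,
            **kwargs: Any) -> list[tuple[int, Any]]:
        """Execute the model for every pending run, ascending by index.

        Returns the sorted list of ``(run index, returned value)`` tuples.
        Already-completed runs (e.g. after a resume) are skipped.
        """
        traj = self.traj
        if not traj.run_table:
            raise NoExplorationError(
                f"trajectory {traj.name!r} has no exploration; call "
                f"explore() before run()"
            )
        pending = [r for r in traj.run_table if not r.completed]
        if self.storage is not None and self.automatic_storing:
            self.storage.store_tree(traj)
        if self.multiproc:
            outcomes, failures = self._run_parallel(model, args, kwargs,
                                                    pending)
        else:
            outcomes, failures = self._run_serial(model, args, kwargs,
                                                  pending)
        for p in traj._explored_params():
            p.freeze_range()
        if self.storage is not None and self.automatic_storing:
            self.storage.store_run_table(traj)
        outcomes.sort(key=lambda t: t[0])
        self.last_outcomes = outcomes
        if failures:
            index, exc = failures[0]
            raise RunFailedError(
                index, f"run {run_name(index)} failed: {exc}"
            ) from exc
        return outcomes

    def resume(self, model: Callable[..., Any], *args: Any,
               **kwargs: Any) -> list[tuple[int, Any]]:
        """Execute exactly the runs whose records are still incomplete."""
        return self.run(model, *args, **kwargs)

    # -- serial ------------------------------------------------------------

    def _run_serial(self, model, args, kwargs, pending: Sequence[RunRecord]):
        traj = self.traj
        outcomes: list[tuple[int, Any]] = []
        failures: list[tuple[int, BaseException]] = []
        progress = _ProgressTracker(self, len(pending))
        for rec in pending:
            traj.current_run_index = rec.index
            traj._in_run = True
            t0 = time.perf_counter()
            try:
                returned = model(traj, *args, **kwargs)
                outcomes.append((rec.index, returned))
            except Exception as exc:
                rec.failed = True
                self.logger.error(
                    "run %s raised", rec.name, exc_info=True)
                failures.append((rec.index, exc))
            finally:
                traj._in_run = False
                traj.current_run_index = -1
            rec.runtime_seconds = time.perf_counter() - t0
            rec.finished_at = time.time()
            rec.completed = not rec.failed
            self._store_run(rec)
            progress.step(rec)
        return outcomes, failures

    # -- parallel ----------------------------------------------------------

    def _run_parallel(self, model, args, kwargs,
                      pending: Sequence[RunRecord]):
        traj = self.traj
        param_defs = [
            (p.full_name, None, p.comment)
            for p in traj._parameter_leaves().values()
        ]
        payloads = []
        for rec in pending:
            defs = [
                (full_name, traj._node_at(full_name).value_at(rec.index),
                 comment)
                for full_name, _, comment in param_defs
            ]
            item = (model, args, kwargs, rec.index, len(traj.run_table),
                    traj.name, defs)
            try:
                payloads.append(pickle.dumps(item))
            except Exception as exc:
                raise SerializationError(
                    f"cannot serialize run payload for worker processes "
                    f"({exc}); model, arguments and parameter values must "
                    f"be picklable"
                ) from exc
        outcomes: list[tuple[int, Any]] = []
        failures: list[tuple[int, BaseException]] = []
        progress = _ProgressTracker(self, len(pending))
        by_index = {rec.index: rec for rec in pending}
        ctx = mp.get_context("fork" if hasattr(os, "fork") else "spawn")
        with ctx.Pool(processes=self.ncores) as pool:
            for raw in pool.imap(_worker_execute, payloads):
                index, returned, runtime, results, error = pickle.loads(raw)
                rec = by_index[index]
                rec.runtime_seconds = runtime
                rec.finished_at = time.time()
                self._attach_results(results)
                if error is not None:
                    rec.failed = True
                    self.logger.error("run %s raised: %s", rec.name, error)
                    failures.append((index, RunFailedError(index, error)))
                else:
                    outcomes.append((index, returned))
                rec.completed = not rec.failed
                self._store_run(rec)
                progress.step(rec)
        return outcomes, failures

    def _attach_results(self, results: list[tuple[str, str, dict]]) -> None:
        """Graft worker-produced result leaves into the parent tree."""
        traj = self.traj
        for full_name, comment, items in results:
            parts = full_name.split(".")
            parent = traj._make_groups(
                traj.root.children[parts[0]], parts[1:-1])
            if parts[-1] in parent.children:
                continue
            leaf = Result(full_name, comment, registry=traj.registry,
                          **items)
            parent.children[parts[-1]] = leaf

    # -- storage & progress --------------------------------------------------

    def _store_run(self, rec: RunRecord) -> None:
        if self.storage is None or not self.automatic_storing:
            return
        run_group = f"results.runs.{rec.name}"
        try:
            self.traj._node_at(run_group)
        except Exception:
            return  # model added no per-run results
        self.storage.store_node(self.traj, run_group)

    def store(self) -> None:
        """Manually persist the whole trajectory (e.g. after post-processing
        with automatic storing turned off)."""
        if self.storage is None:
            raise IOError("environment has no filename to store into")
        self.storage.store_tree(self.traj)


class _ProgressTracker:
    """Emits progress lines at most once per report interval."""

    def __init__(self, env: Environment, total: int):
        self.env = env
        self.total = total
        self.done = 0
        self.runtime_sum = 0.0
        self._last = time.monotonic()

    def step(self, rec: RunRecord) -> None:
        self.done += 1
        self.runtime_sum += rec.runtime_seconds
        now = time.monotonic()
        if (now - self._last >= self.env.report_interval
                or self.done == self.total):
            self._last = now
            mean = self.runtime_sum / self.done
            self.env.logger.info(
                "%s", progress_report(self.done, self.total, mean))
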