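# trajkit

**trajkit** is a data-management toolkit for numerical experiments that
sweep a parameter space. It is aimed at computational scientists — the
bundled examples come from computational neuroscience — who run the same
model over many parameter combinations and want the parameters, the
per-run results and the bookkeeping to live together, reproducibly, in one
place.

Three pieces cooperate:

- a **trajectory**: a rooted tree container that jointly manages
  parameters and results under natural (dotted attribute) naming, with
  lockable typed parameter containers, exploration ranges, links,
  annotations and a run table;
- an **environment**: a scheduler that executes a user model — any
  callable taking the trajectory as first argument — once per explored
  parameter point, serially or on a process pool, with automatic per-run
  storage, error logs, progress/ETA reporting and crash resuming;
- an **HDF5 storage service**: the whole tree is persisted one-to-one
  into a single HDF5 file and can be recovered at three levels (skeleton,
  structure, full), with transparent on-demand loading of individual nodes.

## The model in brief

An experiment over parameters $p_1,\dots,p_d$ is a *trajectory* through
parameter space: an ordered list of points $(p_1^{(i)},\dots,p_d^{(i)})$,
$i = 0,\dots,L-1$, one *single run* per point. Runs are mutually
independent, which makes the sweep embarrassingly parallel. Exploration
installs, for each explored parameter, an ordered type-homogeneous *range*
of length $L$; `cartesian_product` builds matching ranges from factor
sets, with the first-listed parameter cycling fastest. Results added
during run $i$ are sorted under `results.runs.run_{i:08d}`, and the token
`crun` in any query addresses the currently selected run. A trajectory
can be *expanded* after running — the basis of adaptive exploration — and
same-space trajectories can be merged.

## Worked example

```python
from trajkit import Environment, cartesian_product
from trajkit.models import multiply   # computes z = x*y, stores z

env = Environment(trajectory="multiply", filename="multiply.h5")
env.traj.add_parameter("x", 1.0, comment="I am the first dimension!")
env.traj.add_parameter("y", 1.0, comment="I am the second dimension!")
env.traj.explore(cartesian_product({"x": [1.0, 2.0, 3.0, 4.0],
                                    "y": [6.0, 7.0, 8.0]}))
print(env.run(multiply))
```

prints

```
[(0, 6.0), (1, 12.0), (2, 18.0), (3, 24.0), (4, 7.0), (5, 14.0),
 (6, 21.0), (7, 28.0), (8, 8.0), (9, 16.0), (10, 24.0), (11, 32.0)]
```

— one `(run index, returned value)` tuple per explored point: the product
was evaluated twelve times, on `(1.0, 6.0), (2.0, 6.0), …, (4.0, 8.0)`,
and every `z` also sits in `multiply.h5` under
`results/runs/run_XXXXXXXX/z`. Loading it back later needs no full read:

```python
from trajkit import load_trajectory, SKELETON
traj = load_trajectory("multiply.h5", level=SKELETON, auto_load=True)
print(traj["results.runs.run_00000011.z"])   # 32.0, loaded on demand
```

The `examples/` directory holds one narrative script per capability
(basic sweep, parallel cellular automata with lazy reloading, adaptive
optimization with `expand`, a LIF network with grouped parameters, and
merging/resuming). A thin command-line front end mirrors the library:

```bash
trajkit run-example ca --filename ca.h5 --multiproc --ncores 4
trajkit inspect ca.h5
trajkit find ca.h5 --where "rule_number gt 30" --where "rule_number lt 120"
```

## Layout

```
src/trajkit/
  typetags.py     value codecs + tag registry (round-trip fidelity)
  containers.py   Parameter (lockable, explorable) and Result leaves
  tree.py         Trajectory, natural naming, exploration, merge
  storage.py      HDF5 storage service, staged/lazy loading
  runner.py       Environment, serial/parallel scheduling, logging
  models.py       example models (multiply, cellular automata, optimizer, LIF)
  experiments.py  ready-made end-to-end experiments
  cli.py          command-line front end
```
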