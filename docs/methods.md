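# Methods

## The trajectory model

trajkit treats a numerical experiment as a *trajectory* through parameter
space: an ordered list of parameter points, each evaluated by one
independent *single run* of a user model. The trajectory container is a
rooted tree with three reserved top-level groups — `parameters`,
`results`, `config` — whose interior nodes are plain groups and whose
leaves are typed containers. Because the hierarchy consists only of
groups and leaves it is acyclic by construction; *links* add aliases onto
existing nodes without breaking that property (link chasing is capped at
8 hops, after which a `LinkDepthError` signals a cycle).

Queries use dotted paths with *shortcut elision*: intermediate groups may
be omitted and a breadth-first search returns the unique match at minimal
depth. Two matches at the same minimal depth raise `AmbiguousNameError`
rather than guessing — in particular when a parameter and a result share
a leaf name, the caller must spell out the branch. Deeper matches
shadowed by a unique shallower match are ignored. Methods live on the
class as ordinary Python attributes and therefore shadow same-named data
in attribute-style access; `traj["..."]` indexing is the canonical,
collision-free query form. Valid node names are `[A-Za-z_][A-Za-z0-9_]*`
excluding the reserved tokens `crun` and the `run_\d{8}` pattern.

## Parameters, results, type tags

A `Parameter` holds one dimension of the space: a default value, an
optional exploration range, and a lock. Reading a parameter through the
tree API *inside a run* locks it, so later mutation fails loudly instead
of silently invalidating completed runs; plain introspection outside a
run context does not lock, keeping debugging non-destructive. Unlocking
is explicit and logged at warning level. Ranges are type-homogeneous:
every element must carry the same type tag as the default (floats are
compared bitwise for deduplication during merges — ranges are
user-specified literals, so tolerance comparisons would be wrong).
Once runs over a range have completed, the range can only be appended to
(`expand`), never rewritten.

Every stored value carries a *type tag* so that HDF5 round trips restore
the exact Python type: `bool/int/float/complex/str`, NumPy scalars (dtype
in the tag), 1-D/2-D arrays (numeric, boolean, unicode), homogeneous
non-nested tuples and lists, and — for results only — string-keyed
mappings and pandas DataFrames. Nested or heterogeneous sequences are
rejected. Custom kinds register a codec under a new tag; loading a file
containing an unregistered tag raises `UnknownTagError` naming it, so the
registry doubles as the list of container constructors a loader must be
given. Sparse matrices and unit-aware quantities are out of scope.

## Exploration and scheduling

`explore` installs equal-length ranges (length L) and seeds the run table
with L pending records; indices count from 0 and run names are
`run_%08d`. `cartesian_product` expands factor sets into matching
ranges with the first-listed parameter cycling fastest. `expand` appends
points to an explored trajectory (or behaves like `explore` on a fresh
one), continuing the index sequence — the primitive behind adaptive
exploration, where run and post-processing phases alternate.

The environment executes pending runs in ascending index order. Serially,
the model runs in-process with the run pointer set. In multiprocess mode
each worker receives a pruned trajectory view — parameter leaves carrying
only that run's value, no results — which both enforces run independence
and minimizes serialization; result leaves travel back to the parent,
which is the only process that ever writes to the file. Payloads are
pickled eagerly so an unserializable model or argument fails fast with
`SerializationError`. Dispatch order is fixed (no work stealing) to keep
scheduling deterministic; outcome lists are sorted by index regardless of
completion order. A failing run is logged to the error log, flagged in
the run table, and does not abort siblings; the first exception is
re-raised wrapped with its run index after the batch finishes. Partial
results added before the exception are kept. The framework never seeds
global random generators — models derive their randomness from explicit
seed parameters, as the bundled examples do.

Progress is reported at most once per configurable interval (default
10 s, or at the end of the batch); the ETA is the arithmetic mean runtime
of completed runs times the number of remaining runs — no decay
weighting, since runs in one sweep are typically homogeneous. Each
environment writes two log files, `<name>_main.log` at the configured
level and `<name>_errors.log` at error severity only.

## Storage

The tree maps one-to-one onto the HDF5 hierarchy: every node is exactly
one group at the corresponding path; links become native soft links
(dangling targets surface as `NotFoundError` at resolution, not at load).
Leaves are groups with one dataset per item, each carrying a `type_tag`
attribute; scalars are 0-d datasets rather than attributes so that all
items are uniformly addressable by the lazy loader. Text is stored as
UTF-8 variable-length strings with the original dtype recorded for text
arrays; DataFrames become per-column datasets plus a column-order
attribute, avoiding dialect-specific table serializers. Scalar-tagged
exploration ranges are packed into a single 1-D dataset; ranges of
arrays fall back to one dataset per element. Datasets of 1 KiB or more
are zlib-compressed at level 4; smaller ones are raw, since chunking
overhead would dominate tiny items. The run table is a compound dataset
at `overview/runs` with columns (index, name, completed, failed,
runtime_seconds, finished_at) and, being bookkeeping, is rewritten on
every store; payload datasets are never rewritten — re-storing an
unchanged node is a no-op, and in-file deletion/replacement is
unsupported (`UnsupportedOperationError`). All writes go through one
process and one handle; concurrent readers of closed files are fine.

Loading is staged: *skeleton* (root metadata, run table, explored
parameter leaves with their ranges), *structure* (adds empty group/leaf
stubs), *full* (adds payload). With `auto_load`, a resolution miss first
materializes the structure, then pulls the requested leaf's payload —
so skeleton-plus-auto-load answers every query a full load answers, just
later. Group comments and annotations are stored as HDF5 group
attributes (annotations JSON-encoded; they are meant for small notes).

## The bundled models and what the generator emulates

*multiply* (z = x·y) exercises the minimal sweep: a 4×3 Cartesian
product, 12 runs, each returning and storing one float.

*Elementary cellular automata*: n cells with binary states updated for k
steps by rule r ∈ [0, 255]; the next state of a cell is bit
(4·s_left + 2·s_center + s_right) of r, with periodic boundaries. The
bundled experiment explores rules {10, 30, 90, 110, 184, 190} at
n = k = 100 with a seeded random initial row — large enough that patterns
are visibly rule-specific yet each pattern is only 10 000 small integers.
An explicit `initial_state` is accepted so deterministic oracles (e.g.
rule 90's XOR recurrence from a single live cell) can be tested.

*Greedy stochastic optimizer*: maximizes
f(x) = −(x+4)⁶ + 5(x−10)⁴ − 2(x−4)² + x by iterating 30 generations of
200 points drawn from N(best, 0.5²), expanding the trajectory each
generation, starting from x = 0. The per-generation best is recorded as
a result and can only improve — the non-decreasing best sequence is the
invariant the alternating expand/run/post-process loop must preserve.

*LIF network*: N leaky integrate-and-fire neurons,
dV_i/dt = (I₀ − V_i)/τ plus instantaneous synaptic kicks of weight
w ≤ 0 from randomly connected (probability p) presynaptic spikes; at
V ≥ V_T the voltage resets to 0 and a spike is recorded. Integration is
forward Euler; spikes detected at step t are delivered at step t+1, and
there are no self-connections. Defaults — N = 100, τ = 10 ms, V_T = 1,
I₀ = 1.1·V_T, p = 0.1, dt = 0.1 ms, 500 ms duration, initial voltages
uniform on [0, V_T) — were chosen to give regular supra-threshold firing
so the decoupled case can be checked against the closed form
ISI = τ·ln(I₀/(I₀−V_T)) to within 2·dt. These are fixture conventions
for a demonstration network, not fitted to any biological dataset; the
examples emulate sweep workloads (many independent runs, array-valued
monitors), not the statistics of real recordings — passing tests show the
toolkit handles such workloads correctly, not that the models are
biologically calibrated.

## Numerical and design choices

- Cartesian enumeration order (first parameter fastest) is fixed so run
  indices are reproducible across sessions.
- `crun` with no run selected raises `NotFoundError` naming the token.
- Predicate filtering (`find_run_indices`) evaluates in-memory ranges
  only and never triggers disk loads.
- Merging requires identical parameter leaf sets, explored names and
  type tags; the incoming runs are re-indexed and their per-run result
  subtrees re-rooted under the new run names. Non-run results of the
  incoming trajectory are not copied (they would collide with the
  target's own aggregates).
- A config branch exists for run-configuration values; a separate
  derived-parameters branch is deliberately omitted.
- Results added with several positional values are auto-named
  `<leaf>_0, <leaf>_1, …`; keyword items keep their names.
- Workers receive parameter leaves only; config leaves stay in the
  parent process.

## Problem sizes used in the test suite

The default suite keeps fixtures small so the whole run stays fast:
automata at 30–100 cells for 20–100 steps, optimizer checks at up to
30 generations × 200 points, LIF runs of 100–500 ms at N ≤ 100, and
storage-scaling smoke checks of 1 000 scalar-storing runs and 100 runs
each storing a 1 000×125 array. These sizes are the package's own
choices for routine verification; all machinery is size-agnostic.

## Known limitations

- One writer at a time; no parallel HDF5, no multi-host distribution.
- No in-file deletion or compaction; a trajectory file only grows.
- Sparse matrices and unit-carrying quantities have no built-in codecs
  (the registry accepts custom ones).
- Post-processing runs strictly after the run phase, not concurrently
  with it.
- Natural-naming attribute access can be shadowed by API method names;
  indexing is the unambiguous form.
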