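"""The trajectory tree: groups, leaves, links and natural naming.

A :class:`Trajectory` is the single container for one numerical experiment.
It is a rooted tree whose reserved top-level groups are ``parameters``,
``results`` and ``config``.  Leaves are the typed containers from
:mod:`trajkit.containers`; links are light-weight aliases onto existing
nodes.  Because only groups and leaves form the hierarchy there can be no
cycles; link chasing is capped defensively.

Content is addressed by dotted paths with *shortcut elision*: intermediate
groups may be left out and a breadth-first search finds the unique match at
minimal depth (``traj.x`` for ``traj.parameters.x``).  Two matches at the
same minimal depth raise :class:`~trajkit.exceptions.AmbiguousNameError`.

The trajectory also owns the experiment bookkeeping: the ordered run table,
the explored parameter names, and the *current run pointer*.  While the
pointer selects run *k*, explored parameters resolve to their *k*-th range
value and the token ``crun`` in a query maps to the run group
``run_%08d`` — the mechanism behind per-run result addressing.
"""

from __future__ import annotations

import itertools
import re
from collections import deque
from dataclasses import dataclass, field
from math import prod
from typing import Any, Callable, Iterator, Mapping, Sequence

from .containers import BaseContainer, Parameter, Result
from .exceptions import (
    AmbiguousNameError,
    EmptyRangeError,
    ExplorationMismatchError,
    LengthMismatchError,
    LinkDepthError,
    NameCollisionError,
    NotFoundError,
    RunPhaseError,
    SpaceMismatchError,
    UnexploredParameterError,
)
from .typetags import BUILTIN_REGISTRY, TypeTagRegistry

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_RUN_NAME_RE = re.compile(r"^run_\d{8}$")
_RESERVED = {"crun"}
#: maximum link hops before giving up (guards self-referential chains)
LINK_DEPTH_CAP = 8


def run_name(index: int) -> str:
    """Canonical zero-padded run name, e.g. ``run_00000002`` for index 2."""
    return f"run_{index:08d}"


def _check_name(name: str) -> str:
    if not _NAME_RE.match(name):
        raise ValueError(f"invalid node name {name!r}")
    if name in _RESERVED or _RUN_NAME_RE.match(name):
        raise ValueError(f"node name {name!r} is reserved")
    return name


class GroupNode:
    """Interior tree node holding named children."""

    kind = "group"

    def __init__(self, full_name: str, comment: str = ""):
        self.full_name = full_name
        self.comment = comment
        self.children: dict[str, Any] = {}
        self.annotations: dict[str, Any] = {}

    @property
    def name(self) -> str:
        return self.full_name.rsplit(".", 1)[-1]

    def __repr__(self):
        return f"<GroupNode {self.full_name!r} ({len(self.children)} children)>"


class LinkNode:
    """Alias node: resolves to the node at ``target`` (a full dotted path)."""

    kind = "link"

    def __init__(self, full_name: str, target: str):
        self.full_name = full_name
        self.target = target

    @property
    def name(self) -> str:
        return self.full_name.rsplit(".", 1)[-1]

    def __repr__(self):
        return f"<LinkNode {self.full_name!r} -> {self.target!r}>"


@dataclass
class RunRecord:
    """Per-run bookkeeping row of the run table."""

    index: int
    completed: bool = False
    failed: bool = False
    runtime_seconds: float = 0.0
    finished_at: float = 0.0

    @property
    def name(self) -> str:
        return run_name(self.index)


class _ResultItem:
    """Marker for a query that ends on an item inside a result leaf."""

    __slots__ = ("result", "item")

    def __init__(self, result: Result, item: str):
        self.result = result
        self.item = item


class NodeView:
    """Chainable natural-naming handle onto a group node."""

    __slots__ = ("_traj", "_node")

    def __init__(self, traj: "Trajectory", node: GroupNode):
        object.__setattr__(self, "_traj", traj)
        object.__setattr__(self, "_node", node)

    @property
    def node(self) -> GroupNode:
        return self._node

    def __getattr__(self, name: str) -> Any:
        return self._traj._resolve(name, start=self._node)

    def __getitem__(self, query: str) -> Any:
        return self._traj._resolve(query, start=self._node)

    def __repr__(self):
        return f"<NodeView onto {self._node.full_name!r}>"


class Trajectory:
    """Tree container for parameters, results and experiment bookkeeping.

    Parameters
    ----------
    name:
        Identifier of the trajectory; doubles as the HDF5 root group name.
    comment:
        Free-text description.
    registry:
        Type-tag registry for container values; defaults to the built-ins.
    """

    def __init__(self, name: str = "trajectory", comment: str = "",
                 registry: TypeTagRegistry | None = None):
        _check_name(name)
        self.name = name
        self.comment = comment
        self.registry = registry if registry is not None else BUILTIN_REGISTRY
        self.root = GroupNode("")
        for top in ("parameters", "results", "config"):
            self.root.children[top] = GroupNode(top)
        self.run_table: list[RunRecord] = []
        self.explored_names: list[str] = []
        self._current_run_index = -1
        self._in_run = False
        self.auto_load = False
        #: bound storage service set by a load; used for lazy node loading
        self.storage = None
        self._structure_loaded = True

    # ------------------------------------------------------------------
    # run pointer
    # ------------------------------------------------------------------

    @property
    def current_run_index(self) -> int:
        """The run pointer: −1 selects no run (defaults everywhere)."""
        return self._current_run_index

    @current_run_index.setter
    def current_run_index(self, idx: int) -> None:
        n = len(self.run_table)
        if not (idx == -1 or 0 <= idx < n):
            raise IndexError(f"run index {idx} outside -1..{n - 1}")
        self._current_run_index = idx

    @property
    def n_runs(self) -> int:
        return len(self.run_table)

    @property
    def explored(self) -> bool:
        return bool(self.explored_names)

    def _runs_started(self) -> bool:
        return any(r.completed or r.failed for r in self.run_table)

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------

    def _make_groups(self, parent: GroupNode, parts: Sequence[str]) -> GroupNode:
        node = parent
        for part in parts:
            _check_name(part) if not _RUN_NAME_RE.match(part) else None
            child = node.children.get(part)
            if child is None:
                prefix = f"{node.full_name}." if node.full_name else ""
                child = GroupNode(prefix + part)
                node.children[part] = child
            elif child.kind != "group":
                raise NameCollisionError(
                    f"{child.full_name!r} exists and is not a group"
                )
            node = child
        return node

    def _add_leaf(self, branch: str, path: str, leaf_factory) -> Any:
        parts = path.split(".")
        if parts[0] == branch:
            parts = parts[1:]
        if not parts:
            raise ValueError(f"empty path under {branch!r}")
        for part in parts:
            # per-run result groups are the one place run names are valid
            if branch == "results" and _RUN_NAME_RE.match(part):
                continue
            _check_name(part)
        parent = self._make_groups(self.root.children[branch], parts[:-1])
        name = parts[-1]
        if name in parent.children:
            raise NameCollisionError(
                f"node {parent.full_name + '.' + name!r} already exists"
            )
        leaf = leaf_factory(f"{parent.full_name}.{name}")
        parent.children[name] = leaf
        return leaf

    def add_parameter(self, path: str, default: Any = None,
                      comment: str = "") -> Parameter:
        """Add a parameter leaf under ``parameters``; groups auto-created.

        Parameters can only be introduced before any single run executes.
        """
        if self._runs_started() or self._in_run:
            raise RunPhaseError(
                "parameters can only be added before runs are started"
            )
        return self._add_leaf(
            "parameters", path,
            lambda fn: Parameter(fn, default, comment, registry=self.registry),
        )

    def add_config(self, path: str, value: Any = None,
                   comment: str = "") -> Parameter:
        """Add a config leaf (never explored; same container as parameters)."""
        return self._add_leaf(
            "config", path,
            lambda fn: Parameter(fn, value, comment, registry=self.registry),
        )

    def add_result(self, path: str, *values: Any, comment: str = "",
                   **items: Any) -> Result:
        """Add a result leaf.

        Inside a single run the leaf lands under
        ``results.runs.run_%08d.<path>``; outside any run it lands under
        ``results.<path>``.  A single positional value is stored under the
        leaf's own name; several positional values get ``_0``, ``_1``…
        suffixes; keyword items keep their names.
        """
        parts = path.split(".")
        if parts[0] == "results":
            parts = parts[1:]
        if self._in_run and self._current_run_index >= 0:
            parts = ["runs", run_name(self._current_run_index)] + parts

        def factory(full_name):
            leaf = Result(full_name, comment, registry=self.registry)
            name = full_name.rsplit(".", 1)[-1]
            if len(values) == 1:
                leaf.set(name, values[0])
            else:
                for k, v in enumerate(values):
                    leaf.set(f"{name}_{k}", v)
            for k, v in items.items():
                leaf.set(k, v)
            return leaf

        return self._add_leaf("results", ".".join(parts), factory)

    def add_link(self, name: str, target_path: str,
                 group: str | GroupNode = "") -> LinkNode:
        """Create an alias ``name`` (under ``group``, default root) onto an
        existing node addressed by the full dotted path ``target_path``."""
        _check_name(name)
        target = self.get_node(target_path)  # NotFoundError if absent
        parent = group if isinstance(group, GroupNode) else (
            self.root if not group else self.get_node(group)
        )
        if not isinstance(parent, GroupNode):
            raise NotFoundError(f"link parent {group!r} is not a group")
        if name in parent.children:
            raise NameCollisionError(f"node {name!r} already exists in parent")
        prefix = f"{parent.full_name}." if parent.full_name else ""
        link = LinkNode(prefix + name, target.full_name)
        parent.children[name] = link
        return link

    # ------------------------------------------------------------------
    # resolution / natural naming
    # ------------------------------------------------------------------

    def _chase(self, node: Any) -> Any:
        hops = 0
        while isinstance(node, LinkNode):
            hops += 1
            if hops > LINK_DEPTH_CAP:
                raise LinkDepthError(
                    f"link chain exceeded {LINK_DEPTH_CAP} hops at "
                    f"{node.full_name!r}"
                )
            node = self._node_at(node.target)
        return node

    def _node_at(self, full_path: str) -> Any:
        """Exact-path lookup (no elision); links chased along the way."""
        node = self.root
        for part in full_path.split("."):
            node = self._chase(node)
            if not isinstance(node, GroupNode) or part not in node.children:
                raise NotFoundError(f"no node at path {full_path!r}")
            node = node.children[part]
        return node

    def _bfs_token(self, start: GroupNode, token: str) -> Any:
        """Find the unique node named ``token`` at minimal depth below start."""
        level = [start]
        seen: set[int] = {id(start)}
        while level:
            matches = [n.children[token] for n in level if token in n.children]
            if len(matches) > 1:
                raise AmbiguousNameError(
                    f"name {token!r} matches {len(matches)} nodes at the same "
                    f"minimal depth below {start.full_name or '<root>'!r}: "
                    f"{sorted(m.full_name for m in matches)}"
                )
            if matches:
                return matches[0]
            nxt = []
            for n in level:
                for child in n.children.values():
                    child = self._chase(child) if isinstance(child, LinkNode) else child
                    if isinstance(child, GroupNode) and id(child) not in seen:
                        seen.add(id(child))
                        nxt.append(child)
            level = nxt
        raise NotFoundError(
            f"no node matching {token!r} below {start.full_name or '<root>'!r}"
        )

    def _map_token(self, token: str) -> str:
        if token == "crun":
            if self._current_run_index < 0:
                raise NotFoundError(
                    "token 'crun' used but no current run is selected "
                    "(run pointer is -1)"
                )
            return run_name(self._current_run_index)
        return token

    def _search(self, start: GroupNode, tokens: Sequence[str]) -> Any:
        node: Any = start
        for pos, token in enumerate(tokens):
            if isinstance(node, Result):
                # the trailing token may address an item inside the leaf
                if pos == len(tokens) - 1:
                    if not node.data_loaded and self.storage is not None:
                        self.storage.load_leaf_data(self, node)
                    if token in node:
                        return _ResultItem(node, token)
                raise NotFoundError(
                    f"result {node.full_name!r} has no item matching "
                    f"{'.'.join(tokens[pos:])!r}"
                )
            if not isinstance(node, GroupNode):
                raise NotFoundError(
                    f"cannot descend into leaf {node.full_name!r} with "
                    f"remaining query {token!r}"
                )
            node = self._chase(self._bfs_token(node, token))
        return node

    def get_node(self, query: str, start: GroupNode | None = None) -> Any:
        """Resolve a dotted query (shortcuts allowed) to the tree node."""
        start = start if start is not None else self.root
        # map tokens up front so a dangling 'crun' is reported by name
        tokens = [self._map_token(t) for t in query.split(".") if t]
        if not tokens:
            return start
        try:
            return self._search(start, tokens)
        except NotFoundError as exc:
            if self.auto_load and self.storage is not None:
                self.storage.ensure_structure(self)
                return self._search(start, tokens)
            if self.storage is not None and not self._structure_loaded:
                raise NotFoundError(
                    f"{exc} — the trajectory was loaded partially; enable "
                    f"auto_load or load the node explicitly"
                ) from exc
            raise

    def _leaf_value(self, leaf: BaseContainer) -> Any:
        if isinstance(leaf, Parameter):
            if self._in_run:
                leaf.lock()
            if leaf.explored and self._current_run_index >= 0:
                return leaf.value_at(self._current_run_index)
            return leaf.default
        if isinstance(leaf, Result):
            if not leaf.data_loaded and self.storage is not None:
                self.storage.load_leaf_data(self, leaf)
            if len(leaf) == 1:
                return leaf.get(next(iter(leaf)))
            return leaf
        return leaf

    def _resolve(self, query: str, start: GroupNode | None = None) -> Any:
        node = self.get_node(query, start=start)
        if isinstance(node, _ResultItem):
            return node.result.get(node.item)
        if isinstance(node, GroupNode):
            return NodeView(self, node)
        if isinstance(node, Parameter) and not node.data_loaded \
                and self.storage is not None:
            self.storage.load_leaf_data(self, node)
        return self._leaf_value(node)

    def resolve(self, query: str) -> Any:
        """Resolve a dotted query to a value (leaves) or view (groups).

        Explored parameters return the range value of the selected run when
        the run pointer is set; single-item results return the bare item.
        """
        return self._resolve(query)

    def __getitem__(self, query: str) -> Any:
        return self._resolve(query)

    def __getattr__(self, name: str) -> Any:
        if name.startswith("_") or name in ("root",):
            raise AttributeError(name)
        try:
            return self._resolve(name)
        except (NotFoundError, AmbiguousNameError) as exc:
            raise AttributeError(str(exc)) from exc

    # ------------------------------------------------------------------
    # exploration
    # ------------------------------------------------------------------

    def _explored_params(self) -> list[Parameter]:
        return [self._node_at(n) for n in self.explored_names]

    def explore(self, spec: Mapping[str, Sequence[Any]]) -> "Trajectory":
        """Install the exploration: one ordered value sequence per parameter.

        All sequences must share one length *L*; the run table is seeded
        with *L* pending records, indices counted from 0.
        """
        if self.explored:
            raise ExplorationMismatchError(
                "trajectory already explored; use expand() to add points"
            )
        lengths = {len(v) for v in spec.values()}
        if not spec or any(l == 0 for l in lengths):
            raise EmptyRangeError("exploration sequences must be nonempty")
        if len(lengths) != 1:
            raise LengthMismatchError(
                f"exploration sequences have mixed lengths {sorted(lengths)}; "
                f"all must match"
            )
        params = []
        for path in spec:
            node = self.get_node(path)
            if not isinstance(node, Parameter):
                raise NotFoundError(f"{path!r} does not name a parameter")
            params.append(node)
        for p, values in zip(params, spec.values()):
            p.set_range(values)
        self.explored_names = [p.full_name for p in params]
        (length,) = lengths
        self.run_table = [RunRecord(i) for i in range(length)]
        return self

    def expand(self, spec: Mapping[str, Sequence[Any]]) -> "Trajectory":
        """Append explored points to a trajectory (or explore it afresh).

        On an already-explored trajectory the spec must name exactly the
        explored parameters; new pending runs continue the index sequence.
        """
        if not self.explored:
            return self.explore(spec)
        named = {self.get_node(p).full_name for p in spec}
        if named != set(self.explored_names):
            raise ExplorationMismatchError(
                f"expand must name exactly the explored parameters "
                f"{sorted(self.explored_names)}, got {sorted(named)}"
            )
        lengths = {len(v) for v in spec.values()}
        if len(lengths) != 1:
            raise LengthMismatchError(
                f"expansion sequences have mixed lengths {sorted(lengths)}"
            )
        for path, values in spec.items():
            self.get_node(path).append_range(values)
        (extra,) = lengths
        start = len(self.run_table)
        self.run_table.extend(RunRecord(i) for i in range(start, start + extra))
        self._check_table_consistency()
        return self

    def _check_table_consistency(self) -> None:
        for p in self._explored_params():
            assert len(p.range) == len(self.run_table), (
                f"range of {p.full_name} out of sync with run table"
            )

    def iter_runs(self) -> Iterator[str]:
        """Iterate run names in index order, moving the run pointer along.

        Explored parameters consequently resolve to each run's value inside
        the loop; afterwards the pointer is restored to −1.
        """
        try:
            for rec in self.run_table:
                self._current_run_index = rec.index
                yield rec.name
        finally:
            self._current_run_index = -1

    def find_run_indices(self, param_paths: Sequence[str],
                         predicate: Callable[..., bool]) -> list[int]:
        """Indices of runs whose explored values satisfy the predicate.

        Operates on in-memory ranges only; never touches stored results.
        """
        params = []
        for path in param_paths:
            node = self.get_node(path)
            if not isinstance(node, Parameter):
                raise NotFoundError(f"{path!r} does not name a parameter")
            if not node.explored:
                raise UnexploredParameterError(
                    f"parameter {node.full_name!r} has no exploration range"
                )
            params.append(node)
        return [
            i for i in range(len(self.run_table))
            if predicate(*(p.value_at(i) for p in params))
        ]

    # ------------------------------------------------------------------
    # merging
    # ------------------------------------------------------------------

    def _parameter_leaves(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def walk(node):
            for child in node.children.values():
                if isinstance(child, GroupNode):
                    walk(child)
                elif isinstance(child, Parameter):
                    out[child.full_name] = child

        walk(self.root.children["parameters"])
        return out

    @staticmethod
    def _point_key(values: tuple) -> tuple:
        import numpy as np

        return tuple(
            (v.tobytes(), v.shape) if isinstance(v, np.ndarray) else v
            for v in values
        )

    def merge(self, other: "Trajectory",
              remove_duplicates: bool = False) -> "Trajectory":
        """Append another trajectory's runs (same parameter space) to this one.

        The other trajectory's per-run result subtrees are re-rooted under
        the fresh run names.  With ``remove_duplicates``, runs whose
        explored point exactly equals an existing point here are skipped
        (floats compared bitwise: ranges are user-specified literals).
        """
        mine, theirs = self._parameter_leaves(), other._parameter_leaves()
        if set(mine) != set(theirs) or set(self.explored_names) != set(
                other.explored_names):
            raise SpaceMismatchError(
                "trajectories do not reside in the same parameter space"
            )
        for fn, p in mine.items():
            if p.type_tag != theirs[fn].type_tag:
                raise SpaceMismatchError(
                    f"type tag mismatch for {fn!r}: "
                    f"{p.type_tag!r} vs {theirs[fn].type_tag!r}"
                )
        my_params = [mine[n] for n in self.explored_names]
        their_params = [theirs[n] for n in self.explored_names]
        existing = {
            self._point_key(tuple(p.value_at(i) for p in my_params))
            for i in range(len(self.run_table))
        }
        for j in range(len(other.run_table)):
            point = tuple(p.value_at(j) for p in their_params)
            if remove_duplicates and self._point_key(point) in existing:
                continue
            existing.add(self._point_key(point))
            new_index = len(self.run_table)
            for p, v in zip(my_params, point):
                p.append_range([v])
            rec = other.run_table[j]
            self.run_table.append(RunRecord(
                new_index, completed=rec.completed, failed=rec.failed,
                runtime_seconds=rec.runtime_seconds, finished_at=rec.finished_at,
            ))
            self._copy_run_results(other, j, new_index)
        self._check_table_consistency()
        return self

    def _copy_run_results(self, other: "Trajectory", src_index: int,
                          dst_index: int) -> None:
        try:
            src = other._node_at(f"results.runs.{run_name(src_index)}")
        except NotFoundError:
            return

        def copy_into(node, dst_parent: GroupNode):
            for name, child in node.children.items():
                prefix = f"{dst_parent.full_name}."
                if isinstance(child, GroupNode):
                    sub = GroupNode(prefix + name, child.comment)
                    sub.annotations = dict(child.annotations)
                    dst_parent.children[name] = sub
                    copy_into(child, sub)
                elif isinstance(child, Result):
                    res = Result(prefix + name, child.comment,
                                 registry=self.registry)
                    for item in child:
                        res.set(item, child.get(item))
                    res.annotations = dict(child.annotations)
                    dst_parent.children[name] = res

        runs_group = self._make_groups(self.root.children["results"],
                                       ["runs", run_name(dst_index)])
        copy_into(src, runs_group)

    # ------------------------------------------------------------------
    # iteration helpers
    # ------------------------------------------------------------------

    def iter_nodes(self) -> Iterator[tuple[str, Any]]:
        """Yield ``(full_path, node)`` for every node below the root, top-down."""

        def walk(node):
            for child in node.children.values():
                yield child.full_name, child
                if isinstance(child, GroupNode):
                    yield from walk(child)

        yield from walk(self.root)

    def __repr__(self):
        return (f"<Trajectory {self.name!r}: {self.n_runs} runs, "
                f"{len(self.explored_names)} explored parameters>")


def cartesian_product(spec: Mapping[str, Sequence[Any]],
                      order: Sequence[str] | None = None,
                      ) -> dict[str, list[Any]]:
    """Expand factor sequences into equal-length Cartesian-product lists.

    The first parameter in ``order`` (default: spec insertion order) cycles
    fastest, so ``{x: [1,2,3,4], y: [6,7,8]}`` enumerates
    ``(1,6), (2,6), (3,6), (4,6), (1,7), …, (4,8)``.
    """
    order = list(spec) if order is None else list(order)
    if any(len(spec[k]) == 0 for k in order):
        raise EmptyRangeError("Cartesian factors must be nonempty")
    # itertools.product cycles the *last* factor fastest; reverse to make
    # the first-listed parameter the fast axis, then undo per point
    points = [tuple(reversed(pt))
              for pt in itertools.product(*(spec[k] for k in reversed(order)))]
    assert len(points) == prod(len(spec[k]) for k in order)
    return {k: [pt[i] for pt in points] for i, k in enumerate(order)}
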