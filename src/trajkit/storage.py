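"""HDF5 persistence for trajectories.

The whole experiment — parameters, results, config, annotations, links and
the run table — lives in a single HDF5 file.  The tree hierarchy maps
one-to-one onto the HDF5 group hierarchy: every tree node is exactly one
HDF5 group at the corresponding path (links become native soft links), so
files remain inspectable with any generic HDF5 browser.

Leaves are groups with one dataset per item; every item dataset carries a
``type_tag`` attribute so values round-trip with their exact Python type.
Scalars are 0-d datasets rather than attributes, keeping all items
uniformly addressable for lazy loading.  Datasets of 1 KiB or more are
zlib-compressed (level 4); smaller ones are stored raw to avoid chunking
overhead on tiny items.

Loading is staged.  A *skeleton* load recovers only root metadata, the run
table and the explored parameter ranges; a *structure* load adds empty
group and leaf stubs; a *full* load adds all payload data.  With
``auto_load`` enabled on the trajectory, a natural-naming request that
misses the in-memory tree transparently pulls the structure and then the
requested leaf's data from disk — no explicit load call needed.

Writes are strictly single-writer: one service, one process.  Deleting or
replacing stored payload data is unsupported; re-storing an unchanged node
is a no-op apart from refreshed bookkeeping attributes.
"""

from __future__ import annotations

import json
import os
from typing import Any

import h5py
import numpy as np

from .containers import Parameter, Result
from .exceptions import (
    NotFoundError,
    UnsupportedOperationError,
)
from .tree import GroupNode, LinkNode, RunRecord, Trajectory
from .typetags import BUILTIN_REGISTRY, TypeTagRegistry

#: staged load levels
SKELETON, STRUCTURE, FULL = 0, 1, 2

FORMAT_VERSION = "1"

_RUN_TABLE_DTYPE = np.dtype([
    ("index", "i8"),
    ("name", "S16"),
    ("completed", "?"),
    ("failed", "?"),
    ("runtime_seconds", "f8"),
    ("finished_at", "f8"),
])

_SCALARLIKE_BASES = {"bool", "int", "float", "complex", "str", "npscalar"}


def _h5path(traj_name: str, full_name: str = "") -> str:
    path = "/" + traj_name
    if full_name:
        path += "/" + full_name.replace(".", "/")
    return path


class HDF5StorageService:
    """Stores and recalls trajectory (sub)trees in one HDF5 file.

    Parameters
    ----------
    filename:
        Path of the HDF5 file (created on first store).
    registry:
        Type-tag registry used for encoding and decoding; must know every
        custom tag present in the file.
    """

    def __init__(self, filename: str | os.PathLike,
                 registry: TypeTagRegistry | None = None):
        self.filename = str(filename)
        self.registry = registry if registry is not None else BUILTIN_REGISTRY
        #: number of on-demand load operations (useful to verify laziness)
        self.load_calls = 0
        #: number of write operations
        self.write_calls = 0

    # ------------------------------------------------------------------
    # storing
    # ------------------------------------------------------------------

    def store_tree(self, traj: Trajectory) -> str:
        """Persist the complete trajectory; returns the filename."""
        self.write_calls += 1
        with h5py.File(self.filename, "a") as f:
            root = f.require_group(traj.name)
            root.attrs["format_version"] = FORMAT_VERSION
            root.attrs["node_kind"] = "trajectory"
            root.attrs["comment"] = traj.comment
            root.attrs["explored_names"] = json.dumps(traj.explored_names)
            for top in ("parameters", "results", "config"):
                self._store_group_attrs(
                    root.require_group(top), traj.root.children[top]
                )
            for full_name, node in traj.iter_nodes():
                self._store_node_into(f, traj, full_name, node)
            self._write_run_table(root, traj)
        return self.filename

    def store_node(self, traj: Trajectory, path: str) -> None:
        """Persist only the subtree rooted at ``path`` (plus its ancestors'
        group shells); other parts of the file are left untouched."""
        node = traj.get_node(path)
        self.write_calls += 1
        with h5py.File(self.filename, "a") as f:
            root = f.require_group(traj.name)
            root.attrs.setdefault("format_version", FORMAT_VERSION)
            # ancestor group shells
            parts = node.full_name.split(".")
            for depth in range(1, len(parts)):
                ancestor = traj._node_at(".".join(parts[:depth]))
                if isinstance(ancestor, GroupNode):
                    self._store_group_attrs(
                        root.require_group("/".join(parts[:depth])), ancestor
                    )
            self._store_node_into(f, traj, node.full_name, node)
            if isinstance(node, GroupNode):
                for full_name, sub in self._iter_subtree(node):
                    self._store_node_into(f, traj, full_name, sub)

    def store_run_table(self, traj: Trajectory) -> None:
        self.write_calls += 1
        with h5py.File(self.filename, "a") as f:
            root = f.require_group(traj.name)
            root.attrs["explored_names"] = json.dumps(traj.explored_names)
            self._write_run_table(root, traj)
            # expanded ranges accompany new run records
            for full_name in traj.explored_names:
                self._store_node_into(f, traj, full_name,
                                      traj._node_at(full_name))

    def delete_node(self, traj: Trajectory, path: str) -> None:
        raise UnsupportedOperationError(
            "deleting or replacing stored data is not supported"
        )

    @staticmethod
    def _iter_subtree(group: GroupNode):
        for child in group.children.values():
            yield child.full_name, child
            if isinstance(child, GroupNode):
                yield from HDF5StorageService._iter_subtree(child)

    def _store_group_attrs(self, h5group, node) -> None:
        h5group.attrs["node_kind"] = "group"
        h5group.attrs["comment"] = getattr(node, "comment", "")
        ann = getattr(node, "annotations", None)
        if ann:
            h5group.attrs["annotations"] = json.dumps(ann)

    def _store_node_into(self, f: h5py.File, traj: Trajectory,
                         full_name: str, node: Any) -> None:
        parent_path = _h5path(traj.name, full_name).rsplit("/", 1)[0]
        name = full_name.rsplit(".", 1)[-1]
        parent = f.require_group(parent_path)
        if isinstance(node, LinkNode):
            if name not in parent:
                parent[name] = h5py.SoftLink(_h5path(traj.name, node.target))
            return
        if isinstance(node, GroupNode):
            self._store_group_attrs(parent.require_group(name), node)
            return
        h5g = parent.require_group(name)
        h5g.attrs["node_kind"] = "leaf"
        h5g.attrs["container_type"] = node.container_type
        h5g.attrs["comment"] = node.comment
        if node.annotations:
            h5g.attrs["annotations"] = json.dumps(node.annotations)
        if isinstance(node, Parameter):
            self._store_parameter(h5g, node)
        elif isinstance(node, Result):
            self._store_result(h5g, node)
        else:  # custom leaf container kinds go through the registry whole
            if "value" not in h5g:
                self.registry.encode(h5g, "value", node)

    def _store_parameter(self, h5g, p: Parameter) -> None:
        h5g.attrs["locked"] = p.locked
        if p.default is not None and "default" not in h5g:
            self.registry.encode(h5g, "default", p.default)
        if p.explored:
            self._store_range(h5g, p)

    def _store_range(self, h5g, p: Parameter) -> None:
        base = (p.type_tag or "").split(":", 1)[0]
        if base in _SCALARLIKE_BASES:
            existing = h5g.get("range")
            if existing is not None and existing.shape[0] == len(p.range):
                return  # unchanged
            if existing is not None:
                del h5g["range"]  # ranges only grow (expand); rewrite
            if base == "str":
                h5g.create_dataset("range", data=list(p.range),
                                   dtype=h5py.string_dtype("utf-8"))
            else:
                h5g.create_dataset("range", data=np.asarray(p.range))
            h5g["range"].attrs["type_tag"] = f"range:{p.type_tag}"
        else:
            sub = h5g.require_group("range")
            sub.attrs["type_tag"] = f"rangegroup:{p.type_tag}"
            sub.attrs["length"] = len(p.range)
            for i, v in enumerate(p.range):
                key = f"e{i:08d}"
                if key not in sub:
                    self.registry.encode(sub, key, v)

    def _store_result(self, h5g, r: Result) -> None:
        for item in r:
            if item not in h5g:
                self.registry.encode(h5g, item, r.get(item))

    def _write_run_table(self, root, traj: Trajectory) -> None:
        table = np.zeros(len(traj.run_table), dtype=_RUN_TABLE_DTYPE)
        for i, rec in enumerate(traj.run_table):
            table[i] = (rec.index, rec.name.encode(), rec.completed,
                        rec.failed, rec.runtime_seconds, rec.finished_at)
        overview = root.require_group("overview")
        if "runs" in overview:
            del overview["runs"]  # bookkeeping table; always refreshed
        overview.create_dataset("runs", data=table)

    # ------------------------------------------------------------------
    # loading
    # ------------------------------------------------------------------

    def load_trajectory(self, name: str | None = None, level: int = FULL,
                        auto_load: bool = False) -> Trajectory:
        """Recover a trajectory from the file at the requested load level."""
        self.load_calls += 1
        with h5py.File(self.filename, "r") as f:
            name = self._resolve_name(f, name)
            root = f[name]
            traj = Trajectory(name, comment=str(root.attrs.get("comment", "")),
                              registry=self.registry)
            traj.storage = self
            traj.auto_load = auto_load
            traj.explored_names = json.loads(
                root.attrs.get("explored_names", "[]"))
            self._read_run_table(root, traj)
            for full_name in traj.explored_names:
                self._materialize_leaf(f, traj, full_name, load_data=True)
            traj._structure_loaded = False
            if level >= STRUCTURE:
                self._load_structure(f, traj)
            if level >= FULL:
                for full_name, node in traj.iter_nodes():
                    if getattr(node, "kind", None) == "leaf" \
                            and not node.data_loaded:
                        self._read_leaf_data(
                            f[_h5path(name, full_name)], node)
        return traj

    @staticmethod
    def _resolve_name(f: h5py.File, name: str | None) -> str:
        if name is not None:
            if name not in f:
                raise NotFoundError(
                    f"no trajectory named {name!r} in {f.filename!r}"
                )
            return name
        roots = [k for k in f
                 if f[k].attrs.get("node_kind") == "trajectory"]
        if len(roots) != 1:
            raise NotFoundError(
                f"file {f.filename!r} holds {len(roots)} trajectories; "
                f"specify a name"
            )
        return roots[0]

    def _read_run_table(self, root, traj: Trajectory) -> None:
        if "overview" not in root or "runs" not in root["overview"]:
            return
        table = root["overview/runs"][()]
        traj.run_table = [
            RunRecord(int(row["index"]), completed=bool(row["completed"]),
                      failed=bool(row["failed"]),
                      runtime_seconds=float(row["runtime_seconds"]),
                      finished_at=float(row["finished_at"]))
            for row in table
        ]

    def ensure_structure(self, traj: Trajectory) -> None:
        """Idempotently populate the stub hierarchy (lazy-load entry point)."""
        if getattr(traj, "_structure_loaded", False):
            return
        self.load_calls += 1
        with h5py.File(self.filename, "r") as f:
            self._load_structure(f, traj)

    def _load_structure(self, f: h5py.File, traj: Trajectory) -> None:
        root = f[traj.name]

        def walk(h5group, tree_parent: GroupNode):
            for key in h5group:
                link = h5group.get(key, getlink=True)
                prefix = f"{tree_parent.full_name}." if tree_parent.full_name \
                    else ""
                full_name = prefix + key
                if isinstance(link, h5py.SoftLink):
                    if key not in tree_parent.children:
                        target = link.path[len(_h5path(traj.name)) + 1:]
                        tree_parent.children[key] = LinkNode(
                            full_name, target.replace("/", "."))
                    continue
                child = h5group[key]
                kind = child.attrs.get("node_kind", "group")
                if kind == "group":
                    sub = tree_parent.children.get(key)
                    if sub is None:
                        sub = GroupNode(
                            full_name, str(child.attrs.get("comment", "")))
                        if "annotations" in child.attrs:
                            sub.annotations = json.loads(
                                child.attrs["annotations"])
                        tree_parent.children[key] = sub
                    walk(child, sub)
                elif kind == "leaf" and key not in tree_parent.children:
                    tree_parent.children[key] = self._make_stub(
                        child, full_name)

        for key in root:
            if key == "overview":
                continue
            if key in ("parameters", "results", "config"):
                walk(root[key], traj.root.children[key])
                continue
            link = root.get(key, getlink=True)
            if isinstance(link, h5py.SoftLink) \
                    and key not in traj.root.children:
                target = link.path[len(_h5path(traj.name)) + 1:]
                traj.root.children[key] = LinkNode(
                    key, target.replace("/", "."))
        traj._structure_loaded = True

    def _make_stub(self, h5g, full_name: str):
        ctype = h5g.attrs.get("container_type", "result")
        comment = str(h5g.attrs.get("comment", ""))
        if ctype == "parameter":
            stub = Parameter(full_name, comment=comment,
                             registry=self.registry)
        else:
            stub = Result(full_name, comment=comment, registry=self.registry)
        if "annotations" in h5g.attrs:
            stub.annotations = json.loads(h5g.attrs["annotations"])
        stub.data_loaded = False
        return stub

    def load_leaf_data(self, traj: Trajectory, leaf) -> None:
        """Materialize one leaf's payload from disk (on-demand load)."""
        self.load_calls += 1
        with h5py.File(self.filename, "r") as f:
            path = _h5path(traj.name, leaf.full_name)
            if path not in f:
                raise NotFoundError(
                    f"leaf {leaf.full_name!r} not present in "
                    f"{self.filename!r}"
                )
            self._read_leaf_data(f[path], leaf)

    def _materialize_leaf(self, f: h5py.File, traj: Trajectory,
                          full_name: str, load_data: bool) -> None:
        parts = full_name.split(".")
        h5g = f[_h5path(traj.name, full_name)]
        parent = traj._make_groups(
            traj.root.children[parts[0]], parts[1:-1])
        if parts[-1] not in parent.children:
            parent.children[parts[-1]] = self._make_stub(h5g, full_name)
        leaf = parent.children[parts[-1]]
        if load_data and not leaf.data_loaded:
            self._read_leaf_data(h5g, leaf)

    def _read_leaf_data(self, h5g, leaf) -> None:
        if isinstance(leaf, Parameter):
            was_locked = bool(h5g.attrs.get("locked", False))
            leaf.locked = False
            if "default" in h5g:
                leaf.set(self.registry.decode(h5g, "default"))
            if "range" in h5g:
                leaf.set_range(self._read_range(h5g))
            leaf.locked = was_locked
        elif isinstance(leaf, Result):
            for key in h5g:
                leaf.set(key, self.registry.decode(h5g, key))
        leaf.data_loaded = True

    def _read_range(self, h5g) -> list:
        obj = h5g["range"]
        tag = obj.attrs["type_tag"]
        if isinstance(tag, bytes):
            tag = tag.decode()
        kind, elem_tag = tag.split(":", 1)
        if kind == "range":
            base = elem_tag.split(":", 1)[0]
            if base == "str":
                return [v for v in obj.asstr()[()]]
            if base == "npscalar":
                dtype = elem_tag.split(":", 1)[1]
                return [np.dtype(dtype).type(v) for v in obj[()]]
            py = {"bool": bool, "int": int, "float": float,
                  "complex": complex}[base]
            return [py(v) for v in obj[()]]
        length = int(obj.attrs["length"])
        return [self.registry.decode(obj, f"e{i:08d}") for i in range(length)]


def store_trajectory(traj: Trajectory, filename: str | os.PathLike,
                     registry: TypeTagRegistry | None = None,
                     ) -> HDF5StorageService:
    """Persist ``traj`` into ``filename``; returns the bound service."""
    service = HDF5StorageService(filename, registry or traj.registry)
    service.store_tree(traj)
    traj.storage = service
    return service


def load_trajectory(filename: str | os.PathLike, name: str | None = None,
                    level: int = FULL, auto_load: bool = False,
                    registry: TypeTagRegistry | None = None) -> Trajectory:
    """Recover a trajectory from an HDF5 file.

    Parameters
    ----------
    level:
        ``SKELETON`` (0) loads root metadata, run table and explored
        ranges; ``STRUCTURE`` (1) adds empty stubs; ``FULL`` (2, default)
        loads everything.
    auto_load:
        Resolve cache misses by loading nodes from disk on demand.
    registry:
        Must know every custom type tag stored in the file.
    """
    if not os.path.exists(filename):
        raise IOError(f"no such file: {filename!r}")
    service = HDF5StorageService(filename, registry)
    return service.load_trajectory(name=name, level=level, auto_load=auto_load)
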