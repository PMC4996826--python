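"""HDF5 persistence: round trips, staged loading, laziness, idempotence."""

import h5py
import numpy as np
import pytest

from trajkit import (
    FULL,
    SKELETON,
    STRUCTURE,
    HDF5StorageService,
    Trajectory,
    TypeTagRegistry,
    load_trajectory,
    register_container_kind,
    store_trajectory,
)
from trajkit.containers import Parameter, Result
from trajkit.exceptions import (
    NotFoundError,
    UnknownTagError,
    UnsupportedOperationError,
)
from trajkit.tree import GroupNode


def _rich_trajectory():
    """A trajectory exercising every built-in container feature."""
    t = Trajectory("rich", comment="round-trip fixture")
    t.add_parameter("x", 1.0, comment="a float")
    t.add_parameter("n", 7)
    t.add_parameter("flag", True)
    t.add_parameter("label", "hello")
    t.add_parameter("cx", 1 + 2j)
    t.add_parameter("syn.w", -0.5, comment="grouped parameter")
    t.add_parameter("weights", np.linspace(0, 1, 5))
    t.add_parameter("shape", (3, 4))
    t.add_config("ncores", 2)
    t.explore({"x": [1.0, 2.0, 3.0], "n": [10, 20, 30]})
    t.get_node("parameters.label").annotations["origin"] = "fixture"
    t.add_result("summary", 42.0, comment="plain scalar")
    t.add_result("monitors.spikes", t=np.array([0.1, 0.2]),
                 i=np.array([3, 4]))
    t.add_result("table", {"a": 1, "b": 2.0})
    t.add_link("best", "results.summary")
    t.run_table[0].completed = True
    t.run_table[0].runtime_seconds = 0.25
    return t


def _assert_trees_equal(a: Trajectory, b: Trajectory):
    nodes_a = {fn: n for fn, n in a.iter_nodes()}
    nodes_b = {fn: n for fn, n in b.iter_nodes()}
    assert set(nodes_a) == set(nodes_b)
    for fn, na in nodes_a.items():
        nb = nodes_b[fn]
        assert type(na).__name__ == type(nb).__name__, fn
        if isinstance(na, Parameter):
            assert na.type_tag == nb.type_tag
            assert na.comment == nb.comment
            assert na.locked == nb.locked
            assert na.annotations == nb.annotations
            np.testing.assert_array_equal(na.default, nb.default)
            assert (na.range is None) == (nb.range is None)
            if na.range is not None:
                assert na.range == nb.range
        elif isinstance(na, Result):
            assert set(na) == set(nb)
            for item in na:
                assert na.tag(item) == nb.tag(item), (fn, item)
                va, vb = na.get(item), nb.get(item)
                if isinstance(va, np.ndarray):
                    np.testing.assert_array_equal(va, vb)
                else:
                    assert va == vb
        elif hasattr(na, "target"):
            assert na.target == nb.target


class TestRoundTrip:
    def test_full_roundtrip_reproduces_tree(self, tmp_path):
        original = _rich_trajectory()
        fn = tmp_path / "rich.h5"
        store_trajectory(original, fn)
        loaded = load_trajectory(fn, level=FULL)
        assert loaded.name == original.name
        assert loaded.comment == original.comment
        assert loaded.explored_names == original.explored_names
        _assert_trees_equal(original, loaded)

    def test_run_table_roundtrip(self, tmp_path):
        original = _rich_trajectory()
        fn = tmp_path / "rich.h5"
        store_trajectory(original, fn)
        loaded = load_trajectory(fn, level=SKELETON)
        assert len(loaded.run_table) == 3
        rec = loaded.run_table[0]
        assert rec.completed and rec.runtime_seconds == 0.25
        assert not loaded.run_table[1].completed
        assert [r.name for r in loaded.run_table] == [
            "run_00000000", "run_00000001", "run_00000002"]

    def test_hierarchy_maps_one_to_one(self, tmp_path):
        original = _rich_trajectory()
        fn = tmp_path / "rich.h5"
        store_trajectory(original, fn)
        tree_groups = {
            fn_ for fn_, n in original.iter_nodes()
            if isinstance(n, GroupNode)
        }
        with h5py.File(fn, "r") as f:
            root = f["rich"]
            for path in tree_groups:
                assert path.replace(".", "/") in root
            # and every stored group under the top branches maps back
            found = []
            for top in ("parameters", "results", "config"):
                root[top].visit(lambda p: found.append(f"{top}/{p}"))
            for h5p in found:
                obj = root[h5p]
                if isinstance(obj, h5py.Group) \
                        and obj.attrs.get("node_kind") == "group":
                    assert h5p.replace("/", ".") in tree_groups

    def test_format_version_attribute(self, tmp_path):
        fn = tmp_path / "rich.h5"
        store_trajectory(_rich_trajectory(), fn)
        with h5py.File(fn, "r") as f:
            assert f["rich"].attrs["format_version"] == "1"


class TestLoadLevels:
    @pytest.fixture()
    def stored(self, tmp_path):
        fn = tmp_path / "rich.h5"
        store_trajectory(_rich_trajectory(), fn)
        return fn

    def test_skeleton_has_ranges_but_no_results(self, stored):
        t = load_trajectory(stored, level=SKELETON)
        assert t.get_node("parameters.x").range == [1.0, 2.0, 3.0]
        with pytest.raises(NotFoundError):
            t.resolve("summary")

    def test_level_monotonicity(self, stored):
        seen = {}
        for level in (SKELETON, STRUCTURE, FULL):
            t = load_trajectory(stored, level=level)
            seen[level] = {fn for fn, _ in t.iter_nodes()}
        assert seen[SKELETON] <= seen[STRUCTURE] == seen[FULL]

    def test_structure_defers_payload(self, stored):
        t = load_trajectory(stored, level=STRUCTURE)
        node = t.get_node("results.summary")
        assert not node.data_loaded
        assert t.resolve("results.summary") == 42.0  # loads on demand
        assert node.data_loaded

    def test_lazy_load_equals_full_load(self, stored):
        lazy = load_trajectory(stored, level=SKELETON, auto_load=True)
        full = load_trajectory(stored, level=FULL)
        for query in ("results.summary", "results.monitors.spikes.i",
                      "parameters.weights", "results.table"):
            a, b = lazy.resolve(query), full.resolve(query)
            if isinstance(a, np.ndarray):
                np.testing.assert_array_equal(a, b)
            elif isinstance(a, Result):
                assert a.items_dict.keys() == b.items_dict.keys()
            else:
                assert a == b

    def test_full_load_never_touches_disk_again(self, stored):
        t = load_trajectory(stored, level=FULL)
        service = t.storage
        calls = service.load_calls
        t.resolve("results.summary")
        t.resolve("parameters.x")
        assert service.load_calls == calls

    def test_skeleton_without_autoload_advises_explicit_load(self, stored):
        t = load_trajectory(stored, level=SKELETON, auto_load=False)
        with pytest.raises(NotFoundError, match="auto_load"):
            t.resolve("summary")

    def test_soft_link_restored(self, stored):
        t = load_trajectory(stored, level=FULL)
        assert t.resolve("best") == 42.0


class TestPartialStorage:
    def test_store_node_touches_only_subtree(self, tmp_path):
        t = _rich_trajectory()
        fn = tmp_path / "t.h5"
        service = store_trajectory(t, fn)
        t.add_result("final", 9.0)
        service.store_node(t, "results.final")
        loaded = load_trajectory(fn)
        assert loaded.resolve("results.final") == 9.0

    def test_store_node_missing_path(self, tmp_path):
        t = _rich_trajectory()
        service = store_trajectory(t, tmp_path / "t.h5")
        with pytest.raises(NotFoundError):
            service.store_node(t, "results.not_there")

    def test_store_is_idempotent(self, tmp_path):
        t = _rich_trajectory()
        fn = tmp_path / "t.h5"
        service = store_trajectory(t, fn)

        def snapshot():
            items = {}
            with h5py.File(fn, "r") as f:
                def visit(name, obj):
                    if isinstance(obj, h5py.Dataset):
                        items[name] = obj[()]
                f.visititems(visit)
            return items

        before = snapshot()
        service.store_tree(t)
        service.store_node(t, "results.summary")
        after = snapshot()
        assert set(before) == set(after)
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_delete_is_unsupported(self, tmp_path):
        t = _rich_trajectory()
        service = store_trajectory(t, tmp_path / "t.h5")
        with pytest.raises(UnsupportedOperationError):
            service.delete_node(t, "results.summary")


class TestCustomKinds:
    class _UpperCodec:
        """Stores a marker string upper-cased; toy custom kind."""

        tag = "shout"

        def matches(self, value):
            return isinstance(value, str) and value.startswith("shout:")

        def full_tag(self, value):
            return self.tag

        def encode(self, group, name, value):
            group.create_dataset(name, data=value.upper())

        def decode(self, group, name, tag):
            raw = group[name][()]
            raw = raw.decode() if isinstance(raw, bytes) else raw
            return raw.lower()

    def _registry(self):
        from trajkit.typetags import _make_builtin_registry

        reg = _make_builtin_registry()
        # custom codec must win over the generic str codec
        reg._order.insert(0, self._UpperCodec())
        reg._codecs["shout"] = reg._order[0]
        return reg

    def test_registered_kind_roundtrips(self, tmp_path):
        reg = self._registry()
        t = Trajectory("custom", registry=reg)
        t.add_result("msg", "shout:hello")
        fn = tmp_path / "c.h5"
        store_trajectory(t, fn, registry=reg)
        loaded = load_trajectory(fn, registry=reg)
        assert loaded.resolve("msg") == "shout:hello"

    def test_loading_without_registration_names_tag(self, tmp_path):
        reg = self._registry()
        t = Trajectory("custom", registry=reg)
        t.add_result("msg", "shout:hello")
        fn = tmp_path / "c.h5"
        store_trajectory(t, fn, registry=reg)
        with pytest.raises(UnknownTagError, match="shout"):
            load_trajectory(fn)  # default registry lacks the codec


def test_unknown_trajectory_name(tmp_path):
    fn = tmp_path / "t.h5"
    store_trajectory(_rich_trajectory(), fn)
    with pytest.raises(NotFoundError):
        load_trajectory(fn, name="other")


def test_missing_file():
    with pytest.raises(IOError):
        load_trajectory("/nonexistent/nowhere.h5")
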