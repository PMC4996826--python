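"""Trajectory tree: construction, natural naming, exploration, merging."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trajkit import Trajectory, cartesian_product, run_name
from trajkit.exceptions import (
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
from trajkit.tree import RunRecord


class TestConstruction:
    def test_add_parameter_creates_leaf(self, traj):
        traj.add_parameter("x", 1.0, comment="I am the first dimension!")
        assert traj.get_node("parameters.x").default == 1.0

    def test_intermediate_groups_auto_created(self, traj):
        traj.add_parameter("syn.w", -0.5)
        group = traj.get_node("parameters.syn")
        assert group.kind == "group"
        assert traj["parameters.syn.w"] == -0.5

    def test_add_parameter_after_runs_rejected(self, traj):
        traj.add_parameter("x", 1.0)
        traj.explore({"x": [1.0, 2.0]})
        traj.run_table[0].completed = True
        with pytest.raises(RunPhaseError):
            traj.add_parameter("y", 1.0)

    def test_name_collision_rejected(self, traj):
        traj.add_parameter("x", 1.0)
        with pytest.raises(NameCollisionError):
            traj.add_parameter("x", 2.0)

    def test_invalid_names_rejected(self, traj):
        for bad in ("1abc", "a b", "crun", "run_00000002", "a.b..c"):
            with pytest.raises(ValueError):
                traj.add_parameter(bad, 1.0)

    def test_result_outside_run_lands_under_results(self, traj):
        traj.add_result("final", 1.5, 2.5)
        leaf = traj.get_node("results.final")
        assert leaf.get("final_0") == 1.5
        assert leaf.get("final_1") == 2.5

    def test_result_inside_run_lands_under_run_group(self, traj):
        traj.add_parameter("x", 1.0)
        traj.explore({"x": [1.0, 2.0, 3.0]})
        traj.current_run_index = 2
        traj._in_run = True
        traj.add_result("z", 21.0)
        traj._in_run = False
        traj.current_run_index = -1
        assert traj["results.runs.run_00000002.z"] == 21.0

    def test_duplicate_result_path_rejected(self, traj):
        traj.add_result("final", 1.0)
        with pytest.raises(NameCollisionError):
            traj.add_result("final", 2.0)


class TestResolution:
    def test_shortcut_equals_full_path(self, traj):
        traj.add_parameter("x", 1.0)
        assert traj.resolve("x") == traj.resolve("parameters.x") == 1.0

    def test_attribute_style_access(self, traj):
        traj.add_parameter("syn.w", -0.25)
        assert traj.syn.w == -0.25
        assert traj.parameters.syn.w == -0.25

    def test_explored_parameter_resolves_per_run(self, traj):
        traj.add_parameter("rule_number", 0)
        traj.explore({"rule_number": [10, 30, 90, 110, 184, 190]})
        assert traj.rule_number == 0  # no run selected -> default
        traj.current_run_index = 2
        assert traj.rule_number == 90

    def test_missing_name(self, traj):
        with pytest.raises(NotFoundError):
            traj.resolve("nonexistent")

    def test_ambiguous_shortcut_raises(self, traj):
        traj.add_parameter("z", 1.0)
        traj.add_result("z", 2.0)
        with pytest.raises(AmbiguousNameError):
            traj.resolve("z")
        assert traj.resolve("parameters.z") == 1.0
        assert traj.resolve("results.z") == 2.0

    def test_crun_token(self, traj):
        traj.add_parameter("x", 1.0)
        traj.explore({"x": [1.0, 2.0, 3.0]})
        traj.current_run_index = 2
        assert run_name(traj.current_run_index) == "run_00000002"
        with pytest.raises(NotFoundError, match="crun"):
            traj.current_run_index = -1
            traj.resolve("results.runs.crun.z")

    def test_read_during_run_locks_parameter(self, traj):
        traj.add_parameter("x", 1.0)
        traj.explore({"x": [1.0]})
        node = traj.get_node("parameters.x")
        _ = traj.x
        assert not node.locked  # plain introspection does not lock
        traj._in_run = True
        traj.current_run_index = 0
        _ = traj.x
        traj._in_run = False
        assert node.locked


class TestLinks:
    def test_link_aliases_target(self, traj):
        traj.add_result("final", 42.0)
        traj.add_link("best", "results.final")
        assert traj.resolve("best") == traj.resolve("results.final") == 42.0

    def test_link_to_missing_target(self, traj):
        with pytest.raises(NotFoundError):
            traj.add_link("best", "results.nope")

    def test_link_cycle_capped(self, traj):
        traj.add_result("final", 1.0)
        traj.add_link("a", "results.final")
        # rewire into a self-referential chain behind the API's back
        traj.root.children["a"].target = "a"
        with pytest.raises(LinkDepthError):
            traj.resolve("a")


class TestExploration:
    def test_explore_initializes_run_table(self, traj):
        traj.add_parameter("x", 1.0)
        traj.add_parameter("y", 1.0)
        traj.explore(cartesian_product(
            {"x": [1.0, 2.0, 3.0, 4.0], "y": [6.0, 7.0, 8.0]}))
        assert traj.n_runs == 12
        assert [r.index for r in traj.run_table] == list(range(12))
        assert traj.run_table[2].name == "run_00000002"

    def test_length_mismatch(self, traj):
        traj.add_parameter("x", 1.0)
        traj.add_parameter("y", 1.0)
        with pytest.raises(LengthMismatchError):
            traj.explore({"x": [1.0, 2.0], "y": [1.0, 2.0, 3.0]})

    def test_explore_unknown_parameter(self, traj):
        with pytest.raises(NotFoundError):
            traj.explore({"nope": [1, 2]})

    def test_empty_exploration(self, traj):
        traj.add_parameter("x", 1.0)
        with pytest.raises(EmptyRangeError):
            traj.explore({"x": []})

    def test_expand_fresh_behaves_like_explore(self, traj):
        traj.add_parameter("x", 0.0)
        traj.expand({"x": [float(i) for i in range(200)]})
        assert traj.n_runs == 200

    def test_expand_continues_indices(self, traj):
        traj.add_parameter("x", 0.0)
        traj.expand({"x": [float(i) for i in range(200)]})
        traj.expand({"x": [float(i) for i in range(200)]})
        assert traj.n_runs == 400
        assert traj.run_table[200].index == 200
        assert traj.run_table[-1].name == "run_00000399"

    def test_expand_different_name_set_rejected(self, traj):
        traj.add_parameter("x", 0.0)
        traj.add_parameter("y", 0.0)
        traj.explore({"x": [1.0, 2.0]})
        with pytest.raises(ExplorationMismatchError):
            traj.expand({"y": [3.0, 4.0]})

    def test_iter_runs_sets_and_restores_pointer(self, traj):
        traj.add_parameter("rule_number", 0)
        traj.explore({"rule_number": [10, 30, 90, 110, 184, 190]})
        seen = []
        for name in traj.iter_runs():
            seen.append((name, traj.rule_number))
        assert [v for _, v in seen] == [10, 30, 90, 110, 184, 190]
        assert seen[0][0] == "run_00000000"
        assert traj.current_run_index == -1

    def test_iter_runs_early_exit_restores_pointer(self, traj):
        traj.add_parameter("x", 0.0)
        traj.explore({"x": [1.0, 2.0, 3.0]})
        for _ in traj.iter_runs():
            break
        assert traj.current_run_index == -1


class TestPredicateFiltering:
    def test_paper_predicate(self, traj):
        traj.add_parameter("rule_number", 0)
        traj.explore({"rule_number": [10, 30, 90, 110, 184, 190]})
        idx = traj.find_run_indices(["rule_number"],
                                    lambda r: 30 < r < 120)
        assert idx == [2, 3]

    def test_tautology_and_contradiction(self, traj):
        traj.add_parameter("x", 0.0)
        traj.explore({"x": [1.0, 2.0, 3.0]})
        assert traj.find_run_indices(["x"], lambda v: True) == [0, 1, 2]
        assert traj.find_run_indices(["x"], lambda v: False) == []

    def test_unexplored_parameter_rejected(self, traj):
        traj.add_parameter("x", 0.0)
        traj.add_parameter("y", 0.0)
        traj.explore({"x": [1.0]})
        with pytest.raises(UnexploredParameterError):
            traj.find_run_indices(["y"], lambda v: True)

    @settings(deadline=None, max_examples=25)
    @given(values=st.lists(st.integers(0, 50), min_size=1, max_size=30),
           threshold=st.integers(0, 50))
    def test_matches_bruteforce_oracle(self, values, threshold):
        traj = Trajectory("oracle")
        traj.add_parameter("v", 0)
        traj.explore({"v": values})
        pred = lambda v: v >= threshold
        expected = [i for i, v in enumerate(values) if pred(v)]
        assert traj.find_run_indices(["v"], pred) == expected


class TestCartesianProduct:
    def test_first_parameter_cycles_fastest(self):
        out = cartesian_product({"x": [1.0, 2.0, 3.0, 4.0],
                                 "y": [6.0, 7.0, 8.0]})
        points = list(zip(out["x"], out["y"]))
        assert len(points) == 12
        assert points[0] == (1.0, 6.0)
        assert points[1] == (2.0, 6.0)
        assert points[11] == (4.0, 8.0)

    def test_single_factor_identity(self):
        out = cartesian_product({"x": ["a", "b"]})
        assert out == {"x": ["a", "b"]}

    def test_three_bit_counter_oracle(self):
        out = cartesian_product({"a": [0, 1], "b": [0, 1], "c": [0, 1]})
        got = list(zip(out["a"], out["b"], out["c"]))
        # brute-force nested loops, innermost = first-listed parameter
        expected = [(a, b, c)
                    for c in (0, 1) for b in (0, 1) for a in (0, 1)]
        assert got == expected
        assert len(got) == 8

    def test_empty_factor_rejected(self):
        with pytest.raises(EmptyRangeError):
            cartesian_product({"x": [], "y": [1]})

    @settings(deadline=None, max_examples=25)
    @given(lists=st.lists(
        st.lists(st.integers(0, 5), min_size=1, max_size=4),
        min_size=1, max_size=3))
    def test_matches_itertools_oracle(self, lists):
        spec = {f"p{i}": vals for i, vals in enumerate(lists)}
        out = cartesian_product(spec)
        got = set(zip(*(out[k] for k in spec)))
        expected = set(itertools.product(*spec.values()))
        assert got == expected
        total = 1
        for vals in lists:
            total *= len(vals)
        assert all(len(v) == total for v in out.values())


def _make_ca_traj(name, rules):
    t = Trajectory(name)
    t.add_parameter("rule_number", 0)
    t.explore({"rule_number": list(rules)})
    for i, _ in enumerate(t.iter_runs()):
        t._in_run = True
        t.add_result("pattern", float(rules[i]))
        t._in_run = False
        t.run_table[i].completed = True
    return t


class TestMerge:
    def test_merge_appends_and_reroots(self):
        a = _make_ca_traj("a", [10, 30, 90, 110, 184, 190])
        b = _make_ca_traj("b", [1, 2, 3])
        a.merge(b)
        assert a.n_runs == 9
        assert a["results.runs.run_00000006.pattern"] == 1.0
        assert a.get_node("parameters.rule_number").range[-1] == 3

    def test_merge_dedupe_identical_is_noop_on_count(self):
        a = _make_ca_traj("a", [10, 30, 90])
        b = _make_ca_traj("b", [10, 30, 90])
        a.merge(b, remove_duplicates=True)
        assert a.n_runs == 3

    def test_merge_mismatched_space_rejected(self):
        a = _make_ca_traj("a", [10, 30])
        b = Trajectory("b")
        b.add_parameter("other", 0)
        b.explore({"other": [1, 2]})
        with pytest.raises(SpaceMismatchError):
            a.merge(b)

    def test_merge_count_invariant(self):
        a = _make_ca_traj("a", [10, 30, 90])
        b = _make_ca_traj("b", [90, 110])
        a.merge(b, remove_duplicates=True)
        assert a.n_runs == 3 + 2 - 1
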