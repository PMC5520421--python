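"""Local-path enumeration and Local Causality Graph construction."""

import pytest

from bifan.fixtures import GeneratorConfig, random_an
from bifan.localpaths import (
    LocalState,
    Objective,
    build_lcg,
    enab_of_path,
    lcg_to_dot,
    local_paths,
)
from bifan.oracles import oracle_local_paths


class TestLocalPaths:
    def test_direct_path_to_committed_state(self, fig1):
        net, _, _ = fig1
        paths = local_paths(net, Objective("a", 0, 2))
        assert [p.step_ids for p in paths] == [("t3",)]
        assert enab_of_path(paths[0]) == {LocalState("b", 0), LocalState("c", 0)}

    def test_two_step_path(self, fig1):
        net, _, _ = fig1
        paths = local_paths(net, Objective("c", 0, 2))
        assert [p.step_ids for p in paths] == [("t6", "t8")]
        assert enab_of_path(paths[0]) == {LocalState("a", 1), LocalState("b", 0)}

    def test_dead_end_has_no_paths(self, fig1):
        net, _, _ = fig1
        assert local_paths(net, Objective("c", 2, 1)) == []

    def test_trivial_objective_is_the_empty_path(self, fig1):
        net, _, _ = fig1
        for a, i in (("a", 0), ("b", 1), ("c", 2)):
            paths = local_paths(net, Objective(a, i, i))
            assert len(paths) == 1 and len(paths[0]) == 0
            assert enab_of_path(paths[0]) == frozenset()

    def test_unconditioned_step_has_empty_enab(self, fig1):
        net, _, _ = fig1
        paths = local_paths(net, Objective("b", 0, 1))
        assert [p.step_ids for p in paths] == [("t4",)]
        assert enab_of_path(paths[0]) == frozenset()

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_blind_enumeration_oracle(self, seed):
        net = random_an(
            GeneratorConfig(
                n_automata=2 + seed % 3,
                states_per_automaton=(2, 4),
                transitions_per_automaton=(2, 6),
                seed=1000 + seed,
            )
        )
        for a in net.names:
            k = len(net.automata[a])
            for i in range(k):
                for j in range(k):
                    obj = Objective(a, i, j)
                    got = {p.step_ids for p in local_paths(net, obj)}
                    assert got == oracle_local_paths(net, obj)

    @pytest.mark.parametrize("seed", range(10))
    def test_path_length_bounded_by_automaton_size(self, seed):
        net = random_an(
            GeneratorConfig(
                n_automata=3,
                states_per_automaton=(2, 4),
                transitions_per_automaton=(3, 7),
                seed=2000 + seed,
            )
        )
        for a in net.names:
            k = len(net.automata[a])
            for i in range(k):
                for j in range(k):
                    for p in local_paths(net, Objective(a, i, j)):
                        assert len(p) <= k - 1


class TestLCG:
    def test_root_directed_graph_contains_dead_objective(self, fig1):
        """From the context of a state with c=2, the objective c2~>c0 enters
        the graph but owns zero local-path children -- the shape that lets
        the necessary condition fail."""
        net, _, _ = fig1
        context = {"a": [1], "b": [0], "c": [2]}
        lcg = build_lcg(net, [Objective("a", 1, 2)], context=context)
        dead = Objective("c", 2, 0)
        assert dead in lcg.objective_nodes
        assert lcg.children(dead) == []
        lcg.validate()

    def test_trivial_root_objective(self, fig1):
        net, _, _ = fig1
        lcg = build_lcg(net, [Objective("a", 1, 1)], context={"a": [1]})
        assert Objective("a", 1, 1) in lcg.objective_nodes
        eps = [p for p in lcg.path_nodes if len(p) == 0]
        assert len(eps) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_full_lcg_matches_direct_construction(self, seed):
        """With all objectives as roots, node/edge counts equal a brute-force
        construction straight from the definition."""
        net = random_an(GeneratorConfig(n_automata=3, seed=3000 + seed))
        all_objs = [
            Objective(a, i, j)
            for a in net.names
            for i in net.automata[a]
            for j in net.automata[a]
        ]
        lcg = build_lcg(net, all_objs)
        lcg.validate()
        # oracle: straight from the definition
        expected_paths = set()
        expected_edges = set()
        expected_locals = set()
        for obj in all_objs:
            target = LocalState(obj.automaton, obj.to_index)
            expected_locals.add(target)
            expected_edges.add((target, obj))
            for ids in oracle_local_paths(net, obj):
                path = next(
                    p for p in local_paths(net, obj) if p.step_ids == ids
                )
                expected_paths.add(path)
                expected_edges.add((obj, path))
                for ls in enab_of_path(path):
                    expected_locals.add(ls)
                    expected_edges.add((path, ls))
        # every local state is some objective's target here, so the sets agree
        assert lcg.objective_nodes == set(all_objs)
        assert lcg.path_nodes == expected_paths
        assert lcg.local_state_nodes == expected_locals
        assert lcg.edges == expected_edges
        # size bound: |L| + |L|^2 + number of paths
        n_l = len(lcg.local_state_nodes)
        assert len(lcg.nodes()) <= n_l + n_l**2 + len(lcg.path_nodes)

    def test_dot_export_shows_three_node_kinds(self, fig1):
        net, _, _ = fig1
        lcg = build_lcg(net, [Objective("a", 0, 2)])
        dot = lcg_to_dot(lcg)
        assert "shape=box" in dot and "shape=plaintext" in dot
        assert "shape=circle" in dot
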