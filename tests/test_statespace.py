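"""Reachable state graph, attractors, goal connectivity, exact bifurcations."""

import pytest

from bifan.model import Goal, parse_an
from bifan.oracles import oracle_states
from bifan.statespace import (
    StateCapExceeded,
    attractors,
    exact_bifurcations,
    goal_connected,
    graph_to_dot,
    graph_to_json,
    reachable_graph,
)

TOGGLE = """\
automaton "a" [0, 1]
automaton "b" [0, 1]
"a" 0 -> 1 when "b"=0
"a" 1 -> 0 when "b"=1
"b" 0 -> 1 when "a"=1
"b" 1 -> 0 when "a"=0
"""


class TestReachableGraph:
    def test_one_step_successor_present(self, fig1):
        net, s0, _ = fig1
        g = reachable_graph(net, s0)
        assert net.state({"a": 0, "b": 1, "c": 0}) in g.states
        assert (s0, "t4", net.state({"a": 0, "b": 1, "c": 0})) in g.edges

    def test_no_transition_graph_is_single_state(self):
        net = parse_an('automaton "x" [0, 1]\nautomaton "y" [0, 1]\n')
        s0 = net.state({"x": 0, "y": 0})
        g = reachable_graph(net, s0)
        assert g.states == {s0} and g.edges == []

    def test_state_count_matches_enumeration_oracle(self, fig1):
        net, s0, _ = fig1
        g = reachable_graph(net, s0)
        assert len(g) == len(oracle_states(net, s0))

    def test_state_cap_raises(self, fig1):
        net, s0, _ = fig1
        with pytest.raises(StateCapExceeded):
            reachable_graph(net, s0, state_cap=5)

    def test_graph_is_closed(self, fig1):
        net, s0, _ = fig1
        g = reachable_graph(net, s0)
        for s in g.states:
            assert {(t.id, net.apply(s, t)) for t in net.enabled(s)} == set(
                g.successors(s)
            )

    def test_exports_mention_all_states(self, fig1):
        net, s0, _ = fig1
        g = reachable_graph(net, s0)
        js = graph_to_json(g)
        dot = graph_to_dot(g)
        for s in g.states:
            assert str(s) in js and str(s) in dot


class TestAttractors:
    def test_goal_free_attractor_exists(self, fig1):
        net, s0, goal = fig1
        g = reachable_graph(net, s0)
        atts = attractors(g)
        goal_free = [
            a
            for a in atts
            if all(s[goal.automaton] != goal.index for s in a)
        ]
        assert goal_free, "expected an attractor without a2"
        # the committed state <a2,b1,c0> is also terminal here
        assert any(
            any(s[goal.automaton] == goal.index for s in a) for a in atts
        )

    def test_single_state_network(self):
        net = parse_an('automaton "x" [0, 1]\nautomaton "y" [0, 1]\n')
        s0 = net.state({"x": 1, "y": 0})
        assert attractors(reachable_graph(net, s0)) == [{s0}]

    def test_exitless_cycle_is_unique_attractor(self):
        net = parse_an(TOGGLE)
        s0 = net.state({"a": 0, "b": 0})
        g = reachable_graph(net, s0)
        atts = attractors(g)
        assert len(atts) == 1
        assert atts[0] == g.states  # the 4-cycle covers everything reachable

    def test_attractors_are_strongly_connected_and_terminal(self, corpus_instances):
        for net, s0, _goal in corpus_instances[:25]:
            g = reachable_graph(net, s0)
            for comp in attractors(g):
                for s in comp:
                    succs = {s2 for _t, s2 in g.successors(s)}
                    assert succs <= comp  # terminal
                # strongly connected: every state reaches every other
                for s in comp:
                    seen = {s}
                    stack = [s]
                    while stack:
                        x = stack.pop()
                        for _t, y in g.successors(x):
                            if y not in seen:
                                seen.add(y)
                                stack.append(y)
                    assert comp <= seen


class TestGoalConnected:
    def test_fig1_connected_set(self, fig1):
        net, s0, goal = fig1
        g = reachable_graph(net, s0)
        gc = goal_connected(g, goal)
        assert s0 in gc
        atts = attractors(g)
        goal_free = next(
            a for a in atts if all(s["a"] != 2 for s in a)
        )
        assert not (gc & goal_free)

    def test_goal_in_root_is_connected(self, fig1):
        net, _, _ = fig1
        s = net.state({"a": 2, "b": 0, "c": 0})
        g = reachable_graph(net, s)
        assert s in goal_connected(g, Goal("a", 2))

    def test_absent_goal_empty(self, fig1):
        net, s0, _ = fig1
        g = reachable_graph(net, s0)
        s0_graph_without = [s for s in g.states if s["a"] == 2]
        # restrict to a start from which a2 is unreachable
        s = net.state({"a": 0, "b": 0, "c": 2})
        g2 = reachable_graph(net, s)
        assert goal_connected(g2, Goal("a", 2)) == set()

    def test_no_edge_enters_the_connected_set_from_outside(self, corpus_instances):
        for net, s0, goal in corpus_instances[:40]:
            g = reachable_graph(net, s0)
            gc = goal_connected(g, goal)
            for s, _tid, s2 in g.edges:
                assert not (s not in gc and s2 in gc)


class TestExactBifurcations:
    def test_fig1_unique_bifurcation_t8(self, fig1):
        net, s0, goal = fig1
        res = exact_bifurcations(net, s0, goal)
        assert [r.transition for r in res] == ["t8"]
        for sb, su in res[0].witnesses:
            assert su == net.apply(sb, net.transition("t8"))

    def test_always_reachable_goal_has_no_bifurcation(self, fig1):
        net, s0, _ = fig1
        # b1 stays reachable everywhere: t4 (b0->b1) is unconditioned
        assert exact_bifurcations(net, s0, Goal("b", 1)) == []

    def test_unreachable_goal_has_no_bifurcation(self, fig1):
        net, _, _ = fig1
        s = net.state({"a": 0, "b": 0, "c": 2})
        assert exact_bifurcations(net, s, Goal("a", 2)) == []

    def test_bifurcation_implies_goal_free_attractor(self, fig1):
        net, s0, goal = fig1
        assert exact_bifurcations(net, s0, goal)
        g = reachable_graph(net, s0)
        assert any(
            all(s[goal.automaton] != goal.index for s in a)
            for a in attractors(g)
        )
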