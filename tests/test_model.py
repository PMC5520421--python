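"""Model types, AN parsing/serialization, and one-step semantics."""

import pytest

from bifan.fixtures import FIG1_AN, GeneratorConfig, random_an
from bifan.model import (
    ANSemanticError,
    ANSyntaxError,
    LocalState,
    LocalTransition,
    NotApplicableError,
    encode_goal_states,
    parse_an,
)


class TestParsing:
    def test_worked_example_counts(self, fig1):
        net, _s0, _goal = fig1
        assert len(net.automata) == 3
        assert len(net.transitions) == 8
        assert net.automata == {"a": [0, 1, 2], "b": [0, 1], "c": [0, 1, 2]}

    def test_transition_ids_in_file_order(self, fig1):
        net, _, _ = fig1
        assert [t.id for t in net.transitions] == [f"t{i}" for i in range(1, 9)]
        t8 = net.transition("t8")
        assert (t8.automaton, t8.origin, t8.dest) == ("c", 1, 2)
        assert t8.condition_dict == {"b": 0}

    def test_automaton_with_no_transitions_is_valid(self):
        net = parse_an('automaton "x" [0, 1]\n')
        assert net.transitions == []

    def test_self_loop_rejected(self):
        with pytest.raises(ANSemanticError, match="origin and destination"):
            parse_an('automaton "a" [0, 1]\n"a" 0 -> 0\n')

    @pytest.mark.parametrize(
        "text, exc, match",
        [
            ('automaton "a" [0, 1]\n"a" 0 -> 2\n', ANSemanticError, "a_2"),
            ('automaton "a" [0, 1]\n"b" 0 -> 1\n', ANSemanticError, "'b'"),
            ('automaton "a" [0, 1]\nautomaton "a" [0, 1]\n', ANSemanticError, "duplicate"),
            ('automaton "a" [0, 1]\n"a" 0 -> 1 when "a"=1\n', ANSemanticError, "own automaton"),
            ('automaton "a" [0]\n', ANSemanticError, "at least 2"),
            ("garbage here\n", ANSyntaxError, "line 1"),
            ('automaton "a" [0, 1]\n"a" 0 ->\n', ANSyntaxError, "line 2"),
        ],
    )
    def test_rejects_invalid_models(self, text, exc, match):
        with pytest.raises(exc, match=match):
            parse_an(text)

    def test_condition_at_most_one_state_per_automaton(self):
        with pytest.raises(ANSemanticError, match="two condition states"):
            LocalTransition(
                "t1", "a", 0, 1,
                (LocalState("b", 0), LocalState("b", 1)),
            )

    @pytest.mark.parametrize("seed", range(0, 40, 3))
    def test_serialize_parse_round_trip(self, seed):
        net = random_an(GeneratorConfig(n_automata=2 + seed % 4, seed=seed))
        text = net.serialize()
        again = parse_an(text)
        assert again.serialize() == text
        assert again.automata == net.automata
        assert [str(t) for t in again.transitions] == [
            str(t) for t in net.transitions
        ]

    def test_fig1_round_trip(self, fig1):
        net, _, _ = fig1
        assert parse_an(net.serialize()).serialize() == net.serialize()
        assert parse_an(FIG1_AN).serialize() == net.serialize()


class TestSemantics:
    def test_enabled_in_initial_state(self, fig1):
        net, s0, _ = fig1
        assert [t.id for t in net.enabled(s0)] == ["t2", "t3", "t4"]

    def test_enabled_after_committing_a2(self, fig1):
        net, _, _ = fig1
        s = net.state({"a": 2, "b": 0, "c": 0})
        assert [t.id for t in net.enabled(s)] == ["t4"]

    def test_enabled_empty_when_no_origin_matches(self):
        net = parse_an('automaton "a" [0, 1]\n"a" 0 -> 1\n')
        assert net.enabled(net.state({"a": 1})) == []

    def test_apply_unconditioned_transition(self, fig1):
        net, s0, _ = fig1
        s1 = net.apply(s0, net.transition("t4"))
        assert str(s1) == "a=0,b=1,c=0"
        s = net.state({"a": 1, "b": 0, "c": 0})
        assert str(net.apply(s, net.transition("t1"))) == "a=0,b=0,c=0"

    def test_apply_changes_exactly_one_coordinate(self, fig1):
        net, s0, _ = fig1
        seen = {s0}
        frontier = [s0]
        for _ in range(3):
            nxt = []
            for s in frontier:
                for t in net.enabled(s):
                    s2 = net.apply(s, t)
                    diff = [a for a, b in zip(s.values, s2.values) if a != b]
                    assert len(diff) == 1
                    if s2 not in seen:
                        seen.add(s2)
                        nxt.append(s2)
            frontier = nxt

    def test_apply_rejects_disabled_transition(self, fig1):
        net, s0, _ = fig1
        with pytest.raises(NotApplicableError):
            net.apply(s0, net.transition("t1"))  # origin a1, but s0(a)=a0


class TestGoalEncoding:
    def test_single_partial_target(self, fig1):
        net, _, _ = fig1
        net2, goal = encode_goal_states(net, [{"a": 2, "b": 0}])
        assert goal.automaton == "goal" and goal.index == 1
        added = [t for t in net2.transitions if t.automaton == "goal"]
        assert len(added) == 1
        assert added[0].origin == 0 and added[0].dest == 1
        assert added[0].condition_dict == {"a": 2, "b": 0}

    def test_empty_targets_make_goal_unreachable(self, fig1):
        net, s0, _ = fig1
        net2, goal = encode_goal_states(net, [])
        assert not [t for t in net2.transitions if t.automaton == goal.automaton]

    def test_two_targets_two_transitions(self, fig1):
        net, _, _ = fig1
        net2, goal = encode_goal_states(net, [{"a": 2}, {"b": 1, "c": 2}])
        added = [t for t in net2.transitions if t.automaton == goal.automaton]
        assert [t.condition_dict for t in added] == [{"a": 2}, {"b": 1, "c": 2}]

    def test_explicit_name_clash_rejected(self, fig1):
        net, _, _ = fig1
        with pytest.raises(ANSemanticError, match="already declared"):
            encode_goal_states(net, [{"a": 2}], name="b")
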