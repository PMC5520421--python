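"""Explicit reachable state graph, attractors, and exact bifurcations.

The exact characterization of a bifurcation transition: a local transition
``t_b`` such that some reachable global state ``s_b`` can still reach the
goal while ``s_u = s_b . t_b`` cannot.  On the explicit state graph this is
simply an edge crossing the boundary of the set of goal-connected states,
which makes the exact method sound and complete -- at the price of building
the full reachable set (worst case exponential in the number of automata).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import ANError, AutomataNetwork, GlobalState, Goal

__all__ = [
    "StateCapExceeded",
    "StateGraph",
    "BifurcationResult",
    "reachable_graph",
    "attractors",
    "goal_connected",
    "exact_bifurcations",
    "graph_to_json",
    "graph_to_dot",
]

DEFAULT_STATE_CAP = 1_000_000


class StateCapExceeded(ANError):
    """The reachable set outgrew ``state_cap``; use the approximate pipeline."""


@dataclass
class StateGraph:
    """Closed reachable state graph rooted at ``root``.

    ``edges`` are exactly the triples ``(s, t.id, s . t)`` for every state
    ``s`` and every transition ``t`` enabled in ``s``.
    """

    root: GlobalState
    states: set[GlobalState]
    edges: list[tuple[GlobalState, str, GlobalState]]
    _succ: dict[GlobalState, list[tuple[str, GlobalState]]] = field(
        default_factory=dict, repr=False
    )
    _pred: dict[GlobalState, list[GlobalState]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self._succ:
            for s in self.states:
                self._succ[s] = []
                self._pred[s] = []
            for s, tid, s2 in self.edges:
                self._succ[s].append((tid, s2))
                self._pred[s2].append(s)

    def successors(self, s: GlobalState) -> list[tuple[str, GlobalState]]:
        return self._succ[s]

    def predecessors(self, s: GlobalState) -> list[GlobalState]:
        return self._pred[s]

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class BifurcationResult:
    """One certified bifurcation transition.

    ``witnesses`` holds pairs ``(s_b, s_u)`` with ``s_u = s_b . transition``;
    ``method`` records which procedure certified it (``exact``, ``I3``,
    ``I3sharp``).
    """

    transition: str
    witnesses: Optional[list[tuple[GlobalState, GlobalState]]]
    method: str

    def to_dict(self, net: AutomataNetwork) -> dict:
        t = net.transition(self.transition)
        return {
            "transition": t.id,
            "automaton": t.automaton,
            "origin": t.origin,
            "dest": t.dest,
            "condition": t.condition_dict,
            "method": self.method,
            "witnesses": [
                {"s_b": str(sb), "s_u": str(su)}
                for sb, su in (self.witnesses or [])
            ],
        }


def reachable_graph(
    net: AutomataNetwork,
    s0: GlobalState,
    state_cap: int = DEFAULT_STATE_CAP,
) -> StateGraph:
    """Breadth-first closure of ``s0`` under the asynchronous semantics.

    Deterministic: states are expanded in discovery order and successors in
    transition-identifier order.  Raises `StateCapExceeded` when the set
    would grow past ``state_cap``.
    """
    states = {s0}
    edges: list[tuple[GlobalState, str, GlobalState]] = []
    queue = deque([s0])
    while queue:
        s = queue.popleft()
        for t in net.enabled(s):
            s2 = net.apply(s, t)
            edges.append((s, t.id, s2))
            if s2 not in states:
                if len(states) >= state_cap:
                    raise StateCapExceeded(
                        f"reachable set exceeds state cap {state_cap}"
                    )
                states.add(s2)
                queue.append(s2)
    return StateGraph(s0, states, edges)


def attractors(g: StateGraph) -> list[set[GlobalState]]:
    """Terminal strongly connected components of a closed state graph.

    An attractor is a set of states that is strongly connected and closed
    under outgoing transitions: the long-run behaviours of the network.
    Ordered by canonical minimal state.
    """
    dg = nx.DiGraph()
    dg.add_nodes_from(g.states)
    dg.add_edges_from((s, s2) for s, _tid, s2 in g.edges)
    cond = nx.condensation(dg)
    out = [
        set(cond.nodes[n]["members"])
        for n in cond.nodes
        if cond.out_degree(n) == 0
    ]
    return sorted(out, key=lambda comp: min(s.values for s in comp))


def goal_connected(g: StateGraph, goal: Goal) -> set[GlobalState]:
    """States of ``g`` from which some state containing the goal is reachable.

    Backward closure from the goal states; reflexive, so states already
    containing the goal are included.
    """
    seeds = [s for s in g.states if s[goal.automaton] == goal.index]
    seen = set(seeds)
    queue = deque(seeds)
    while queue:
        s = queue.popleft()
        for p in g.predecessors(s):
            if p not in seen:
                seen.add(p)
                queue.append(p)
    return seen


def exact_bifurcations(
    net: AutomataNetwork,
    s0: GlobalState,
    goal: Goal,
    state_cap: int = DEFAULT_STATE_CAP,
    with_witnesses: bool = True,
) -> list[BifurcationResult]:
    """Sound and complete bifurcation identification on the explicit graph.

    A local transition is reported when one of its state-graph edges leads
    from a goal-connected state to a non-goal-connected one.  Results are in
    transition-identifier order with all crossing edges attached as
    witnesses (unless ``with_witnesses`` is false).
    """
    g = reachable_graph(net, s0, state_cap)
    connected = goal_connected(g, goal)
    crossing: dict[str, list[tuple[GlobalState, GlobalState]]] = {}
    for s, tid, s2 in g.edges:
        if s in connected and s2 not in connected:
            crossing.setdefault(tid, []).append((s, s2))
    return [
        BifurcationResult(
            t.id, crossing[t.id] if with_witnesses else None, "exact"
        )
        for t in net.transitions
        if t.id in crossing
    ]


def graph_to_json(g: StateGraph) -> str:
    return json.dumps(
        {
            "root": str(g.root),
            "states": sorted(str(s) for s in g.states),
            "edges": [
                {"source": str(s), "transition": tid, "target": str(s2)}
                for s, tid, s2 in g.edges
            ],
        },
        indent=2,
    )


def graph_to_dot(g: StateGraph) -> str:
    lines = ["digraph stategraph {"]
    for s in sorted(g.states, key=lambda s: s.values):
        shape = "doublecircle" if s == g.root else "box"
        lines.append(f'  "{s}" [shape={shape}];')
    for s, tid, s2 in g.edges:
        lines.append(f'  "{s}" -> "{s2}" [label="{tid}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
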