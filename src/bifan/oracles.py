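"""Exhaustive reference implementations used for validation only.

Everything here recomputes semantics by brute force -- plain depth-first
enumeration over dictionaries, direct temporal-formula evaluation, blind
sequence filtering -- sharing no traversal code with the production modules
it cross-checks.  Size-capped: these are ground truth on test fixtures, not
tools for real models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Union

from .localpaths import Objective
from .model import AutomataNetwork, GlobalState, Goal

__all__ = [
    "OracleVerdict",
    "oracle_states",
    "oracle_reach",
    "oracle_ef_states",
    "oracle_ctl_bifurcations",
    "oracle_local_paths",
]

ORACLE_CAP = 10_000

State = tuple[tuple[str, int], ...]  # sorted (automaton, index) pairs


@dataclass(frozen=True)
class OracleVerdict:
    query: str
    verdict: Union[bool, frozenset]
    method: str


def _freeze(s: GlobalState) -> State:
    return tuple(sorted(s.items()))


def _successors(net: AutomataNetwork, s: State) -> list[tuple[str, State]]:
    d = dict(s)
    out = []
    for t in net.transitions:
        if d[t.automaton] != t.origin:
            continue
        if any(d[c.automaton] != c.index for c in t.condition):
            continue
        d2 = dict(d)
        d2[t.automaton] = t.dest
        out.append((t.id, tuple(sorted(d2.items()))))
    return out


def oracle_states(
    net: AutomataNetwork, s0: GlobalState, cap: int = ORACLE_CAP
) -> set[State]:
    """All states reachable from ``s0``, by depth-first enumeration."""
    start = _freeze(s0)
    seen = {start}
    stack = [start]
    while stack:
        s = stack.pop()
        for _tid, s2 in _successors(net, s):
            if s2 not in seen:
                if len(seen) >= cap:
                    raise RuntimeError(f"oracle cap {cap} exceeded")
                seen.add(s2)
                stack.append(s2)
    return seen


def oracle_reach(
    net: AutomataNetwork, s: GlobalState, goal: Goal, cap: int = ORACLE_CAP
) -> bool:
    """Exhaustive-search truth of ``s ->* (some state containing the goal)``."""
    for st in oracle_states(net, s, cap):
        if dict(st)[goal.automaton] == goal.index:
            return True
    return False


def oracle_ef_states(
    net: AutomataNetwork, s0: GlobalState, goal: Goal, cap: int = ORACLE_CAP
) -> tuple[set[State], set[State]]:
    """``(reachable states, those satisfying EF goal)`` from ``s0``.

    EF is evaluated by forward fixpoint over successor lists: start from the
    states containing the goal and repeatedly mark any state with a marked
    successor, until stable.
    """
    states = oracle_states(net, s0, cap)
    succ = {s: [s2 for _t, s2 in _successors(net, s)] for s in states}
    ef = {s for s in states if dict(s)[goal.automaton] == goal.index}
    changed = True
    while changed:
        changed = False
        for s in states:
            if s not in ef and any(s2 in ef for s2 in succ[s]):
                ef.add(s)
                changed = True
    return states, ef


def oracle_ctl_bifurcations(
    net: AutomataNetwork, s0: GlobalState, goal: Goal, cap: int = ORACLE_CAP
) -> frozenset[str]:
    """Direct evaluation of the temporal characterization of bifurcations.

    A transition ``t`` qualifies iff some reachable state satisfies: ``t``
    is enabled, EF goal holds, and some one-step successor both carries
    ``dest(t)`` and falsifies EF goal.  Successors range over *all* edges,
    exactly as the formula's next-step operator prescribes.
    """
    states, ef = oracle_ef_states(net, s0, goal, cap)
    succ = {s: [s2 for _t, s2 in _successors(net, s)] for s in states}
    out = set()
    for t in net.transitions:
        for s in states:
            d = dict(s)
            if d[t.automaton] != t.origin:
                continue
            if any(d[c.automaton] != c.index for c in t.condition):
                continue
            if s not in ef:
                continue
            if any(
                dict(s2)[t.automaton] == t.dest and s2 not in ef
                for s2 in succ[s]
            ):
                out.add(t.id)
                break
    return frozenset(out)


def oracle_local_paths(net: AutomataNetwork, obj: Objective) -> set[tuple[str, ...]]:
    """Blind enumeration of the acyclic local-path set, as step-id tuples.

    Generates *every* transition sequence of the automaton up to length
    ``|S(a)| - 1`` and filters by the defining clauses (chaining, endpoints,
    non-revisiting) -- no search-tree pruning shared with the production
    enumeration.
    """
    if obj.from_index == obj.to_index:
        return {()}
    trans = [t for t in net.transitions if t.automaton == obj.automaton]
    max_len = len(net.automata[obj.automaton]) - 1
    found: set[tuple[str, ...]] = set()
    for length in range(1, max_len + 1):
        for seq in product(trans, repeat=length):
            if seq[0].origin != obj.from_index:
                continue
            if seq[-1].dest != obj.to_index:
                continue
            if any(a.dest != b.origin for a, b in zip(seq, seq[1:])):
                continue
            ok = True
            for n in range(length):
                for m in range(n + 1):
                    if seq[n].dest == seq[m].origin:
                        ok = False
            if ok:
                found.add(tuple(t.id for t in seq))
    return found
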