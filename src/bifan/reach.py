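"""Static reachability approximations on the Local Causality Graph.

Two one-sided answers to ``s ->* g1`` that never build the state space:

* Over-approximation (necessary condition): the least fixpoint ``Omega`` of

      F(Omega) = { a_i ~> a_j | exists a local path tau of a_i ~> a_j
                   with s(b) ~> b_k in Omega for every b_k in enab(tau) }

  ``g1`` can only be reachable if ``s(g) ~> g1`` lands in ``Omega``; a
  negative answer *proves* non-reachability, a positive one proves nothing.

* Under-approximation (sufficient condition): an acyclic sub-LCG in which
  every required objective owns exactly one chosen local path, every path
  carries all its condition states, objectives start from the chosen
  context states, and condition states of a path step are pairwise
  independent.  Such a witness *proves* reachability; absence proves
  nothing.  Finding one is a backtracking search over (context-state choice
  per automaton, local-path choice per objective); checking a candidate is
  linear in its size.

For the saturation of same-automaton objectives the witness graph's own
ordering is used: when two local states of one automaton both occur, the
objective ``a_i ~> a_j`` is required unless ``a_i`` is an ancestor of
``a_j`` in the acyclic witness -- ancestors are needed strictly after their
descendants, so the automaton cannot yet have moved to ``a_i`` when ``a_j``
is first demanded.  Incomparable pairs require both directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .localpaths import (
    LCGNode,
    LocalCausalityGraph,
    LocalPath,
    Objective,
    enab_of_path,
    local_paths,
)
from .model import AutomataNetwork, GlobalState, Goal, LocalState

__all__ = [
    "Context",
    "OAResult",
    "UAWitness",
    "oa_reach",
    "ua_reach",
    "validate_ua_witness",
    "witness_to_json",
    "witness_to_dot",
]


@dataclass(frozen=True)
class Context:
    """A set of possible initial local states per automaton.

    A global state is the special case mapping every automaton to a
    singleton.  The under-approximation picks one allowed index per
    involved automaton; a witness then holds for every global state
    consistent with the picked indices.
    """

    allowed: Mapping[str, frozenset[int]]

    @classmethod
    def from_state(cls, s: GlobalState) -> "Context":
        return cls({a: frozenset([i]) for a, i in s.items()})

    @classmethod
    def of(cls, allowed: Mapping[str, Iterable[int]]) -> "Context":
        return cls({a: frozenset(v) for a, v in allowed.items()})

    def validate(self, net: AutomataNetwork) -> None:
        for a, idxs in self.allowed.items():
            if not idxs:
                raise ValueError(f"context for {a!r} is empty")
            for i in idxs:
                net._check_local(a, i, "context")


@dataclass(frozen=True)
class OAResult:
    """Outcome of the necessary condition.

    ``omega`` is the fixpoint restricted to the objectives the query can
    involve; ``decision=False`` certifies the goal is unreachable.
    """

    omega: frozenset[Objective]
    decision: bool


def oa_reach(net: AutomataNetwork, s: GlobalState, goal: Goal) -> OAResult:
    """Necessary condition for reaching ``goal`` from ``s``.

    Collects the objectives reachable from the root objective
    ``s(g) ~> g1`` through local paths and their conditions, then runs
    chaotic iteration of F to its least fixpoint.
    """
    root = Objective(goal.automaton, s[goal.automaton], goal.index)
    relevant: set[Objective] = set()
    stack = [root]
    while stack:
        obj = stack.pop()
        if obj in relevant:
            continue
        relevant.add(obj)
        for p in local_paths(net, obj):
            for ls in enab_of_path(p):
                stack.append(Objective(ls.automaton, s[ls.automaton], ls.index))
    omega: set[Objective] = set()
    changed = True
    while changed:
        changed = False
        for obj in relevant:
            if obj in omega:
                continue
            for p in local_paths(net, obj):
                if all(
                    Objective(ls.automaton, s[ls.automaton], ls.index) in omega
                    for ls in enab_of_path(p)
                ):
                    omega.add(obj)
                    changed = True
                    break
    return OAResult(frozenset(omega), root in omega)


@dataclass
class UAWitness:
    """A sub-LCG certifying simultaneous reachability of the targets.

    ``chosen_states`` fixes one context index per involved automaton; the
    certificate is valid from any global state agreeing with them on the
    automata of ``sub_lcg``.
    """

    sub_lcg: LocalCausalityGraph
    chosen_paths: dict[Objective, LocalPath]
    context: Context
    chosen_states: dict[str, int]
    targets: frozenset[LocalState]


@dataclass
class _SearchState:
    allowed: Mapping[str, frozenset[int]]  # shared, never mutated
    sigma: dict[str, int]
    locals_: set[LocalState]
    chosen: dict[Objective, LocalPath]
    edges: set[tuple[LCGNode, LCGNode]]
    required: set[Objective]

    def clone(self) -> "_SearchState":
        return _SearchState(
            self.allowed,
            dict(self.sigma),
            set(self.locals_),
            dict(self.chosen),
            set(self.edges),
            set(self.required),
        )


def _conn(edges: set[tuple[LCGNode, LCGNode]], start: LCGNode) -> set[LCGNode]:
    """Forward-reachable vertices from ``start`` (inclusive)."""
    succ: dict[LCGNode, list[LCGNode]] = {}
    for a, b in edges:
        succ.setdefault(a, []).append(b)
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for w in succ.get(v, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _acyclic(edges: set[tuple[LCGNode, LCGNode]]) -> bool:
    succ: dict[LCGNode, list[LCGNode]] = {}
    nodes: set[LCGNode] = set()
    for a, b in edges:
        succ.setdefault(a, []).append(b)
        nodes.add(a)
        nodes.add(b)
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(nodes, WHITE)

    def visit(v: LCGNode) -> bool:
        color[v] = GREY
        for w in succ.get(v, ()):
            if color[w] == GREY:
                return False
            if color[w] == WHITE and not visit(w):
                return False
        color[v] = BLACK
        return True

    return all(color[v] != WHITE or visit(v) for v in nodes)


def _independence_ok(
    chosen: Mapping[Objective, LocalPath],
    edges: set[tuple[LCGNode, LCGNode]],
    targets: Iterable[LocalState] = (),
) -> bool:
    """Independence of jointly required local states.

    For each step of each chosen path -- and for the root's target set,
    which must hold simultaneously -- at most one required state ``a_i``
    may be 'interfered with': such that some other state of the group is
    connected (in the witness) to a local state of automaton ``a`` other
    than ``a_i``.  The un-interfered states can be established
    independently and the one flagged state last.
    """
    conn_cache: dict[LCGNode, set[LCGNode]] = {}

    def conn(v: LCGNode) -> set[LCGNode]:
        if v not in conn_cache:
            conn_cache[v] = _conn(edges, v)
        return conn_cache[v]

    groups = [sorted(step.condition) for p in chosen.values() for step in p.steps]
    groups.append(sorted(targets))
    for enab in groups:
        flagged = 0
        for a_i in enab:
            others = [b for b in enab if b != a_i]
            if any(
                any(
                    isinstance(v, LocalState)
                    and v.automaton == a_i.automaton
                    and v != a_i
                    for v in conn(b_j)
                )
                for b_j in others
            ):
                flagged += 1
        # a lone required state interferes with nothing
        if flagged > 1:
            return False
    return True


def _saturate(
    net: AutomataNetwork, st: _SearchState
) -> Optional[tuple[str, list]]:
    """Deterministic propagation; returns the next branch point or None.

    Forced consequences (unique-option choices) are applied in place:
    * every local state needs a chosen context index for its automaton;
    * every required objective needs one chosen local path (no path = dead
      branch, signalled by raising _Dead);
    * ordering-aware pair saturation between same-automaton local states.
    """
    while True:
        # 1. context choice per automaton with a local state in the graph
        for ls in sorted(st.locals_):
            a = ls.automaton
            if a not in st.sigma:
                opts = sorted(st.allowed[a])
                if len(opts) == 1:
                    st.sigma[a] = opts[0]
                    continue
                return ("sigma", [(a, i) for i in opts])
        # 2. sigma-objectives and accumulated pair requirements
        new_req = False
        for ls in sorted(st.locals_):
            obj = Objective(ls.automaton, st.sigma[ls.automaton], ls.index)
            edge = (ls, obj)
            if edge not in st.edges or obj not in st.required:
                st.edges.add(edge)
                st.required.add(obj)
                new_req = True
        # 3. ordering-aware saturation between same-automaton local states
        by_automaton: dict[str, list[LocalState]] = {}
        for ls in st.locals_:
            by_automaton.setdefault(ls.automaton, []).append(ls)
        for a, group in sorted(by_automaton.items()):
            for a_i in sorted(group):
                for a_j in sorted(group):
                    if a_i == a_j:
                        continue
                    obj = Objective(a, a_i.index, a_j.index)
                    if obj in st.required:
                        continue
                    # exempt when a_i is an ancestor of a_j
                    if a_j in _conn(st.edges, a_i):
                        continue
                    st.edges.add((a_j, obj))
                    st.required.add(obj)
                    new_req = True
        # 4. path choice per required objective
        for obj in sorted(st.required):
            if obj in st.chosen:
                continue
            paths = local_paths(net, obj)
            if not paths:
                raise _Dead()
            if len(paths) == 1:
                _commit_path(st, obj, paths[0])
                new_req = True
                continue
            return ("path", [(obj, p) for p in paths])
        if not new_req:
            return None


class _Dead(Exception):
    pass


def _commit_path(st: _SearchState, obj: Objective, path: LocalPath) -> None:
    st.chosen[obj] = path
    st.edges.add((obj, path))
    for ls in sorted(enab_of_path(path)):
        st.edges.add((path, ls))
        st.locals_.add(ls)


def ua_reach(
    net: AutomataNetwork,
    ctx: Context,
    targets: Iterable[LocalState],
) -> Optional[UAWitness]:
    """Sufficient condition for simultaneously reaching all ``targets``.

    Backtracking search, deterministic order (automata lexicographic,
    context indices ascending, paths by length then step identifiers);
    returns the first witness found, or None.  A witness certifies that
    every ``targets`` local state is reachable -- jointly -- from any global
    state drawn from ``ctx`` that agrees with the witness's chosen states;
    None certifies nothing.
    """
    targets = frozenset(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    ctx.validate(net)
    for ls in targets:
        net._check_local(ls.automaton, ls.index, "target")

    # automata pulled in only through conditions default to 'unconstrained':
    # the witness then fixes a value and is valid for matching states only.
    allowed = {
        a: frozenset(ctx.allowed.get(a, net.automata[a])) for a in net.names
    }
    root = _SearchState(allowed, {}, set(targets), {}, set(), set())

    def search(st: _SearchState) -> Optional[_SearchState]:
        try:
            branch = _saturate(net, st)
        except _Dead:
            return None
        if branch is None:
            if _acyclic(st.edges) and _independence_ok(
                st.chosen, st.edges, targets
            ):
                return st
            return None
        kind, options = branch
        for opt in options:
            st2 = st.clone()
            if kind == "sigma":
                a, i = opt
                st2.sigma[a] = i
            else:
                obj, p = opt
                _commit_path(st2, obj, p)
            result = search(st2)
            if result is not None:
                return result
        return None

    final = search(root)
    if final is None:
        return None
    lcg = LocalCausalityGraph(
        local_state_nodes=set(final.locals_),
        objective_nodes=set(final.required),
        path_nodes=set(final.chosen.values()),
        edges=set(final.edges),
    )
    return UAWitness(
        sub_lcg=lcg,
        chosen_paths=dict(final.chosen),
        context=ctx,
        chosen_states=dict(final.sigma),
        targets=targets,
    )


def validate_ua_witness(net: AutomataNetwork, w: UAWitness) -> None:
    """Independent re-check of every structural clause of a witness.

    Raises AssertionError on the first violated clause.  Used by the test
    suite and safe to call on any returned witness.
    """
    lcg = w.sub_lcg
    lcg.validate()
    # targets present
    for ls in w.targets:
        assert ls in lcg.local_state_nodes, f"target {ls} missing"
    # chosen context states are drawn from the declared context
    for a, i in w.chosen_states.items():
        assert i in w.context.allowed.get(a, net.automata[a]), (
            f"chosen state {a}={i} outside context"
        )
    # every local state has its context objective, with edge
    for ls in lcg.local_state_nodes:
        obj = Objective(ls.automaton, w.chosen_states[ls.automaton], ls.index)
        assert (ls, obj) in lcg.edges, f"missing context objective {obj}"
        assert obj in lcg.objective_nodes
    # every objective node owns exactly one chosen path, edge present,
    # and the path's conditions are all in the graph
    for obj in lcg.objective_nodes:
        assert obj in w.chosen_paths, f"objective {obj} has no chosen path"
        p = w.chosen_paths[obj]
        assert p in local_paths(net, obj), f"{p} does not realize {obj}"
        assert (obj, p) in lcg.edges
        children = [b for a, b in lcg.edges if a == obj]
        assert children == [p] or set(children) == {p}, (
            f"objective {obj} has several path children"
        )
        for ls in enab_of_path(p):
            assert (p, ls) in lcg.edges
            assert ls in lcg.local_state_nodes
    # pair saturation: same-automaton pairs are covered or ordered
    for a_i in lcg.local_state_nodes:
        for a_j in lcg.local_state_nodes:
            if a_i.automaton != a_j.automaton or a_i == a_j:
                continue
            obj = Objective(a_i.automaton, a_i.index, a_j.index)
            assert obj in lcg.objective_nodes or a_j in _conn(lcg.edges, a_i), (
                f"pair {a_i},{a_j} neither covered nor ordered"
            )
    assert _acyclic(lcg.edges), "witness graph is cyclic"
    assert _independence_ok(w.chosen_paths, lcg.edges, w.targets), (
        "dependent required states"
    )


def witness_to_json(w: UAWitness) -> str:
    import json

    return json.dumps(
        {
            "targets": sorted(str(t) for t in w.targets),
            "chosen_states": dict(sorted(w.chosen_states.items())),
            "chosen_paths": {
                str(obj): list(p.step_ids)
                for obj, p in sorted(w.chosen_paths.items())
            },
        },
        indent=2,
    )


def witness_to_dot(w: UAWitness) -> str:
    from .localpaths import lcg_to_dot

    return lcg_to_dot(w.sub_lcg)
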