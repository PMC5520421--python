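"""Local paths and the Local Causality Graph (LCG).

The static analyses decompose a global reachability question into
*objectives* ``a_i ~> a_j`` -- drive automaton ``a`` from local state ``i``
to ``j`` -- realized by *local paths*: acyclic chains of transitions inside
automaton ``a``.  Each local path demands the local states of its enabling
conditions, which recursively raises further objectives in other automata.
The LCG is the tripartite digraph over local states, objectives and local
paths wiring up these dependencies; both the reachability over- and
under-approximation are conditions on sub-graphs of the LCG, whose size is
polynomial in the number of transitions for bounded per-automaton state
counts -- tiny compared to the global state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

from .model import AutomataNetwork, LocalState, LocalTransition

__all__ = [
    "Objective",
    "LocalPath",
    "LocalCausalityGraph",
    "local_paths",
    "enab_of_path",
    "build_lcg",
    "lcg_to_dot",
]


@dataclass(frozen=True, order=True)
class Objective:
    """The task ``a_i ~> a_j`` of driving one automaton between local states."""

    automaton: str
    from_index: int
    to_index: int

    def __str__(self) -> str:
        return f"{self.automaton}_{self.from_index}~>{self.automaton}_{self.to_index}"


@dataclass(frozen=True)
class LocalPath:
    """An acyclic within-automaton realization of an objective.

    Empty exactly when the objective is trivial (``i = j``); otherwise the
    steps chain from ``from_index`` to ``to_index`` without ever re-entering
    a previously used origin.  Two paths are equal iff their step-identifier
    sequences are equal.
    """

    objective: Objective
    steps: tuple[LocalTransition, ...] = ()

    def __post_init__(self) -> None:
        obj = self.objective
        if not self.steps:
            assert obj.from_index == obj.to_index, "empty path on a real move"
            return
        assert self.steps[0].origin == obj.from_index
        assert self.steps[-1].dest == obj.to_index
        for a, b in zip(self.steps, self.steps[1:]):
            assert a.dest == b.origin
        origins = [t.origin for t in self.steps]
        for n in range(len(self.steps)):
            assert all(
                self.steps[n].dest != origins[m] for m in range(n + 1)
            ), "local path revisits a local state"

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def step_ids(self) -> tuple[str, ...]:
        return tuple(t.id for t in self.steps)

    def __str__(self) -> str:
        if not self.steps:
            return f"eps[{self.objective}]"
        return "[" + ";".join(self.step_ids) + "]"


LCGNode = Union[LocalState, Objective, LocalPath]


def enab_of_path(p: LocalPath) -> frozenset[LocalState]:
    """Union of the enabling conditions of the path's steps."""
    out: set[LocalState] = set()
    for t in p.steps:
        out.update(t.condition)
    return frozenset(out)


def local_paths(net: AutomataNetwork, obj: Objective) -> list[LocalPath]:
    """All acyclic local paths realizing ``obj``.

    The trivial objective yields the singleton empty path.  Enumeration is a
    depth-first search over the automaton's transitions (identifier order)
    pruning any step whose destination revisits a used origin, hence every
    path has at most ``|S(a)| - 1`` steps.  Results are cached per network
    and returned sorted by (length, step identifiers).
    """
    cache = net._caches.setdefault("local_paths", {})
    if obj in cache:
        return cache[obj]
    net._check_local(obj.automaton, obj.from_index, str(obj))
    net._check_local(obj.automaton, obj.to_index, str(obj))
    if obj.from_index == obj.to_index:
        result = [LocalPath(obj, ())]
        cache[obj] = result
        return result

    trans = [t for t in net.transitions if t.automaton == obj.automaton]
    result = []

    # `origins` = origins of the steps taken so far (the start counts); a
    # step may never lead back into one of them, which bounds path length
    # by |S(a)| - 1.
    def dfs(path: list[LocalTransition], at: int, origins: set[int]) -> None:
        for t in trans:
            if t.origin != at:
                continue
            if t.dest == obj.to_index:
                result.append(LocalPath(obj, tuple(path + [t])))
            elif t.dest not in origins:
                path.append(t)
                dfs(path, t.dest, origins | {at})
                path.pop()

    dfs([], obj.from_index, {obj.from_index})
    result.sort(key=lambda p: (len(p), p.step_ids))
    cache[obj] = result
    return result


@dataclass
class LocalCausalityGraph:
    """Tripartite digraph over local states, objectives and local paths.

    Edge families (the only three): local state -> each objective ending at
    it; objective -> each of its local paths; local path -> each local state
    of its enabling conditions.
    """

    local_state_nodes: set[LocalState] = field(default_factory=set)
    objective_nodes: set[Objective] = field(default_factory=set)
    path_nodes: set[LocalPath] = field(default_factory=set)
    edges: set[tuple[LCGNode, LCGNode]] = field(default_factory=set)

    def nodes(self) -> list[LCGNode]:
        return (
            list(self.local_state_nodes)
            + list(self.objective_nodes)
            + list(self.path_nodes)
        )

    def children(self, node: LCGNode) -> list[LCGNode]:
        return [b for a, b in self.edges if a == node]

    def validate(self) -> None:
        for a, b in self.edges:
            if isinstance(a, LocalState):
                assert isinstance(b, Objective), "local states point to objectives"
                assert (b.automaton, b.to_index) == (a.automaton, a.index)
            elif isinstance(a, Objective):
                assert isinstance(b, LocalPath) and b.objective == a
            else:
                assert isinstance(a, LocalPath) and isinstance(b, LocalState)
                assert b in enab_of_path(a)


def build_lcg(
    net: AutomataNetwork,
    roots: Iterable[Objective],
    context: Optional[Mapping[str, Iterable[int]]] = None,
) -> LocalCausalityGraph:
    """Construct the LCG restricted to what the root objectives can involve.

    Starting from the root objectives and their target local states, the
    closure follows edge direction: a local state node ``a_j`` spawns the
    objectives ending at ``a_j``, each objective its local paths, each path
    the local states of its conditions.  Without a ``context`` a local state
    spawns objectives from *every* local state of its automaton (the full
    Definition-style graph, reachable part); with a context only objectives
    from the allowed initial indices are spawned, which is the shape used by
    the reachability analyses.
    """
    lcg = LocalCausalityGraph()
    pending_obj: list[Objective] = []
    pending_ls: list[LocalState] = []

    def add_objective(obj: Objective) -> None:
        if obj not in lcg.objective_nodes:
            lcg.objective_nodes.add(obj)
            pending_obj.append(obj)

    def add_local(ls: LocalState) -> None:
        if ls not in lcg.local_state_nodes:
            lcg.local_state_nodes.add(ls)
            pending_ls.append(ls)

    for obj in sorted(set(roots)):
        add_objective(obj)
        add_local(LocalState(obj.automaton, obj.to_index))

    while pending_obj or pending_ls:
        while pending_obj:
            obj = pending_obj.pop()
            for p in local_paths(net, obj):
                lcg.path_nodes.add(p)
                lcg.edges.add((obj, p))
                for ls in sorted(enab_of_path(p)):
                    add_local(ls)
                    lcg.edges.add((p, ls))
        while pending_ls:
            ls = pending_ls.pop()
            if context is not None:
                sources = context.get(ls.automaton, ())
            else:
                sources = net.automata[ls.automaton]
            for i in sorted(sources):
                obj = Objective(ls.automaton, i, ls.index)
                lcg.edges.add((ls, obj))
                add_objective(obj)
    return lcg


def lcg_to_dot(lcg: LocalCausalityGraph) -> str:
    """DOT rendering: boxed local states, plain objectives, small circles
    for local paths."""
    lines = ["digraph lcg {"]
    for ls in sorted(lcg.local_state_nodes):
        lines.append(f'  "{ls}" [shape=box];')
    for obj in sorted(lcg.objective_nodes):
        lines.append(f'  "{obj}" [shape=plaintext];')
    for p in sorted(lcg.path_nodes, key=str):
        lines.append(f'  "{p}" [shape=circle, width=0.2, label=""];')
    for a, b in sorted(lcg.edges, key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
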