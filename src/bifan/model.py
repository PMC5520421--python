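"""Automata-network data model, text format, and asynchronous one-step semantics.

An automata network (AN) is a finite set of finite-state automata whose local
transitions are conditioned on the local states of *other* automata.  A global
state assigns one local state per automaton; the asynchronous semantics applies
exactly one enabled local transition per step.  ANs encode exactly the
asynchronous dynamics of Boolean and multi-valued (Thomas) regulatory networks.

The canonical text format is line-oriented (UTF-8, ``#`` comments)::

    automaton "a" [0, 1, 2]
    "a" 0 -> 1 when "b"=0
    "a" 1 -> 0
    initial "a"=0, "b"=1

Automata are serialized in lexicographic order and transition identifiers
(``t1``, ``t2``, ...) are assigned in file order, so ``serialize -> parse``
round-trips to an identical network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "ANError",
    "ANSyntaxError",
    "ANSemanticError",
    "NotApplicableError",
    "LocalState",
    "LocalTransition",
    "Goal",
    "GlobalState",
    "AutomataNetwork",
    "parse_an",
    "serialize_an",
    "enabled",
    "apply",
    "encode_goal_states",
]


class ANError(Exception):
    """Base class for model errors."""


class ANSyntaxError(ANError):
    """Malformed AN text; carries 1-based line and column."""

    def __init__(self, message: str, line: int, column: int = 1):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class ANSemanticError(ANError):
    """Well-formed text violating a model invariant (undeclared state, ...)."""


class NotApplicableError(ANError):
    """Raised when applying a transition that is not enabled."""


@dataclass(frozen=True, order=True)
class LocalState:
    """A single local state ``a_i`` of one automaton."""

    automaton: str
    index: int

    def __str__(self) -> str:  # e.g. "a_1"
        return f"{self.automaton}_{self.index}"


@dataclass(frozen=True, order=True)
class Goal:
    """A designated goal local state ``g_1``.

    A global state *contains the goal* when its ``automaton`` coordinate
    equals ``index``.
    """

    automaton: str
    index: int

    @classmethod
    def parse(cls, text: str) -> "Goal":
        m = re.fullmatch(r'\s*"?([^"=]+?)"?\s*=\s*(\d+)\s*', text)
        if m is None:
            raise ANSemanticError(f"cannot parse goal specification {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def as_local_state(self) -> LocalState:
        return LocalState(self.automaton, self.index)

    def __str__(self) -> str:
        return f"{self.automaton}={self.index}"


@dataclass(frozen=True)
class LocalTransition:
    """A conditioned local transition ``a_i --ell--> a_j``.

    ``condition`` holds at most one local state per *other* automaton; the
    transition is enabled in a global state ``s`` when ``s(a) = origin`` and
    every condition local state is in ``s``.
    """

    id: str
    automaton: str
    origin: int
    dest: int
    condition: tuple[LocalState, ...] = ()

    def __post_init__(self) -> None:
        if self.origin == self.dest:
            raise ANSemanticError(
                f"transition {self.id}: origin and destination are both "
                f"{self.automaton}_{self.origin}"
            )
        seen = set()
        for ls in self.condition:
            if ls.automaton == self.automaton:
                raise ANSemanticError(
                    f"transition {self.id}: condition on its own automaton "
                    f"{self.automaton!r}"
                )
            if ls.automaton in seen:
                raise ANSemanticError(
                    f"transition {self.id}: two condition states for "
                    f"automaton {ls.automaton!r}"
                )
            seen.add(ls.automaton)
        object.__setattr__(self, "condition", tuple(sorted(self.condition)))

    @property
    def condition_dict(self) -> dict[str, int]:
        return {ls.automaton: ls.index for ls in self.condition}

    def origin_state(self) -> LocalState:
        return LocalState(self.automaton, self.origin)

    def dest_state(self) -> LocalState:
        return LocalState(self.automaton, self.dest)

    def __str__(self) -> str:
        cond = ",".join(str(c) for c in self.condition)
        arrow = f"{self.automaton}_{self.origin} -> {self.automaton}_{self.dest}"
        return f"{self.id}: {arrow}" + (f" when {cond}" if cond else "")


@dataclass(frozen=True, order=True)
class GlobalState:
    """One local state per automaton; hashable and totally ordered.

    ``names`` is the lexicographically sorted tuple of automata identifiers
    (shared across all states of a network) and ``values`` the matching local
    state indices.
    """

    names: tuple[str, ...] = field(compare=False, repr=False)
    values: tuple[int, ...]

    def __getitem__(self, automaton: str) -> int:
        try:
            return self.values[self.names.index(automaton)]
        except ValueError:
            raise KeyError(automaton) from None

    def replace(self, automaton: str, index: int) -> "GlobalState":
        pos = self.names.index(automaton)
        vals = list(self.values)
        vals[pos] = index
        return GlobalState(self.names, tuple(vals))

    def items(self) -> Iterator[tuple[str, int]]:
        return zip(self.names, self.values)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    def __str__(self) -> str:  # canonical "a=0,b=1,c=0"
        return ",".join(f"{a}={i}" for a, i in self.items())


_RE_AUTOMATON = re.compile(r'automaton\s+"([^"]*)"\s*\[([^\]]*)\]\s*$')
_RE_TRANSITION = re.compile(
    r'"([^"]*)"\s+(\d+)\s*->\s*(\d+)\s*(?:when\s+(.*?))?\s*$'
)
_RE_INITIAL = re.compile(r"initial\s+(.*?)\s*$")
_RE_COND_ITEM = re.compile(r'\s*"([^"]*)"\s*=\s*(\d+)\s*$')


class AutomataNetwork:
    """An automata network ``(Sigma, S, T)``.

    ``automata`` maps each automaton identifier to its list of local state
    indices ``0..k-1`` (k >= 2); ``transitions`` is the list of local
    transitions in identifier order.  Automata are kept in lexicographic
    order, which fixes the canonical serialization of global states.
    """

    def __init__(
        self,
        automata: Mapping[str, Sequence[int]],
        transitions: Iterable[LocalTransition] = (),
        declared_initial: Optional[GlobalState] = None,
    ):
        self.automata: dict[str, list[int]] = {
            name: list(automata[name]) for name in sorted(automata)
        }
        self.transitions: list[LocalTransition] = list(transitions)
        self.declared_initial = declared_initial
        self._names = tuple(self.automata)
        self._pos = {name: i for i, name in enumerate(self._names)}
        self.validate()
        # compiled per-transition tables for the hot single-step loop
        self._compiled = [
            (
                self._pos[t.automaton],
                t.origin,
                t.dest,
                tuple((self._pos[c.automaton], c.index) for c in t.condition),
            )
            for t in self.transitions
        ]
        self._caches: dict[str, dict] = {}

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        for name, states in self.automata.items():
            if len(states) < 2:
                raise ANSemanticError(
                    f"automaton {name!r} has {len(states)} local state(s); "
                    "at least 2 are required"
                )
            if states != list(range(len(states))):
                raise ANSemanticError(
                    f"automaton {name!r}: local states must be 0..k-1, got {states}"
                )
        seen_ids: set[str] = set()
        for t in self.transitions:
            if t.id in seen_ids:
                raise ANSemanticError(f"duplicate transition id {t.id!r}")
            seen_ids.add(t.id)
            self._check_local(t.automaton, t.origin, t.id)
            self._check_local(t.automaton, t.dest, t.id)
            for c in t.condition:
                self._check_local(c.automaton, c.index, t.id)
        if self.declared_initial is not None:
            s = self.declared_initial
            if s.names != self._names:
                raise ANSemanticError("initial state does not cover all automata")
            for a, i in s.items():
                self._check_local(a, i, "initial state")

    def _check_local(self, automaton: str, index: int, where: str) -> None:
        if automaton not in self.automata:
            raise ANSemanticError(f"{where}: undeclared automaton {automaton!r}")
        if index not in range(len(self.automata[automaton])):
            raise ANSemanticError(
                f"{where}: undeclared local state {automaton}_{index}"
            )

    # -- states ----------------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def local_states(self) -> list[LocalState]:
        return [
            LocalState(a, i) for a in self._names for i in self.automata[a]
        ]

    def state(self, assignment: Mapping[str, int]) -> GlobalState:
        missing = set(self._names) - set(assignment)
        if missing:
            raise ANSemanticError(f"state misses automata {sorted(missing)}")
        extra = set(assignment) - set(self._names)
        if extra:
            raise ANSemanticError(f"state assigns unknown automata {sorted(extra)}")
        s = GlobalState(self._names, tuple(assignment[a] for a in self._names))
        for a, i in s.items():
            self._check_local(a, i, "state")
        return s

    def parse_state(self, text: str) -> GlobalState:
        """Parse ``"a=0,b=1,c=0"`` into a global state."""
        assignment: dict[str, int] = {}
        for part in text.split(","):
            m = re.fullmatch(r'\s*"?([^"=]+?)"?\s*=\s*(\d+)\s*', part)
            if m is None:
                raise ANSemanticError(f"cannot parse state item {part!r}")
            assignment[m.group(1)] = int(m.group(2))
        return self.state(assignment)

    def transition(self, tid: str) -> LocalTransition:
        for t in self.transitions:
            if t.id == tid:
                return t
        raise KeyError(tid)

    # -- semantics -------------------------------------------------------
    def enabled(self, s: GlobalState) -> list[LocalTransition]:
        """Local transitions applicable in ``s``, in identifier order."""
        vals = s.values
        out = []
        for t, (pos, origin, _dest, cond) in zip(self.transitions, self._compiled):
            if vals[pos] == origin and all(vals[p] == k for p, k in cond):
                out.append(t)
        return out

    def apply(self, s: GlobalState, t: LocalTransition) -> GlobalState:
        pos = self._pos[t.automaton]
        vals = s.values
        if vals[pos] != t.origin or any(
            vals[self._pos[c.automaton]] != c.index for c in t.condition
        ):
            raise NotApplicableError(f"{t} is not applicable in <{s}>")
        new_vals = list(vals)
        new_vals[pos] = t.dest
        return GlobalState(s.names, tuple(new_vals))

    # -- serialization ---------------------------------------------------
    def serialize(self) -> str:
        lines = []
        for name, states in self.automata.items():
            lines.append(
                f'automaton "{name}" [{", ".join(str(i) for i in states)}]'
            )
        for t in self.transitions:
            line = f'"{t.automaton}" {t.origin} -> {t.dest}'
            if t.condition:
                cond = ", ".join(f'"{c.automaton}"={c.index}' for c in t.condition)
                line += f" when {cond}"
            lines.append(line)
        if self.declared_initial is not None:
            pairs = ", ".join(
                f'"{a}"={i}' for a, i in self.declared_initial.items()
            )
            lines.append(f"initial {pairs}")
        return "\n".join(lines) + "\n"

    def copy(self) -> "AutomataNetwork":
        return AutomataNetwork(
            self.automata, self.transitions, self.declared_initial
        )

    def __repr__(self) -> str:
        return (
            f"AutomataNetwork({len(self.automata)} automata, "
            f"{len(self.transitions)} transitions)"
        )


def parse_an(text: str) -> AutomataNetwork:
    """Parse the canonical AN text format.

    Transition identifiers ``t1, t2, ...`` are assigned in file order.
    Syntax errors carry line/column; semantic errors name the offending
    automaton or local state.
    """
    automata: dict[str, list[int]] = {}
    raw_transitions: list[tuple[int, str, int, int, list[LocalState]]] = []
    initial: Optional[dict[str, int]] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("automaton"):
            m = _RE_AUTOMATON.match(line)
            if m is None:
                raise ANSyntaxError("malformed automaton declaration", lineno)
            name = m.group(1)
            if name in automata:
                raise ANSemanticError(
                    f"line {lineno}: duplicate automaton {name!r}"
                )
            body = m.group(2).strip()
            try:
                states = [int(x) for x in body.split(",")] if body else []
            except ValueError:
                raise ANSyntaxError(
                    "state list must be comma-separated integers",
                    lineno,
                    line.index("[") + 2,
                ) from None
            automata[name] = states
        elif line.startswith("initial"):
            m = _RE_INITIAL.match(line)
            if m is None:
                raise ANSyntaxError("malformed initial declaration", lineno)
            initial = {}
            for item in m.group(1).split(","):
                mi = _RE_COND_ITEM.match(item)
                if mi is None:
                    raise ANSyntaxError(
                        f"malformed initial item {item.strip()!r}", lineno
                    )
                initial[mi.group(1)] = int(mi.group(2))
        elif line.startswith('"'):
            m = _RE_TRANSITION.match(line)
            if m is None:
                raise ANSyntaxError("malformed transition", lineno)
            name, i, j = m.group(1), int(m.group(2)), int(m.group(3))
            cond: list[LocalState] = []
            if m.group(4):
                for item in m.group(4).split(","):
                    mi = _RE_COND_ITEM.match(item)
                    if mi is None:
                        raise ANSyntaxError(
                            f"malformed condition item {item.strip()!r}", lineno
                        )
                    cond.append(LocalState(mi.group(1), int(mi.group(2))))
            raw_transitions.append((lineno, name, i, j, cond))
        else:
            raise ANSyntaxError(f"unrecognized statement {line!r}", lineno)

    transitions = []
    for n, (lineno, name, i, j, cond) in enumerate(raw_transitions, start=1):
        try:
            transitions.append(
                LocalTransition(f"t{n}", name, i, j, tuple(cond))
            )
        except ANSemanticError as e:
            raise ANSemanticError(f"line {lineno}: {e}") from None

    net_initial = None
    net = AutomataNetwork(automata, transitions)
    if initial is not None:
        net_initial = net.state(initial)
        net = AutomataNetwork(automata, transitions, net_initial)
    return net


def serialize_an(net: AutomataNetwork) -> str:
    return net.serialize()


def enabled(net: AutomataNetwork, s: GlobalState) -> list[LocalTransition]:
    """Transitions applicable in ``s`` (one-step asynchronous semantics)."""
    return net.enabled(s)


def apply(net: AutomataNetwork, s: GlobalState, t: LocalTransition) -> GlobalState:
    """Apply one enabled local transition; changes exactly one coordinate."""
    return net.apply(s, t)


def encode_goal_states(
    net: AutomataNetwork,
    targets: Iterable[Mapping[str, int]],
    name: Optional[str] = None,
) -> tuple[AutomataNetwork, Goal]:
    """Encode a set of (partial) goal states as a single goal local state.

    Returns a copy of ``net`` extended with a fresh 2-state automaton ``g``
    (initially 0) and, per target assignment, one transition ``g: 0 -> 1``
    conditioned by that assignment.  Reaching any target state then flips
    ``g`` to 1, so the returned ``Goal`` ``(g, 1)`` captures the disjunction
    of the targets.  With no targets, ``g=1`` is unreachable.
    """
    if name is None:
        name = "goal"
        n = 1
        while name in net.automata:
            n += 1
            name = f"goal{n}"
    elif name in net.automata:
        raise ANSemanticError(f"goal automaton name {name!r} already declared")

    automata = {a: list(v) for a, v in net.automata.items()}
    automata[name] = [0, 1]
    transitions = list(net.transitions)
    next_id = len(transitions) + 1
    for target in targets:
        cond = tuple(LocalState(a, i) for a, i in sorted(target.items()))
        for c in cond:
            net._check_local(c.automaton, c.index, "goal target")
        transitions.append(
            LocalTransition(f"t{next_id}", name, 0, 1, cond)
        )
        next_id += 1
    initial = None
    extended = AutomataNetwork(automata, transitions)
    if net.declared_initial is not None:
        assignment = net.declared_initial.to_dict()
        assignment[name] = 0
        initial = extended.state(assignment)
        extended = AutomataNetwork(automata, transitions, initial)
    return extended, Goal(name, 1)
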