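"""Built-in models and a seeded random network generator.

Every property of the package is testable without external model files: the
three-automaton worked example ships as text, and `random_an` produces
arbitrary valid networks deterministically from a seed.  The test corpus
(200 networks, 2-5 automata with 2-3 local states each, 1-4 transitions per
automaton, condition sizes 0-2) is built by `corpus` and pinned in the
repository; the generator is the single source of randomness and is driven
exclusively by explicit integer seeds.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from typing import Iterator, Optional

from .model import (
    ANSemanticError,
    AutomataNetwork,
    GlobalState,
    Goal,
    LocalState,
    LocalTransition,
    parse_an,
)

__all__ = ["GeneratorConfig", "random_an", "builtin", "corpus", "FIG1_AN"]

# Three automata a/b/c; from <a0,b0,c0> the goal a2 is reachable until the
# c1 -> c2 transition (t8) fires, which is the unique bifurcation transition.
FIG1_AN = '''\
automaton "a" [0, 1, 2]
automaton "b" [0, 1]
automaton "c" [0, 1, 2]
"a" 1 -> 0
"a" 0 -> 1 when "b"=0
"a" 0 -> 2 when "b"=0, "c"=0
"b" 0 -> 1
"b" 1 -> 0 when "a"=0
"c" 0 -> 1 when "a"=1
"c" 1 -> 0 when "b"=1
"c" 1 -> 2 when "b"=0
initial "a"=0, "b"=0, "c"=0
'''


def builtin(name: str) -> tuple[AutomataNetwork, GlobalState, Goal]:
    """Return a named built-in instance ``(network, initial state, goal)``."""
    if name == "fig1":
        net = parse_an(FIG1_AN)
        assert net.declared_initial is not None
        return net, net.declared_initial, Goal("a", 2)
    raise KeyError(f"unknown builtin model {name!r}")


def _automaton_names(n: int) -> list[str]:
    letters = string.ascii_lowercase
    names = []
    for i in range(n):
        if i < len(letters):
            names.append(letters[i])
        else:
            names.append(letters[i % len(letters)] + str(i // len(letters)))
    return names


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random network generator.

    Ranges are inclusive ``(low, high)`` pairs.  ``condition_size`` counts
    local states drawn from *other* automata, so its lower bound must not
    exceed ``n_automata - 1``; sampled sizes are clamped to that many.
    """

    n_automata: int = 3
    states_per_automaton: tuple[int, int] = (2, 3)
    transitions_per_automaton: tuple[int, int] = (1, 4)
    condition_size: tuple[int, int] = (0, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_automata < 2:
            raise ValueError("need at least 2 automata")
        for lo, hi in (
            self.states_per_automaton,
            self.transitions_per_automaton,
            self.condition_size,
        ):
            if lo > hi or lo < 0:
                raise ValueError(f"empty range ({lo}, {hi})")
        if self.states_per_automaton[0] < 2:
            raise ValueError("automata need at least 2 local states")
        if self.condition_size[0] > self.n_automata - 1:
            raise ValueError(
                "condition_size lower bound exceeds the number of other automata"
            )


def random_an(cfg: GeneratorConfig) -> AutomataNetwork:
    """Generate a valid network, deterministically for a fixed seed.

    Conditions are drawn only from other automata, with at most one local
    state per automaton; origin and destination always differ.  A random
    total state is declared as initial.
    """
    rng = random.Random(cfg.seed)
    names = _automaton_names(cfg.n_automata)
    automata = {
        name: list(range(rng.randint(*cfg.states_per_automaton)))
        for name in names
    }
    transitions: list[LocalTransition] = []
    tid = 0
    for name in names:
        k = len(automata[name])
        others = [o for o in names if o != name]
        for _ in range(rng.randint(*cfg.transitions_per_automaton)):
            origin = rng.randrange(k)
            dest = rng.choice([i for i in range(k) if i != origin])
            size = min(rng.randint(*cfg.condition_size), len(others))
            cond = tuple(
                LocalState(o, rng.randrange(len(automata[o])))
                for o in sorted(rng.sample(others, size))
            )
            tid += 1
            transitions.append(LocalTransition(f"t{tid}", name, origin, dest, cond))
    net = AutomataNetwork(automata, transitions)
    initial = net.state({a: rng.randrange(len(automata[a])) for a in names})
    return AutomataNetwork(automata, transitions, initial)


def corpus(
    count: int = 200, seed: int = 0
) -> Iterator[tuple[AutomataNetwork, GlobalState, Goal]]:
    """Yield ``count`` random instances ``(network, initial state, goal)``.

    Network shapes cycle through 2-5 automata; the goal is a random declared
    local state (sometimes trivially present in, or unreachable from, the
    initial state -- both are meaningful queries).
    """
    for i in range(count):
        inst_seed = seed * 1_000_003 + i
        cfg = GeneratorConfig(
            n_automata=2 + i % 4,
            states_per_automaton=(2, 3),
            transitions_per_automaton=(1, 4),
            condition_size=(0, 2),
            seed=inst_seed,
        )
        net = random_an(cfg)
        rng = random.Random(inst_seed + 500_000_011)
        name = rng.choice(net.names)
        goal = Goal(name, rng.randrange(len(net.automata[name])))
        assert net.declared_initial is not None
        yield net, net.declared_initial, goal


def dump_corpus(count: int = 200, seed: int = 0) -> str:
    """Serialize the corpus to one pinned text blob (see tests/data)."""
    parts = []
    for i, (net, s0, goal) in enumerate(corpus(count, seed)):
        parts.append(f"# === instance {i} goal {goal} ===")
        parts.append(net.serialize().rstrip("\n"))
    return "\n".join(parts) + "\n"


def load_corpus(text: str) -> Iterator[tuple[AutomataNetwork, GlobalState, Goal]]:
    """Parse a blob produced by `dump_corpus`."""
    header: Optional[str] = None
    chunk: list[str] = []
    entries: list[tuple[str, str]] = []
    for line in text.splitlines():
        if line.startswith("# ==="):
            if header is not None:
                entries.append((header, "\n".join(chunk)))
            header, chunk = line, []
        else:
            chunk.append(line)
    if header is not None:
        entries.append((header, "\n".join(chunk)))
    for header, body in entries:
        goal = Goal.parse(header.split("goal", 1)[1].strip(" ="))
        net = parse_an(body)
        if net.declared_initial is None:
            raise ANSemanticError("corpus entry misses an initial state")
        yield net, net.declared_initial, goal
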