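"""Encoding Boolean networks as automata networks.

Input is the tabular ``targets, factors`` text form: one row per node with a
Boolean update function over node names (operators ``&``, ``|``, ``!``,
parentheses, literals ``0``/``1``).  Each node becomes a 2-state automaton;
for node ``x`` with function ``f``, the encoding emits one transition
``x: 0 -> 1`` per prime implicant of ``f`` restricted to ``x=0``, and one
``x: 1 -> 0`` per prime implicant of ``!f`` restricted to ``x=1``.  The
restriction removes ``x`` from its own conditions (the model forbids
self-conditions), and the union of all prime implicants equals the
restricted function exactly, so the asynchronous state graph of the
encoding coincides with the Boolean network's.

All prime implicants are computed by truth-table expansion and iterated
merging, ordered deterministically by literal count then lexicographically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import Callable, Mapping, Optional

from .model import ANSemanticError, ANSyntaxError, AutomataNetwork, LocalState, LocalTransition

__all__ = ["encode_boolean_network", "parse_boolean_expression", "prime_implicants"]

_TOKEN = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_.-]*)|(?P<op>[&|!()])|(?P<const>[01]))")


@dataclass(frozen=True)
class _Expr:
    """Parsed Boolean expression: an evaluator plus its syntactic support."""

    fn: Callable[[Mapping[str, int]], bool]
    support: frozenset[str]

    def __call__(self, env: Mapping[str, int]) -> bool:
        return self.fn(env)


def parse_boolean_expression(text: str) -> _Expr:
    """Recursive-descent parser; precedence ``!`` > ``&`` > ``|``."""
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        if text[pos:].strip() == "":
            break
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ANSyntaxError(
                f"unexpected character {text[pos]!r} in expression", 1, pos + 1
            )
        pos = m.end()
        for kind in ("name", "op", "const"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
    idx = 0

    def peek() -> Optional[tuple[str, str]]:
        return tokens[idx] if idx < len(tokens) else None

    def take() -> tuple[str, str]:
        nonlocal idx
        tok = tokens[idx]
        idx += 1
        return tok

    def parse_or() -> _Expr:
        left = parse_and()
        while peek() == ("op", "|"):
            take()
            right = parse_and()
            lf, rf = left.fn, right.fn
            left = _Expr(
                lambda env, lf=lf, rf=rf: lf(env) or rf(env),
                left.support | right.support,
            )
        return left

    def parse_and() -> _Expr:
        left = parse_not()
        while peek() == ("op", "&"):
            take()
            right = parse_not()
            lf, rf = left.fn, right.fn
            left = _Expr(
                lambda env, lf=lf, rf=rf: lf(env) and rf(env),
                left.support | right.support,
            )
        return left

    def parse_not() -> _Expr:
        if peek() == ("op", "!"):
            take()
            inner = parse_not()
            f = inner.fn
            return _Expr(lambda env, f=f: not f(env), inner.support)
        return parse_atom()

    def parse_atom() -> _Expr:
        tok = peek()
        if tok is None:
            raise ANSyntaxError("unexpected end of expression", 1, len(text))
        kind, value = take()
        if kind == "const":
            bit = value == "1"
            return _Expr(lambda env, bit=bit: bit, frozenset())
        if kind == "name":
            return _Expr(lambda env, value=value: bool(env[value]), frozenset([value]))
        if (kind, value) == ("op", "("):
            inner = parse_or()
            if peek() != ("op", ")"):
                raise ANSyntaxError("missing closing parenthesis", 1, len(text))
            take()
            return inner
        raise ANSyntaxError(f"unexpected token {value!r}", 1, 1)

    expr = parse_or()
    if idx != len(tokens):
        raise ANSyntaxError(f"trailing tokens after expression", 1, 1)
    return expr


def prime_implicants(
    fn: Callable[[Mapping[str, int]], bool], variables: list[str]
) -> list[dict[str, int]]:
    """All prime implicants of ``fn`` over ``variables``.

    Truth-table expansion followed by iterated pairwise merging of
    implicants differing in exactly one literal; implicants absorbed by a
    merge are dropped, survivors are prime.  A tautology yields the single
    empty implicant; an unsatisfiable function yields none.  Deterministic
    order: literal count, then lexicographic on (variable, value) pairs.
    """
    variables = sorted(variables)
    minterms = [
        dict(zip(variables, bits))
        for bits in product((0, 1), repeat=len(variables))
        if fn(dict(zip(variables, bits)))
    ]
    if not variables:
        return [{}] if fn({}) else []
    current = {tuple(sorted(m.items())) for m in minterms}
    primes: set[tuple] = set()
    while current:
        merged_from: set[tuple] = set()
        nxt: set[tuple] = set()
        items = sorted(current)
        for i, a in enumerate(items):
            for b in items[i + 1 :]:
                da, db = dict(a), dict(b)
                if set(da) != set(db):
                    continue
                diff = [v for v in da if da[v] != db[v]]
                if len(diff) == 1:
                    m = dict(da)
                    del m[diff[0]]
                    nxt.add(tuple(sorted(m.items())))
                    merged_from.add(a)
                    merged_from.add(b)
        primes.update(current - merged_from)
        current = nxt
    out = [dict(p) for p in primes]
    out.sort(key=lambda d: (len(d), sorted(d.items())))
    return out


def encode_boolean_network(text: str) -> AutomataNetwork:
    """Parse a ``targets, factors`` table and encode it as an AN.

    Each node gets a 2-state automaton (0 inactive, 1 active); transitions
    are generated per prime implicant of the update function restricted to
    the opposite value of the node itself, so ``|origin - dest| = 1`` and no
    node conditions its own transitions.  Rows are processed in file order,
    nodes serialized lexicographically; unknown names in factor expressions
    are rejected.
    """
    rows: list[tuple[str, _Expr]] = []
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if not re.fullmatch(r"targets\s*,\s*factors", line, re.IGNORECASE):
                raise ANSyntaxError('expected header "targets, factors"', lineno)
            header_seen = True
            continue
        if "," not in line:
            raise ANSyntaxError("expected '<node>, <expression>'", lineno)
        name, expr_text = line.split(",", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.-]*", name):
            raise ANSyntaxError(f"invalid node name {name!r}", lineno)
        rows.append((name, parse_boolean_expression(expr_text)))
    if not header_seen:
        raise ANSyntaxError('missing header "targets, factors"', 1)

    nodes = [name for name, _ in rows]
    if len(set(nodes)) != len(nodes):
        dup = sorted({n for n in nodes if nodes.count(n) > 1})
        raise ANSemanticError(f"duplicate node rows: {dup}")
    declared = set(nodes)
    for name, expr in rows:
        unknown = expr.support - declared
        if unknown:
            raise ANSemanticError(
                f"node {name!r}: unknown node(s) {sorted(unknown)} in factors"
            )

    automata = {name: [0, 1] for name in nodes}
    transitions: list[LocalTransition] = []
    tid = 0
    for name in sorted(nodes):
        expr = dict(rows)[name]
        others = sorted(expr.support - {name})
        for origin, dest, polarity in ((0, 1, True), (1, 0, False)):
            # restrict f to the node's current value, then take f or !f
            def restricted(env: Mapping[str, int], origin=origin, polarity=polarity):
                full = dict(env)
                full[name] = origin
                value = expr(full)
                return value if polarity else not value

            for implicant in prime_implicants(restricted, others):
                tid += 1
                cond = tuple(
                    LocalState(v, k) for v, k in sorted(implicant.items())
                )
                transitions.append(
                    LocalTransition(f"t{tid}", name, origin, dest, cond)
                )
    return AutomataNetwork(automata, transitions)
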