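"""Approximate bifurcation identification.

The exact characterization -- ``t_b`` is a bifurcation transition iff some
state ``s_b`` satisfies (C1) the goal is unreachable from ``s_u = s_b.t_b``,
(C2) the goal is reachable from ``s_b``, (C3) ``s_b`` is reachable from the
initial state -- requires exact reachability checks, PSPACE-complete in
general.  The approximate pipeline relaxes each condition one-sidedly:

* (I1#)  the over-approximation *denies* goal reachability from ``s_u``
         (implies C1);
* (I2#)  an under-approximation witness certifies goal reachability from
         ``s_b`` (implies C2);
* (I3)   ``s_b`` belongs to the explicitly computed reachable set from
         ``s0`` (equivalent to C3), or
* (I3#)  an under-approximation witness certifies simultaneous reachability
         of all coordinates of ``s_b`` from ``s0`` (implies C3; scales to
         models whose reachable set is intractable).

Every reported transition therefore is a true bifurcation transition (no
false positives); the approximations may miss some (false negatives).
"""

from __future__ import annotations

import time
from itertools import product
from typing import Optional

from .model import AutomataNetwork, GlobalState, Goal, LocalState, LocalTransition
from .reach import Context, oa_reach, ua_reach
from .statespace import (
    DEFAULT_STATE_CAP,
    BifurcationResult,
    exact_bifurcations,
    reachable_graph,
)

__all__ = ["find_bifurcations", "classify_modes", "results_to_tsv"]

MODES = ("I3", "I3sharp")


def _candidate_states(
    net: AutomataNetwork, t: LocalTransition
) -> tuple[dict[str, int], list[str]]:
    """Post-state coordinates forced by ``t`` and the free automata.

    ``s_u`` must carry the transition's destination and all its condition
    states; ``s_b`` is ``s_u`` with the transition's automaton reset to the
    origin.  Remaining automata are free and enumerated by the caller.
    """
    fixed_u = {t.automaton: t.dest}
    fixed_u.update(t.condition_dict)
    free = [a for a in net.names if a not in fixed_u]
    return fixed_u, free


def find_bifurcations(
    net: AutomataNetwork,
    s0: GlobalState,
    goal: Goal,
    mode: str = "I3",
    state_cap: int = DEFAULT_STATE_CAP,
    all_witnesses: bool = False,
) -> list[BifurcationResult]:
    """Sound, incomplete bifurcation identification via (I1#), (I2#), (I3/I3#).

    For each local transition, free automata assignments are enumerated
    (deterministically) and the cheap necessary-condition fixpoint (I1#) is
    evaluated before the expensive witness searches.  A transition is
    reported once with the first accepting ``(s_b, s_u)`` pair, or with all
    of them when ``all_witnesses`` is set.  The result is always a subset
    of `exact_bifurcations`.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    net._check_local(goal.automaton, goal.index, "goal")
    reach_set: Optional[set[GlobalState]] = None
    if mode == "I3":
        reach_set = reachable_graph(net, s0, state_cap).states

    results: list[BifurcationResult] = []
    for t in net.transitions:
        fixed_u, free = _candidate_states(net, t)
        # the transition must be able to fire: origin must not clash with a
        # condition on its own automaton (excluded by the model invariants)
        witnesses: list[tuple[GlobalState, GlobalState]] = []
        domains = [net.automata[a] for a in free]
        for values in product(*domains):
            assignment = dict(fixed_u)
            assignment.update(zip(free, values))
            s_u = net.state(assignment)
            if s_u[goal.automaton] == goal.index:
                continue  # the post-state must not already contain the goal
            s_b = s_u.replace(t.automaton, t.origin)
            # (I1#): the necessary condition must deny the goal from s_u
            if oa_reach(net, s_u, goal).decision:
                continue
            # (I2#): certify the goal from s_b
            if (
                ua_reach(
                    net,
                    Context.from_state(s_b),
                    [goal.as_local_state()],
                )
                is None
            ):
                continue
            # (I3)/(I3#): certify s_b reachable from s0
            if reach_set is not None:
                if s_b not in reach_set:
                    continue
            else:
                targets = [LocalState(a, i) for a, i in s_b.items()]
                if ua_reach(net, Context.from_state(s0), targets) is None:
                    continue
            witnesses.append((s_b, s_u))
            if not all_witnesses:
                break
        if witnesses:
            results.append(BifurcationResult(t.id, witnesses, mode))
    return results


def classify_modes(
    net: AutomataNetwork,
    s0: GlobalState,
    goal: Goal,
    state_cap: int = DEFAULT_STATE_CAP,
) -> dict:
    """Run every available method and report per-method sets and timings.

    The exact method is omitted (with a note) when the reachable state set
    exceeds ``state_cap``; the approximate methods are always run.  Timings
    are wall-clock seconds and informational only.
    """
    report: dict = {"goal": str(goal), "initial": str(s0), "methods": {}}
    sets: dict[str, list[str]] = {}

    def run(name: str, fn) -> None:
        start = time.perf_counter()
        try:
            res = fn()
        except Exception as e:  # state cap, typically
            report["methods"][name] = {"error": str(e)}
            return
        elapsed = time.perf_counter() - start
        tids = [r.transition for r in res]
        sets[name] = tids
        report["methods"][name] = {
            "transitions": tids,
            "count": len(tids),
            "time_s": round(elapsed, 6),
        }

    run("exact", lambda: exact_bifurcations(net, s0, goal, state_cap))
    run("I3", lambda: find_bifurcations(net, s0, goal, "I3", state_cap))
    run("I3sharp", lambda: find_bifurcations(net, s0, goal, "I3sharp", state_cap))

    if "exact" in sets:
        for name in ("I3", "I3sharp"):
            if name in sets:
                report["methods"][name]["missed_vs_exact"] = sorted(
                    set(sets["exact"]) - set(sets[name])
                )
    return report


def results_to_tsv(net: AutomataNetwork, results: list[BifurcationResult]) -> str:
    lines = ["transition\tautomaton\torigin\tdest\tcondition\tmethod\twitness_s_b\twitness_s_u"]
    for r in results:
        t = net.transition(r.transition)
        cond = ",".join(f"{a}={i}" for a, i in sorted(t.condition_dict.items()))
        first = (r.witnesses or [(None, None)])[0]
        sb = str(first[0]) if first[0] is not None else ""
        su = str(first[1]) if first[1] is not None else ""
        lines.append(
            f"{t.id}\t{t.automaton}\t{t.origin}\t{t.dest}\t{cond}\t{r.method}\t{sb}\t{su}"
        )
    return "\n".join(lines) + "\n"
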