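# bifan — bifurcation transitions in asynchronous automata networks

`bifan` identifies the *decisive* transitions of a discrete regulatory-network
model: the local transitions whose occurrence irreversibly removes the ability
to reach a goal local state.  In models of cellular differentiation these are
the steps that commit the system to one lineage and forfeit another, so they
point directly at the entities and interactions that control a fate decision.
The package is for modellers working with Boolean, multi-valued (Thomas), or
general automata-network models of signalling and gene regulatory networks.

## The model and the problem

An **automata network** (AN) is a tuple (Σ, S, T): a finite set Σ of finite
automata, each with local states S(a) = {0,…,k−1}, and local transitions
t = a_i —ℓ→ a_j (i ≠ j) whose enabling condition ℓ holds at most one local
state of each *other* automaton.  A global state s assigns one local state per
automaton; under the **asynchronous semantics** one enabled transition fires
at a time (s · t replaces only the a-coordinate), and competing transitions
are resolved non-deterministically.  Asynchronous Boolean and Thomas networks
are encoded exactly in this class.

Given an initial state s₀ and a goal local state g₁, a **bifurcation
transition** t_b is a local transition with global states s_b, s_u = s_b · t_b
such that

1. s₀ →\* s_b (the bifurcation state is reachable),
2. s_b →\* g₁ (the goal is still reachable before the step),
3. s_u ↛\* g₁ (the goal is unreachable after it).

On the explicit state graph these are exactly the edges that leave the set of
goal-connected states, which yields the **exact method**: build reach(s₀),
take the backward closure of the goal states, report the crossing edges.
Sound and complete, but the state graph is exponential in |Σ|.

The **approximate method** replaces the reachability checks by static
analyses over the *Local Causality Graph* (LCG) — a tripartite digraph over
local states, *objectives* a_i ↝ a_j, and their acyclic *local paths*, whose
size is polynomial in |T| for bounded automata:

* **(I1#)** ¬OA(s_u →\* g₁): a least-fixpoint *necessary* condition
  (over-approximation) must *deny* the goal from s_u;
* **(I2#)** UA(s_b →\* g₁): an acyclic sub-LCG witness (*sufficient*
  condition, under-approximation) must *certify* the goal from s_b;
* **(I3)** s_b ∈ reach(s₀) (explicit set membership), or
  **(I3#)** UA(s₀ →\* s_b) — fully static, scales to models whose state space
  is intractable.

Since UA ⇒ truth ⇒ OA, every reported transition is a true bifurcation
transition (**no false positives**); some may be missed (false negatives).
Candidates (t_b, s_b, s_u) are enumerated by a deterministic backtracking
search with the cheap fixpoint test applied first.

## Worked example

The built-in three-automaton model (automata `a`, `b`, `c`, 8 local
transitions, initial state ⟨a0,b0,c0⟩, goal `a=2`):

```
$ python examples/worked_example.py
model: 3 automata, 8 local transitions
initial state <a=0,b=0,c=0>, goal a=2

transitions enabled in <a=0,b=0,c=0>: ['t2', 't3', 't4']
applying t4 (b: 0->1, unconditioned) yields <a=0,b=1,c=0>

reachable states: 14; goal-connected: 10
attractor 0 (goal-free): a=0,b=0,c=2 | a=0,b=1,c=2 | a=1,b=0,c=2 | a=1,b=1,c=2
attractor 1 (goal): a=2,b=1,c=0

exact bifurcations (edges leaving the goal-connected set):
  t8: c_1 -> c_2 when b_0  with 2 witness pair(s), e.g. <a=1,b=0,c=1> -> <a=1,b=0,c=2>
method exact   : ['t8']
method I3      : ['t8']
method I3sharp : ['t8']
```

Three of the eight transitions are enabled initially; 14 global states are
reachable, 10 of which can still reach the goal.  The four states with `c=2`
form a goal-free attractor, and the unique transition whose firing crosses
into it is `t8` (`c: 1 -> 2 when b=0`) — found identically by the exact
method and by both approximate modes.  The other examples show the static
analyses in isolation (`examples/static_analysis.py`) and the Boolean-network
front end (`examples/boolean_network.py`).

The same analyses are available from the shell:

```
$ bifan bifurcations model.an --initial "a=0,b=0,c=0" --goal "a=2" --method i3 --json
$ bifan attractors model.an
$ bifan oa model.an --initial "a=1,b=0,c=2" --goal "a=2"
$ bifan gen-random --n-automata 4 --seed 7
```

Subcommands: `parse`, `encode-bn`, `reach`, `attractors`, `local-paths`,
`oa`, `ua`, `bifurcations`, `gen-random`.  Goal *states* (partial
assignments) are supported via `--goal-states "CI=2,Cro=0;CI=2,CII=1"`,
which transparently adds a fresh 2-state goal automaton.

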