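# Methods

## Scope and model class

`bifan` analyses finite asynchronous automata networks (ANs).  Each automaton
holds one local state; a local transition rewrites one automaton's state and
may be conditioned on at most one local state of each other automaton; one
transition fires per step, chosen non-deterministically.  This class captures
exactly the asynchronous semantics of Boolean and multi-valued (Thomas)
regulatory networks, which is the intended application domain: qualitative
models of signalling and gene regulation in which attractors represent
phenotypes and goal local states represent markers of interest.

A *bifurcation transition* for an initial state s₀ and goal local state g₁ is
a local transition t_b with a reachable pre-state s_b from which the goal is
reachable, while it is not from s_u = s_b·t_b.  Identifying these transitions
explains *where and how* the dynamics exits the basin of the goal; it is
deliberately distinct from intervention/cut-set prediction, which asks what
to perturb rather than what the unperturbed system does.

## Exact method

`reachable_graph` performs a breadth-first closure of s₀ under the one-step
semantics (deterministic: discovery order by transition identifier).
`goal_connected` is the backward closure of the goal states inside that
graph; the reachability relation is reflexive, so a state containing the
goal is goal-connected — no special-casing of goals present in s₀.
`exact_bifurcations` reports every transition labelling an edge from a
goal-connected state to a non-goal-connected one, with all crossing edges as
witness pairs.  Attractors are the terminal strongly connected components of
the reachable graph (SCCs via networkx condensation; terminal = no outgoing
component edge).  The default `state_cap` is 1,000,000 states; exceeding it
raises `StateCapExceeded`, the signal to switch to the approximate pipeline.

## Static approximations

Both approximations work on the Local Causality Graph (LCG) built from
*objectives* a_i↝a_j and their *local paths* (acyclic within-automaton
transition chains; the trivial objective owns the empty path).  Local paths
are enumerated by depth-first search pruning any step whose destination
revisits a used origin, so paths have at most |S(a)|−1 steps; enumeration
order is deterministic (length, then step identifiers) and cached per
network.  The LCG is built lazily from the queried roots; the full graph
over all objectives is available but not the default, keeping memory
proportional to what a query actually touches.

**Over-approximation (necessary).**  From a state s, the set Ω of
*plausible* objectives is the least fixpoint of

    F(Ω) = { a_i↝a_j | ∃ τ ∈ local-paths(a_i↝a_j) :
             ∀ b_k ∈ enab(τ), s(b)↝b_k ∈ Ω }

computed by chaotic iteration restricted to the objectives reachable from
the root s(g)↝g₁ (sound: F consults only those).  decision = root ∈ Ω; a
negative decision proves non-reachability.

**Under-approximation (sufficient).**  A witness is an acyclic sub-LCG in
which: the target local states hang under a (virtual) root; one context
index per involved automaton is fixed (from the allowed context sets);
every local state node carries the objective from its automaton's chosen
context index; every included objective owns exactly one chosen local path;
every path node carries all its condition states; and jointly required
state groups satisfy an independence condition.  The search is backtracking
over (context-index choice per automaton, path choice per objective), with
forced choices propagated eagerly, in deterministic order (automata
lexicographic, indices ascending, paths by length then step identifiers);
the first witness is returned and re-validated by an independent structural
checker.  Checking a candidate is linear in its size; the search is the NP
part.

Two clauses of the witness condition were genuinely open design points and
are fixed as follows, as this package's own reading:

* *Same-automaton saturation with ordering.*  When two local states a_i,
  a_j of one automaton both occur in the witness, the objective a_i↝a_j is
  required **unless a_i is an ancestor of a_j** in the acyclic witness
  graph.  Descendants are established strictly before their ancestors, so
  when a_j is first needed the automaton can only be at its context index,
  at a descendant, or at an incomparable state — and objectives from all of
  those are required (both directions for incomparable pairs).  The naive
  all-pairs rule is provably too strong (it demands objectives with no
  local paths in elementary certifiable cases); the no-saturation rule is
  unsound.
* *Independence of jointly required states.*  For every chosen-path step,
  and for the root's target group (which must hold simultaneously), at most
  one required state a_i may be *interfered with*, i.e. some other state of
  the group is connected, inside the witness, to a local state of automaton
  a other than a_i.  The interfered state can then be established last.
  The weaker per-group reading that flags a_i only when *every* other
  member interferes was tested and found unsound for groups of three or
  more (mutual interference hides behind a harmless third member), so the
  existential reading is used; both coincide for groups of at most two.

Soundness of the resulting one-sided tests is enforced empirically in the
test suite: on the full 200-network corpus and every (reachable state,
goal) query, UA-witness ⇒ exhaustive-oracle reachability ⇒ OA-accepts, and
any returned witness re-validates structurally.  Completeness is *not*
claimed in either direction, matching the one-sided design.

## Approximate bifurcation search

For each transition t the candidate post-state s_u carries dest(t) and
enab(t); the remaining automata are enumerated (product of their domains,
deterministic order), and s_b is s_u with t's automaton reset to orig(t).
Filters run cheapest-first:

1. s_u(g) ≠ g₁ (an explicit guard: the post-state must not itself contain
   the goal);
2. (I1#) the over-approximation must deny g₁ from s_u;
3. (I2#) the under-approximation must certify g₁ from s_b (singleton
   context at s_b — with total candidate states this enumeration is
   result-equivalent to searching over a free-automata context, and keeps
   (I1#), which needs a total s_u, aligned with (I2#));
4. (I3) s_b ∈ reach(s₀) (explicit membership — the reachable state *set*
   equals by definition the set a partial-order prefix would represent, so
   explicit enumeration is used as the membership test; prefix construction
   is an optimisation, not a semantic difference), or (I3#) the
   under-approximation must certify simultaneous reachability of all |Σ|
   coordinates of s_b from s₀.

A transition is reported once with its first accepting witness pair
(`all_witnesses` enumerates them all).  Mode I3 is exact in condition (3)
and so misses fewer transitions; mode I3# is fully static and scales past
intractable state spaces.  No ordering between the two modes' result sizes
is asserted — only that each is a subset of the exact result, which the
corpus tests check instance by instance along with witness validity.

## Boolean-network encoding

The `targets, factors` table maps each node x with update function f to a
2-state automaton: one transition x:0→1 per prime implicant of f restricted
to x=0, one x:1→0 per prime implicant of ¬f restricted to x=1.  The
restriction removes x from its own conditions (self-conditions are illegal
in the model); all prime implicants are emitted (truth-table expansion and
iterated merging, ordered by literal count then lexicographically).  The
union of all prime implicants equals the restricted function exactly, so
the encoding's asynchronous state graph coincides with the Boolean
network's — verified in tests against an independent truth-table evaluator
on random networks of up to 4 nodes.  Redundant consensus implicants can
produce semantically subsumed duplicate transitions; this is harmless for
the dynamics and keeps the emitted condition set canonical.  Goal *states*
(partial assignments) are encoded by a fresh 2-state goal automaton with
one 0→1 transition per target assignment, so single-local-state goals lose
no generality.

## Fixtures and the synthetic corpus

`random_an` draws valid networks from explicit integer seeds: uniformly
sampled state counts, transitions (origin ≠ destination), and condition
sets over other automata (at most one state each).  The pinned test corpus
(`tests/data/corpus_an.txt`) holds 200 instances cycling over 2–5 automata
with 2–3 states per automaton, 1–4 transitions per automaton and condition
sizes 0–2, each with a random initial state and goal; a test regenerates
the file byte-for-byte so the corpus and generator cannot drift apart.
These sizes keep every instance within exhaustive-oracle range (≤ 243
global states) while exercising dead-end objectives, unreachable goals,
goals already present, cyclic attractors and multi-automaton conditions.
What the corpus does not emulate: the scale (hundreds of automata), the
sparseness and the long condition chains of real signalling models — so
passing tests demonstrate correctness of the semantics and one-sidedness of
the approximations, not the practical completeness of the approximate modes
on real networks (the false-negative rate there depends on model
structure).

## Oracles

The `oracles` module is validation-only ground truth: reachable sets by raw
depth-first enumeration over dictionaries, EF-goal by forward fixpoint over
successor lists, the temporal characterization of bifurcations evaluated
clause by clause over all one-step successors, and local paths by blind
sequence filtering.  None of it shares traversal code with the production
modules, and all of it is capped (10,000 states) — it exists so that every
production result on fixtures is cross-checked by an independent
implementation.

## Numerical and degenerate-input choices

* State serialization is canonical: automata lexicographic, `a=0,b=1,c=0`.
* Transition identifiers are assigned in file order (`t1…`); all result
  orderings follow identifier order, making reports byte-reproducible.
* Automata with no transitions, empty transition sets, empty goal-target
  sets (goal then unreachable), and goals present in the initial state are
  all legal and covered by tests.
* The only randomness in the package is the fixture generator, driven by
  explicit seeds; analyses are fully deterministic.
* Timings in `classify_modes` reports are informational and never asserted.

## Known limitations

* The exact method is bounded by `state_cap`; no symbolic (decision
  diagram) representation is provided.
* The approximate modes inherit the incompleteness of the one-sided
  analyses; on unfavourable structures they may return empty results for
  goals that do have bifurcations.
* The under-approximation search is exponential in the worst case (it is
  an NP witness search); practical behaviour relies on the smallness of
  per-automaton state counts, as in typical biological models.
* Multi-valued inputs are accepted directly in the AN format; function
  tables for Thomas networks are not parsed (only Boolean tables are).
* Universal/existential bifurcations over *sets* of initial states and
  probabilistic extensions are out of scope.
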