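"""Reachability without the state space: the two one-sided analyses.

The over-approximation (a least fixpoint over objectives of the Local
Causality Graph) can *prove* a goal unreachable; the under-approximation
(an acyclic sub-LCG witness) can *prove* it reachable.  Neither ever builds
the global state graph, which is what makes them usable on networks with
hundreds of automata.
"""

from bifan import Context, LocalState, builtin, oa_reach, ua_reach
from bifan.reach import witness_to_json

net, _s0, goal = builtin("fig1")

# once automaton c has committed to c=2, a=2 is lost: the necessary
# condition fails because no local path leads from c2 back to c0
s = net.state({"a": 1, "b": 0, "c": 2})
res = oa_reach(net, s, goal)
print(f"OA(<{s}> ->* {goal}) = {res.decision}"
      f"  ->  {'inconclusive' if res.decision else 'PROVED unreachable'}")

# one step earlier (c=1) the fixpoint still accepts -- inconclusive
s = net.state({"a": 1, "b": 0, "c": 1})
print(f"OA(<{s}> ->* {goal}) = {oa_reach(net, s, goal).decision}"
      "  ->  inconclusive (necessary condition only)")

# the under-approximation finds a certified witness from <a0,b1,c1>
s = net.state({"a": 0, "b": 1, "c": 1})
w = ua_reach(net, Context.from_state(s), [LocalState("a", 2)])
print(f"\nUA(<{s}> ->* {goal}): witness found = {w is not None}")
print("chosen local paths per objective:")
print(witness_to_json(w))
print("Reading: b serves b0 (via t5, needs a0), c serves c0 (via t7, needs"
      " b1), then a climbs a0 -> a2 via t3 -- an acyclic, independent plan.")
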