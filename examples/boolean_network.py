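"""From a Boolean network table to bifurcation analysis.

Encodes a small Boolean network given in 'targets, factors' form as an
automata network (one transition per prime implicant), encodes a two-node
goal *state* as a fresh goal automaton, and finds its bifurcations.
"""

from bifan import (
    encode_boolean_network,
    encode_goal_states,
    exact_bifurcations,
    find_bifurcations,
)

TABLE = """\
targets, factors
x, !y
y, !x
z, x & !y
"""

net = encode_boolean_network(TABLE)
print("encoded automata network:")
print(net.serialize())

# goal: the state where x won and z is expressed -- as a partial state
net2, goal = encode_goal_states(net, [{"x": 1, "y": 0, "z": 1}])
s0 = net2.state({"x": 0, "y": 0, "z": 0, goal.automaton: 0})
print(f"goal automaton '{goal.automaton}' flips to 1 in states matching "
      "x=1,y=0,z=1")

for r in exact_bifurcations(net2, s0, goal):
    t = net2.transition(r.transition)
    print(f"exact: {t}")
approx = find_bifurcations(net2, s0, goal, mode="I3sharp")
print(f"I3sharp finds: {[r.transition for r in approx]}")
print("\nThe mutual-inhibition switch decides between x and y: letting y "
      "switch on while x is still off (t3) commits the race against x, "
      "after which the goal state is forfeit.")
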