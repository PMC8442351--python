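"""Solve the capacity-allocation MDP by backward induction.

Solves the full case-study instance (constant synthetic show
probability 0.8 per booked outpatient), prints the expected cost of one
business day under the optimal policy, and queries the policy for the
worked example state: 1 inpatient, 3 outpatients and 1 emergency
waiting in period 1 with 3 scanners free.
"""

from radcap import baseline_config, feasible_regular_actions, solve

config = baseline_config(show_probs=0.8)
result = solve(config)

print(f"states evaluated:    {result.n_states:,}")
print(f"solve time:          {result.solve_seconds:.2f} s")
print(f"expected day cost:   US$ {result.expected_day_cost:.2f}")

state = (1, 3, 1)
actions = feasible_regular_actions(state, config.capacity(1))
chosen = result.policy.regular_action(1, state)
print(f"\nstate {state} in period 1 (capacity {config.capacity(1)}):")
print(f"  feasible actions: {[tuple(a) for a in actions]}")
print(f"  optimal action:   {tuple(chosen)}")
# The optimal action selects (a_ip, a_op, a_ep) patients for service; the
# emergency patient is always seated, and the remaining two slots go to
# whichever mix minimises expected waiting + overtime + penalty cost.
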