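"""Independent reference computations used by the test suite.

Everything here deliberately avoids the package's own computational
paths: the Poisson-binomial pmf is recomputed by explicit subset
enumeration, transition kernels by brute-force enumeration of arrival
outcomes, and optimal values by exhaustive enumeration of all
deterministic Markov policies with exact policy evaluation.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from radcap.config import ProblemConfig
from radcap.states import (
    feasible_overtime_actions,
    feasible_regular_actions,
    overtime_states,
    regular_states,
)


def subset_enumeration_pmf(slot_probs) -> np.ndarray:
    """Poisson-binomial pmf by summing over all 2^Q show/no-show subsets."""
    q = len(slot_probs)
    pmf = np.zeros(q + 1)
    for outcome in product((0, 1), repeat=q):
        prob = 1.0
        for shown, p in zip(outcome, slot_probs):
            prob *= p if shown else 1.0 - p
        pmf[sum(outcome)] += prob
    return pmf


def brute_force_regular_kernel(state, action, period: int, config: ProblemConfig):
    """Next-state distribution by enumerating every arrival outcome.

    ``period`` is 1-based and must be < N; shows are resolved for the
    slots booked in period+1.
    """
    w_ip, w_op, w_ep = state
    a_ip, a_op, a_ep = action
    slots = config.show_probs[period]  # 0-based index period == period+1 slots
    p_ip = config.p_ip[period - 1]
    p_ep = config.p_ep[period - 1]
    dist: dict[tuple[int, int, int], float] = {}
    for dip in (0, 1):
        pr_ip = p_ip if dip else 1.0 - p_ip
        for dep in (0, 1):
            pr_ep = p_ep if dep else 1.0 - p_ep
            for outcome in product((0, 1), repeat=len(slots)):
                pr_op = 1.0
                for shown, p in zip(outcome, slots):
                    pr_op *= p if shown else 1.0 - p
                key = (w_ip - a_ip + dip, w_op - a_op + sum(outcome), dep)
                dist[key] = dist.get(key, 0.0) + pr_ip * pr_ep * pr_op
    return {k: v for k, v in dist.items() if v > 0.0}


def brute_force_initial_distribution(config: ProblemConfig):
    """Period-1 state distribution by enumerating pre-day arrival outcomes."""
    slots = config.show_probs[0]
    p_ip, p_ep = config.p_ip[0], config.p_ep[0]
    dist: dict[tuple[int, int, int], float] = {}
    for dip in (0, 1):
        pr_ip = p_ip if dip else 1.0 - p_ip
        for dep in (0, 1):
            pr_ep = p_ep if dep else 1.0 - p_ep
            for outcome in product((0, 1), repeat=len(slots)):
                pr_op = 1.0
                for shown, p in zip(outcome, slots):
                    pr_op *= p if shown else 1.0 - p
                key = (dip, sum(outcome), dep)
                dist[key] = dist.get(key, 0.0) + pr_ip * pr_ep * pr_op
    return {k: v for k, v in dist.items() if v > 0.0}


def _stage_plan(config: ProblemConfig):
    """(label, states, action-lists) per decision stage, in forward order."""
    plan = []
    for i in range(1, config.n_regular + 1):
        states = regular_states(i, config, restricted=True)
        plan.append(
            ("R", i, states,
             {z: feasible_regular_actions(z, config.capacity(i)) for z in states})
        )
    for k in range(1, config.n_overtime + 1):
        states = overtime_states(k, config, restricted=True)
        plan.append(
            ("O", k, states,
             {s: feasible_overtime_actions(s, config.overtime_cap(k)) for s in states})
        )
    return plan


def count_deterministic_policies(config: ProblemConfig) -> int:
    n = 1
    for _, _, _, actions in _stage_plan(config):
        for acts in actions.values():
            n *= len(acts)
    return n


def _evaluate_policy(config: ProblemConfig, plan, choice: dict):
    """Exact expected cost-to-go of one deterministic policy, per stage.

    Backward *evaluation* (no minimisation) with expectations taken by
    brute-force outcome enumeration.  Returns the period-1 value table.
    """
    n, k_max = config.n_regular, config.n_overtime
    v_next: dict = {}
    # terminal penalties on everything a last-stage action can reach
    kind, idx, states, actions = plan[-1]
    terminal = {}
    for s in states:
        for a in actions[s]:
            if kind == "O":
                t = (s[0] - a[0], s[1] - a[1])
            else:
                t = (s[0] - a[0], s[1] - a[1])
            terminal[t] = config.pc_ip * t[0] + config.pc_op * t[1]
    v_next = terminal
    for kind, idx, states, actions in reversed(plan):
        v_here = {}
        for s in states:
            a = choice[(kind, idx, s)]
            if kind == "O":
                succ = (s[0] - a[0], s[1] - a[1])
                v_here[s] = config.oc_ip * a[0] + config.oc_op * a[1] + v_next[succ]
            elif idx == n:
                succ = (s[0] - a[0], s[1] - a[1])
                cost = config.wc_ip * (s[0] - a[0]) + config.wc_op * (s[1] - a[1])
                v_here[s] = cost + v_next[succ]
            else:
                cost = config.wc_ip * (s[0] - a[0]) + config.wc_op * (s[1] - a[1])
                ev = 0.0
                for nxt, p in brute_force_regular_kernel(s, a, idx, config).items():
                    ev += p * v_next[nxt]
                v_here[s] = cost + ev
        v_next = v_here
    return v_next  # period-1 table


def exhaustive_policy_minimum(config: ProblemConfig):
    """Minimum expected cost-to-go at period 1, over ALL deterministic
    Markov policies, state by state."""
    plan = _stage_plan(config)
    keys, options = [], []
    for kind, idx, states, actions in plan:
        for s in states:
            keys.append((kind, idx, s))
            options.append(actions[s])
    best: dict = {}
    for combo in product(*options):
        choice = dict(zip(keys, combo))
        v1 = _evaluate_policy(config, plan, choice)
        for s, v in v1.items():
            if s not in best or v < best[s]:
                best[s] = v
    return best


def welch_t(sample_a, sample_b) -> float:
    """Textbook Welch two-sample t statistic."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))
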