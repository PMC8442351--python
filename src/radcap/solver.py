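"""Backward-induction (dynamic programming) solution of the one-day MDP.

The value function is computed regressively: the terminal stage charges
the penalty for every patient still unserved; each overtime period
minimises overtime cost plus the (deterministic) successor value; each
regular period minimises waiting cost plus the expectation of the next
period's value under the arrival/no-show kernel.  The crossing from the
last regular period into overtime is deterministic because no patients
arrive once regular hours end, and the EP component is dropped there
(after-hours emergencies go to dedicated equipment).

Values are stored per period over the restricted state sets only; a
successor that falls outside the next period's restricted set raises
immediately, which doubles as a forward-closure check of the state
enumeration.  Argmin ties are broken by the fixed IP-descending action
order, so policies are reproducible across runs and platforms.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from .config import ProblemConfig
from .costs import overtime_cost, penalty_cost, waiting_cost
from .states import (
    ActionPair,
    ActionTriple,
    OvertimeState,
    RegularState,
    feasible_overtime_actions,
    feasible_regular_actions,
    overtime_states,
    regular_states,
)
from .transition import initial_state_distribution, ip_transition, op_show_pmf

__all__ = [
    "ValueTables",
    "PolicyTable",
    "SolveResult",
    "StateClosureError",
    "terminal_values",
    "backward_overtime",
    "backward_regular",
    "solve",
    "policy_to_frame",
    "values_to_frame",
]


class StateClosureError(RuntimeError):
    """A reachable successor state is missing from the enumerated set."""


@dataclass
class ValueTables:
    """Per-period expected cost-to-go tables.

    ``regular[i-1]`` maps each period-``i`` state to V_i; ``overtime[k-1]``
    likewise for overtime period k; ``terminal`` holds the penalty values
    of the post-overtime states.
    """

    regular: list[dict[RegularState, float]] = field(default_factory=list)
    overtime: list[dict[OvertimeState, float]] = field(default_factory=list)
    terminal: dict[OvertimeState, float] = field(default_factory=dict)


@dataclass
class PolicyTable:
    """Argmin action per period and state (the optimal policy)."""

    regular: list[dict[RegularState, ActionTriple]] = field(default_factory=list)
    overtime: list[dict[OvertimeState, ActionPair]] = field(default_factory=list)

    def regular_action(self, period: int, state, rng=None) -> ActionTriple:
        try:
            return self.regular[period - 1][RegularState(*state)]
        except KeyError:
            raise StateClosureError(
                f"no stored action for regular period {period}, state {tuple(state)}"
            ) from None

    def overtime_action(self, k: int, state, rng=None) -> ActionPair:
        try:
            return self.overtime[k - 1][OvertimeState(*state)]
        except KeyError:
            raise StateClosureError(
                f"no stored action for overtime period {k}, state {tuple(state)}"
            ) from None


@dataclass
class SolveResult:
    values: ValueTables
    policy: PolicyTable
    expected_day_cost: float
    n_states: int
    solve_seconds: float
    config: ProblemConfig


def terminal_values(config: ProblemConfig, restricted: bool = True) -> dict[OvertimeState, float]:
    """Penalty value of every terminal-reachable (w_ip, w_op) state."""
    reachable: set[OvertimeState] = set()
    if config.n_overtime > 0:
        for s in overtime_states(config.n_overtime, config, restricted):
            for b in feasible_overtime_actions(s, config.overtime_cap(config.n_overtime)):
                reachable.add(OvertimeState(s.w_ip - b.b_ip, s.w_op - b.b_op))
    else:
        n = config.n_regular
        for z in regular_states(n, config, restricted):
            for a in feasible_regular_actions(z, config.capacity(n)):
                reachable.add(OvertimeState(z.w_ip - a.a_ip, z.w_op - a.a_op))
    return {s: penalty_cost(s, config) for s in reachable}


def backward_overtime(
    config: ProblemConfig,
    next_values: dict[OvertimeState, float],
    restricted: bool = True,
) -> tuple[list[dict[OvertimeState, float]], list[dict[OvertimeState, ActionPair]]]:
    """Value and policy sweeps for overtime periods K..1.

    Successors are deterministic: serving ``b`` from state ``s`` leads to
    ``s - b`` (no arrivals in overtime).
    """
    values: list[dict[OvertimeState, float]] = [None] * config.n_overtime  # type: ignore
    policies: list[dict[OvertimeState, ActionPair]] = [None] * config.n_overtime  # type: ignore
    for k in range(config.n_overtime, 0, -1):
        cap = config.overtime_cap(k)
        v_k: dict[OvertimeState, float] = {}
        pi_k: dict[OvertimeState, ActionPair] = {}
        for s in overtime_states(k, config, restricted):
            best_v, best_b = None, None
            for b in feasible_overtime_actions(s, cap):
                succ = OvertimeState(s.w_ip - b.b_ip, s.w_op - b.b_op)
                try:
                    v = overtime_cost(b, config) + next_values[succ]
                except KeyError:
                    raise StateClosureError(
                        f"overtime period {k}: successor {succ} of state {s} "
                        "missing from next-stage values"
                    ) from None
                if best_v is None or v < best_v - 1e-12:
                    best_v, best_b = v, b
            v_k[s], pi_k[s] = best_v, best_b
        values[k - 1], policies[k - 1] = v_k, pi_k
        next_values = v_k
    return values, policies


def backward_regular(
    config: ProblemConfig,
    next_values: dict,
    restricted: bool = True,
) -> tuple[list[dict[RegularState, float]], list[dict[RegularState, ActionTriple]]]:
    """Value and policy sweeps for regular periods N..1.

    ``next_values`` holds the stage-N+1 values: the first overtime table
    when overtime exists, else the terminal penalties.  For i < N the
    expectation over arrivals is shared between actions through the
    post-service residual ``(w - a)``, so it is memoised per period.
    """
    n = config.n_regular
    values: list[dict[RegularState, float]] = [None] * n  # type: ignore
    policies: list[dict[RegularState, ActionTriple]] = [None] * n  # type: ignore

    for i in range(n, 0, -1):
        cap = config.capacity(i)
        v_i: dict[RegularState, float] = {}
        pi_i: dict[RegularState, ActionTriple] = {}
        if i == n:
            # deterministic crossing into overtime: s_1 = (w_ip - a_ip, w_op - a_op)
            def expected(x_ip: int, x_op: int, _nv=next_values, _i=i):
                succ = OvertimeState(x_ip, x_op)
                try:
                    return _nv[succ]
                except KeyError:
                    raise StateClosureError(
                        f"regular period {_i}: overtime successor {succ} missing"
                    ) from None
        else:
            nv = values[i]  # V_{i+1}, filled in the previous iteration
            p_ip = config.p_ip[i - 1]
            p_ep = config.p_ep[i - 1]
            op_pmf = op_show_pmf(config.show_probs[i])  # slots booked for i+1
            ip_kernel = list(ip_transition(0, 0, p_ip).items())
            ep_kernel = list(ip_transition(0, 0, p_ep).items())
            cache: dict[tuple[int, int], float] = {}

            def expected(x_ip: int, x_op: int, _i=i, _nv=nv, _cache=cache,
                         _ipk=ip_kernel, _epk=ep_kernel, _pmf=op_pmf):
                key = (x_ip, x_op)
                if key in _cache:
                    return _cache[key]
                total = 0.0
                for dip, p1 in _ipk:
                    for u, p2 in enumerate(_pmf):
                        if p2 == 0.0:
                            continue
                        for dep, p3 in _epk:
                            succ = RegularState(x_ip + dip, x_op + u, dep)
                            try:
                                total += p1 * p2 * p3 * _nv[succ]
                            except KeyError:
                                raise StateClosureError(
                                    f"regular period {_i}: successor {succ} "
                                    "missing from next-stage values"
                                ) from None
                _cache[key] = total
                return total

        for z in regular_states(i, config, restricted):
            best_v, best_a = None, None
            for a in feasible_regular_actions(z, cap):
                v = waiting_cost(z, a, config) + expected(z.w_ip - a.a_ip, z.w_op - a.a_op)
                if best_v is None or v < best_v - 1e-12:
                    best_v, best_a = v, a
            v_i[z], pi_i[z] = best_v, best_a
        values[i - 1], policies[i - 1] = v_i, pi_i
    return values, policies


def solve(config: ProblemConfig, restricted: bool = True) -> SolveResult:
    """Full backward-induction solve: terminal -> overtime -> regular sweeps.

    Returns the value and policy tables plus the expected cost of one
    business day, i.e. the initial-state distribution averaged over V_1.
    """
    t0 = time.perf_counter()
    tables = ValueTables()
    tables.terminal = terminal_values(config, restricted)
    if config.n_overtime > 0:
        tables.overtime, ot_policy = backward_overtime(config, tables.terminal, restricted)
        stage_np1 = tables.overtime[0]
    else:
        ot_policy = []
        stage_np1 = tables.terminal
    tables.regular, reg_policy = backward_regular(config, stage_np1, restricted)
    policy = PolicyTable(regular=reg_policy, overtime=ot_policy)

    expected = 0.0
    v1 = tables.regular[0]
    for z, p in initial_state_distribution(config).items():
        if p == 0.0:
            continue
        try:
            expected += p * v1[z]
        except KeyError:
            raise StateClosureError(f"initial state {z} missing from period-1 values") from None

    n_states = sum(len(t) for t in tables.regular) + sum(len(t) for t in tables.overtime)
    return SolveResult(
        values=tables,
        policy=policy,
        expected_day_cost=expected,
        n_states=n_states,
        solve_seconds=time.perf_counter() - t0,
        config=config,
    )


def policy_to_frame(policy: PolicyTable) -> pd.DataFrame:
    """Flatten a policy to one row per (period, state, action)."""
    rows = []
    for i, table in enumerate(policy.regular, start=1):
        for z, a in sorted(table.items()):
            rows.append(("regular", i, z.w_ip, z.w_op, z.w_ep, a.a_ip, a.a_op, a.a_ep))
    for k, table in enumerate(policy.overtime, start=1):
        for s, b in sorted(table.items()):
            rows.append(("overtime", k, s.w_ip, s.w_op, 0, b.b_ip, b.b_op, 0))
    return pd.DataFrame(
        rows,
        columns=["stage", "period", "w_ip", "w_op", "w_ep", "a_ip", "a_op", "a_ep"],
    )


def values_to_frame(values: ValueTables) -> pd.DataFrame:
    """Flatten value tables to one row per (period, state, value)."""
    rows = []
    for i, table in enumerate(values.regular, start=1):
        for z, v in sorted(table.items()):
            rows.append(("regular", i, z.w_ip, z.w_op, z.w_ep, v))
    for k, table in enumerate(values.overtime, start=1):
        for s, v in sorted(table.items()):
            rows.append(("overtime", k, s.w_ip, s.w_op, 0, v))
    for s, v in sorted(values.terminal.items()):
        rows.append(("terminal", 0, s.w_ip, s.w_op, 0, v))
    return pd.DataFrame(
        rows, columns=["stage", "period", "w_ip", "w_op", "w_ep", "value"]
    )
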