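"""State-space and action-space enumeration.

Regular-period states are triples ``(w_ip, w_op, w_ep)`` of patients
waiting at the start of the period; overtime states drop the EP
component (EPs arriving after hours go to dedicated equipment).  Two
enumeration modes are provided:

* *unrestricted* — only the per-type box bounds (``w_ip <= i``,
  ``w_op <=`` cumulative schedule, ``w_ep in {0, 1}``; overtime
  ``w_ip <= N``, ``w_op <=`` total schedule);
* *restricted* — additionally the capacity-aware joint bound
  ``w_ip + w_op <= cumAg_i + i - sum_{l<i}(C_l - 1)``, i.e. every past
  period is guaranteed to have dedicated at least ``C_l - 1`` slots to
  IPs/OPs (the worst case of one emergency arrival per past period).
  For overtime period k the bound further shrinks by the overtime
  capacity already consumed, ``sum_{y<k} C_{N+y}``.

On the case-study instance the two modes total 93,534 and 52,680 states
respectively; the restricted mode is what the solver enumerates.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

from .config import ProblemConfig

__all__ = [
    "RegularState",
    "OvertimeState",
    "ActionTriple",
    "ActionPair",
    "InfeasibleStateError",
    "regular_states",
    "overtime_states",
    "count_states",
    "count_states_by_period",
    "regular_joint_bound",
    "overtime_joint_bound",
    "feasible_regular_actions",
    "feasible_overtime_actions",
]


class RegularState(NamedTuple):
    w_ip: int
    w_op: int
    w_ep: int


class OvertimeState(NamedTuple):
    w_ip: int
    w_op: int


class ActionTriple(NamedTuple):
    a_ip: int
    a_op: int
    a_ep: int


class ActionPair(NamedTuple):
    b_ip: int
    b_op: int


class InfeasibleStateError(ValueError):
    """A state admits no feasible action (e.g. more EPs than capacity)."""


def regular_joint_bound(period: int, config: ProblemConfig) -> int | None:
    """Joint bound on ``w_ip + w_op`` for a regular period, or None.

    Returns ``None`` both for period 1 (no joint bound applies) and when
    cumulative capacity exceeds cumulative potential arrivals, in which
    case enumeration falls back to the period-1-style box.
    """
    if period == 1:
        return None
    cum_ag = config.cumulative_schedule(period)
    consumed = sum(c - 1 for c in config.regular_capacity[: period - 1])
    if cum_ag + period < consumed:
        return None
    return cum_ag + period - consumed


def overtime_joint_bound(k: int, config: ProblemConfig) -> int:
    """Joint bound on ``w_ip + w_op`` at the start of overtime period k.

    May be negative when overtime capacity has already cleared every
    patient that could possibly remain; callers treat that as "only the
    empty state".
    """
    n = config.n_regular
    consumed_regular = sum(c - 1 for c in config.regular_capacity)
    consumed_overtime = sum(config.overtime_capacity[: k - 1])
    return config.total_scheduled + n - consumed_regular - consumed_overtime


def regular_states(
    period: int, config: ProblemConfig, restricted: bool = True
) -> list[RegularState]:
    """Feasible states at the start of regular period ``period`` (1-based)."""
    if not 1 <= period <= config.n_regular:
        raise ValueError(f"period {period} outside 1..{config.n_regular}")
    if period == 1:
        return [
            RegularState(w_ip, w_op, w_ep)
            for w_ip in range(2)
            for w_op in range(config.schedule[0] + 1)
            for w_ep in range(2)
        ]
    bound = regular_joint_bound(period, config) if restricted else None
    if restricted and bound is None:
        # capacity outruns arrivals: only day-start-style states possible
        return [
            RegularState(w_ip, w_op, w_ep)
            for w_ip in range(2)
            for w_op in range(config.schedule[period - 1] + 1)
            for w_ep in range(2)
        ]
    max_op = config.cumulative_schedule(period)
    states = []
    for w_ip in range(period + 1):
        op_hi = max_op if bound is None else min(max_op, bound - w_ip)
        for w_op in range(op_hi + 1):
            states.append(RegularState(w_ip, w_op, 0))
            states.append(RegularState(w_ip, w_op, 1))
    return states


def overtime_states(
    k: int, config: ProblemConfig, restricted: bool = True
) -> list[OvertimeState]:
    """Feasible states at the start of overtime period ``k`` (1-based)."""
    if not 1 <= k <= config.n_overtime:
        raise ValueError(f"overtime period {k} outside 1..{config.n_overtime}")
    max_ip, max_op = config.n_regular, config.total_scheduled
    if not restricted:
        return [
            OvertimeState(w_ip, w_op)
            for w_ip in range(max_ip + 1)
            for w_op in range(max_op + 1)
        ]
    bound = overtime_joint_bound(k, config)
    if bound < 0:
        return [OvertimeState(0, 0)]
    states = []
    for w_ip in range(min(max_ip, bound) + 1):
        for w_op in range(min(max_op, bound - w_ip) + 1):
            states.append(OvertimeState(w_ip, w_op))
    return states


def count_states_by_period(
    config: ProblemConfig, restricted: bool = True
) -> list[tuple[str, int]]:
    """Per-period state counts, labelled "R1".."RN", "O1".."OK"."""
    rows = [
        (f"R{i}", len(regular_states(i, config, restricted)))
        for i in range(1, config.n_regular + 1)
    ]
    rows += [
        (f"O{k}", len(overtime_states(k, config, restricted)))
        for k in range(1, config.n_overtime + 1)
    ]
    return rows


def count_states(config: ProblemConfig, restricted: bool = True) -> int:
    """Total state count over all regular and overtime periods."""
    return sum(n for _, n in count_states_by_period(config, restricted))


@lru_cache(maxsize=200_000)
def _regular_actions_cached(
    w_ip: int, w_op: int, w_ep: int, capacity: int
) -> tuple[ActionTriple, ...]:
    if w_ep > capacity:
        raise InfeasibleStateError(
            f"state ({w_ip},{w_op},{w_ep}) has more emergencies than capacity {capacity}"
        )
    served = min(capacity, w_ip + w_op + w_ep)
    r = served - w_ep  # slots left for IPs/OPs after the mandatory EPs
    actions = tuple(
        ActionTriple(a_ip, r - a_ip, w_ep)
        for a_ip in range(min(w_ip, r), max(0, r - w_op) - 1, -1)
    )
    return actions


def feasible_regular_actions(state, capacity: int) -> list[ActionTriple]:
    """All feasible actions for a regular-period state, IP-descending.

    Every waiting EP must be selected (emergency priority), and exactly
    ``min(capacity, |z|)`` patients are served — no voluntary idling.
    Raises :class:`InfeasibleStateError` if the EPs alone exceed capacity.
    """
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    w_ip, w_op, w_ep = state
    return list(_regular_actions_cached(w_ip, w_op, w_ep, capacity))


def feasible_overtime_actions(state, capacity: int) -> list[ActionPair]:
    """All feasible actions for an overtime state, IP-descending."""
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    w_ip, w_op = state
    served = min(capacity, w_ip + w_op)
    return [
        ActionPair(b_ip, served - b_ip)
        for b_ip in range(min(w_ip, served), max(0, served - w_op) - 1, -1)
    ]
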