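"""Benchmark capacity-allocation policies P1-P5.

All heuristics share the mandatory structure of a feasible action: every
waiting emergency patient is seated first, and exactly
``min(capacity, waiting)`` patients are served.  They differ only in how
the remaining capacity is split between waiting IPs and OPs:

* P1 — random: draw uniformly without replacement from the pooled
  IP + OP waiting lists;
* P2 — OPs first (closest to the studied department's practice);
* P3 — IPs first;
* P4 — mixed: IPs first in the first half of the day, OPs first in the
  second half and in overtime;
* P5 — the mirror of P4: OPs first early, IPs first late and in overtime.

The first "half" is ``ceil(N/2)`` periods (19 of 37 in the case study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ProblemConfig
from .states import ActionPair, ActionTriple, InfeasibleStateError

__all__ = ["HeuristicPolicy", "heuristic_action", "make_policy", "POLICY_NAMES"]

POLICY_NAMES = ("P1", "P2", "P3", "P4", "P5")


def _split(remaining: int, first: int, second: int) -> tuple[int, int]:
    """Fill ``remaining`` slots from ``first`` then ``second`` waiting pools."""
    take_first = min(first, remaining)
    take_second = min(second, remaining - take_first)
    return take_first, take_second


@dataclass(frozen=True)
class HeuristicPolicy:
    """A priority rule over waiting IPs and OPs.

    ``n_regular`` fixes the half-day split used by the mixed policies
    P4/P5.  Use :func:`heuristic_action` (or :func:`make_policy`, which
    binds per-period capacities from a config) to obtain actions.
    """

    name: str
    n_regular: int

    def __post_init__(self) -> None:
        if self.name not in POLICY_NAMES:
            raise ValueError(f"unknown policy {self.name!r}; choose from {POLICY_NAMES}")

    @property
    def first_half(self) -> int:
        return -(-self.n_regular // 2)  # ceil(N/2): 19 of 37

    def ip_first_regular(self, period: int) -> bool:
        early = period <= self.first_half
        return {"P2": False, "P3": True, "P4": early, "P5": not early}[self.name]

    def ip_first_overtime(self) -> bool:
        # P4 keeps OP priority in overtime; P5 switches to IPs
        return self.name in ("P3", "P5")


def heuristic_action(
    policy: HeuristicPolicy,
    period: int,
    state,
    capacity: int,
    rng: np.random.Generator | None = None,
):
    """Action chosen by a benchmark policy in the given state.

    A 3-tuple state is treated as a regular-period state (``period`` is
    the 1-based regular period) and returns an :class:`ActionTriple`; a
    2-tuple is an overtime state (``period`` is the overtime index k) and
    returns an :class:`ActionPair`.  ``rng`` is only consulted by P1.
    """
    if len(state) == 3:
        w_ip, w_op, w_ep = state
        if w_ep > capacity:
            raise InfeasibleStateError(
                f"state {tuple(state)} has more emergencies than capacity {capacity}"
            )
        remaining = min(capacity, w_ip + w_op + w_ep) - w_ep
        if policy.name == "P1":
            take = min(remaining, w_ip + w_op)
            a_ip = int(rng.hypergeometric(w_ip, w_op, take)) if take else 0
            return ActionTriple(a_ip, take - a_ip, w_ep)
        if policy.ip_first_regular(period):
            a_ip, a_op = _split(remaining, w_ip, w_op)
        else:
            a_op, a_ip = _split(remaining, w_op, w_ip)
        return ActionTriple(a_ip, a_op, w_ep)

    w_ip, w_op = state
    remaining = min(capacity, w_ip + w_op)
    if policy.name == "P1":
        b_ip = int(rng.hypergeometric(w_ip, w_op, remaining)) if remaining else 0
        return ActionPair(b_ip, remaining - b_ip)
    if policy.ip_first_overtime():
        b_ip, b_op = _split(remaining, w_ip, w_op)
    else:
        b_op, b_ip = _split(remaining, w_op, w_ip)
    return ActionPair(b_ip, b_op)


class _BoundHeuristic:
    """Heuristic bound to a config, exposing the simulator interface.

    Mirrors :class:`~radcap.solver.PolicyTable`: ``regular_action`` and
    ``overtime_action`` with 1-based period/overtime indices.
    """

    def __init__(self, policy: HeuristicPolicy, config: ProblemConfig):
        self._policy = policy
        self._config = config
        self.name = policy.name

    def regular_action(self, period: int, state, rng=None) -> ActionTriple:
        return heuristic_action(
            self._policy, period, state, self._config.capacity(period), rng
        )

    def overtime_action(self, k: int, state, rng=None) -> ActionPair:
        return heuristic_action(
            self._policy, k, state, self._config.overtime_cap(k), rng
        )


def make_policy(name: str, config: ProblemConfig):
    """Instantiate a named policy bound to ``config``.

    ``name`` in P1..P5 returns the corresponding heuristic; ``"optimal"``
    solves the MDP and returns its policy table.
    """
    if name == "optimal":
        from .solver import solve

        return solve(config).policy
    return _BoundHeuristic(HeuristicPolicy(name, config.n_regular), config)
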