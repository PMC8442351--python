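"""Exact one-step transition distributions between regular-period states.

Per period, at most one inpatient and one emergency patient arrive
(independent Bernoulli trials), while the outpatients booked for the
*next* period show independently, each with their own slot probability —
so the OP arrival count follows a Poisson-binomial distribution.  The
joint kernel is the product of the three independent component kernels.

The Poisson-binomial pmf is computed by iterative convolution: starting
from the point mass at zero, each slot ``h`` convolves the running pmf
with ``(1 - p_h, p_h)``.  This is exact (no truncation) and O(Q^2) for Q
slots, which is negligible at clinic scale.
"""

from __future__ import annotations

import numpy as np

from .config import ProblemConfig
from .states import ActionTriple, RegularState

__all__ = [
    "ip_transition",
    "op_show_pmf",
    "joint_transition",
    "initial_state_distribution",
]


def ip_transition(w: int, a: int, p_arrival: float) -> dict[int, float]:
    """Bernoulli single-arrival kernel for IPs (and, identically, EPs).

    After serving ``a`` of ``w`` waiting patients, the successor count is
    ``w - a`` with probability ``1 - p_arrival`` and ``w - a + 1`` with
    probability ``p_arrival``.
    """
    if not 0 <= a <= w:
        raise ValueError(f"action {a} infeasible for waiting count {w}")
    if not 0.0 <= p_arrival <= 1.0:
        raise ValueError("p_arrival must lie in [0, 1]")
    base = w - a
    out: dict[int, float] = {}
    if p_arrival < 1.0:
        out[base] = 1.0 - p_arrival
    if p_arrival > 0.0:
        out[base + 1] = out.get(base + 1, 0.0) + p_arrival
    return out


def op_show_pmf(slot_probs) -> np.ndarray:
    """Poisson-binomial pmf of the number of shows among scheduled slots.

    Returns an array of length ``len(slot_probs) + 1`` whose ``u``-th
    entry is the probability that exactly ``u`` of the booked outpatients
    show up.  An empty slot list gives a point mass at zero.
    """
    probs = np.asarray(slot_probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("slot probabilities must lie in [0, 1]")
    pmf = np.ones(1)
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def joint_transition(
    state: RegularState,
    action: ActionTriple,
    period: int,
    config: ProblemConfig,
) -> dict[RegularState, float]:
    """Distribution of the next regular-period state given an action.

    Valid for ``1 <= period <= N - 1``; the crossing from period N into
    overtime is deterministic (no further arrivals) and handled by the
    solver.  The OP component uses the show probabilities of the slots
    booked for period ``period + 1``.
    """
    if not 1 <= period <= config.n_regular - 1:
        raise ValueError(
            f"period {period} outside 1..{config.n_regular - 1}; the N -> overtime "
            "transition is deterministic"
        )
    w_ip, w_op, w_ep = state
    a_ip, a_op, a_ep = action
    if a_ip > w_ip or a_op > w_op or a_ep != w_ep or min(a_ip, a_op) < 0:
        raise ValueError(f"action {action} infeasible for state {state}")
    ip_kernel = ip_transition(w_ip, a_ip, config.p_ip[period - 1])
    ep_kernel = ip_transition(w_ep, a_ep, config.p_ep[period - 1])
    op_pmf = op_show_pmf(config.show_probs[period])  # slots of period+1
    op_base = w_op - a_op
    dist: dict[RegularState, float] = {}
    for nip, p1 in ip_kernel.items():
        for u, p2 in enumerate(op_pmf):
            if p2 == 0.0:
                continue
            for nep, p3 in ep_kernel.items():
                nxt = RegularState(nip, op_base + u, nep)
                dist[nxt] = dist.get(nxt, 0.0) + p1 * p2 * p3
    return dist


def initial_state_distribution(config: ProblemConfig) -> dict[RegularState, float]:
    """Distribution of the period-1 state from the empty pre-day state.

    The day starts empty; before period 1 an IP and an EP may arrive
    (Bernoulli with the period-1 probabilities) and the OPs booked for
    period 1 show or not.
    """
    ip_kernel = ip_transition(0, 0, config.p_ip[0])
    ep_kernel = ip_transition(0, 0, config.p_ep[0])
    op_pmf = op_show_pmf(config.show_probs[0])
    dist: dict[RegularState, float] = {}
    for nip, p1 in ip_kernel.items():
        for u, p2 in enumerate(op_pmf):
            if p2 == 0.0:
                continue
            for nep, p3 in ep_kernel.items():
                dist[RegularState(nip, u, nep)] = p1 * p2 * p3
    return dist
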