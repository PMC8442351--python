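"""Monte-Carlo simulation of business days and policy comparison.

Each simulated day replays the model dynamics forward: the day starts
empty, arrivals before period 1 set the initial state, then every
regular period applies the policy's action, accrues waiting cost and
draws the next arrivals (Bernoulli IP/EP, per-slot Bernoulli OP shows);
the leftover demand crosses deterministically into overtime, where each
served patient accrues overtime cost, and whoever remains at the end
incurs the terminal penalty.

Policy comparison uses common random numbers by default: every policy
sees the same per-day arrival streams (a child seed per day index),
which sharpens paired contrasts; pass ``common_random_numbers=False``
for fully independent streams.  Significance versus the reference policy
is assessed with Welch's unequal-variance two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ProblemConfig
from .costs import overtime_cost, penalty_cost, waiting_cost
from .policies import POLICY_NAMES, make_policy

__all__ = [
    "DayResult",
    "SimulationSummary",
    "PolicyComparison",
    "simulate_day",
    "simulate_many",
    "compare_policies",
    "occupancy_rate",
]


@dataclass(frozen=True)
class DayResult:
    """Cost decomposition and patient accounting for one simulated day."""

    waiting_cost: float
    overtime_cost: float
    penalty_cost: float
    unserved_ip: int
    unserved_op: int
    served_ip: int
    served_op: int
    served_ep: int
    served_regular: int
    served_overtime: int
    arrived_ip: int
    arrived_op: int
    arrived_ep: int

    @property
    def total_cost(self) -> float:
        return self.waiting_cost + self.overtime_cost + self.penalty_cost

    @property
    def served(self) -> int:
        return self.served_regular + self.served_overtime


def simulate_day(policy, config: ProblemConfig, rng: np.random.Generator) -> DayResult:
    """Simulate one business day under ``policy`` and return its accounting."""
    n, k_max = config.n_regular, config.n_overtime
    # separate stream for in-policy randomness (P1), so that under common
    # random numbers every policy sees identical arrival draws
    policy_rng = np.random.default_rng(int(rng.integers(2**31)))
    # pre-day arrivals into the period-1 state
    w_ip = int(rng.random() < config.p_ip[0])
    w_ep = int(rng.random() < config.p_ep[0])
    w_op = int(sum(rng.random() < p for p in config.show_probs[0]))
    arrived_ip, arrived_op, arrived_ep = w_ip, w_op, w_ep

    wait_cost = 0.0
    served_regular = 0
    served_ip = served_op = served_ep = 0
    for i in range(1, n + 1):
        state = (w_ip, w_op, w_ep)
        a_ip, a_op, a_ep = policy.regular_action(i, state, policy_rng)
        _check_regular(state, (a_ip, a_op, a_ep), config.capacity(i))
        wait_cost += waiting_cost(state, (a_ip, a_op, a_ep), config)
        served_regular += a_ip + a_op + a_ep
        served_ip += a_ip
        served_op += a_op
        served_ep += a_ep
        w_ip -= a_ip
        w_op -= a_op
        w_ep -= a_ep
        if i < n:
            new_ip = int(rng.random() < config.p_ip[i - 1])
            new_ep = int(rng.random() < config.p_ep[i - 1])
            new_op = int(sum(rng.random() < p for p in config.show_probs[i]))
            w_ip += new_ip
            w_op += new_op
            w_ep += new_ep
            arrived_ip += new_ip
            arrived_op += new_op
            arrived_ep += new_ep

    # overtime: no arrivals; EP backlog is zero by construction (a_ep = w_ep)
    ot_cost = 0.0
    served_overtime = 0
    for k in range(1, k_max + 1):
        state = (w_ip, w_op)
        b_ip, b_op = policy.overtime_action(k, state, policy_rng)
        _check_overtime(state, (b_ip, b_op), config.overtime_cap(k))
        ot_cost += overtime_cost((b_ip, b_op), config)
        served_overtime += b_ip + b_op
        served_ip += b_ip
        served_op += b_op
        w_ip -= b_ip
        w_op -= b_op

    pen_cost = penalty_cost((w_ip, w_op), config)
    return DayResult(
        waiting_cost=wait_cost,
        overtime_cost=ot_cost,
        penalty_cost=pen_cost,
        unserved_ip=w_ip,
        unserved_op=w_op,
        served_ip=served_ip,
        served_op=served_op,
        served_ep=served_ep,
        served_regular=served_regular,
        served_overtime=served_overtime,
        arrived_ip=arrived_ip,
        arrived_op=arrived_op,
        arrived_ep=arrived_ep,
    )


def _check_regular(state, action, capacity) -> None:
    w_ip, w_op, w_ep = state
    a_ip, a_op, a_ep = action
    ok = (
        0 <= a_ip <= w_ip
        and 0 <= a_op <= w_op
        and a_ep == w_ep
        and a_ip + a_op + a_ep == min(capacity, w_ip + w_op + w_ep)
    )
    if not ok:
        raise RuntimeError(f"policy returned infeasible action {action} in state {state}")


def _check_overtime(state, action, capacity) -> None:
    w_ip, w_op = state
    b_ip, b_op = action
    ok = 0 <= b_ip <= w_ip and 0 <= b_op <= w_op and b_ip + b_op == min(
        capacity, w_ip + w_op
    )
    if not ok:
        raise RuntimeError(f"policy returned infeasible action {action} in state {state}")


@dataclass(frozen=True)
class SimulationSummary:
    """Replicate-level sample and its descriptive statistics."""

    policy: str
    n_days: int
    mean_cost: float
    sd_cost: float
    q75_cost: float
    mean_unserved_ip: float
    sd_unserved_ip: float
    mean_unserved_op: float
    sd_unserved_op: float
    occupancy: float
    days: pd.DataFrame

    @property
    def se_cost(self) -> float:
        return self.sd_cost / np.sqrt(self.n_days)


def _day_seeds(seed: int, n_days: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_days, dtype=np.uint32)


def simulate_many(
    policy,
    config: ProblemConfig,
    n_days: int,
    seed: int | np.ndarray = 0,
    policy_name: str = "policy",
) -> SimulationSummary:
    """Simulate ``n_days`` independent business days.

    ``seed`` may be an integer (expanded to one child seed per day) or a
    precomputed array of per-day seeds, which is how
    :func:`compare_policies` shares arrival streams across policies.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    seeds = seed if isinstance(seed, np.ndarray) else _day_seeds(int(seed), n_days)
    records = []
    for day_seed in seeds[:n_days]:
        day = simulate_day(policy, config, np.random.default_rng(int(day_seed)))
        records.append(
            (
                day.waiting_cost, day.overtime_cost, day.penalty_cost,
                day.total_cost, day.unserved_ip, day.unserved_op,
                day.served, day.served_ip, day.served_op, day.served_ep,
                day.arrived_ip, day.arrived_op, day.arrived_ep,
            )
        )
    days = pd.DataFrame(
        records,
        columns=[
            "waiting_cost", "overtime_cost", "penalty_cost", "total_cost",
            "unserved_ip", "unserved_op", "served", "served_ip",
            "served_op", "served_ep", "arrived_ip", "arrived_op", "arrived_ep",
        ],
    )
    return SimulationSummary(
        policy=policy_name,
        n_days=n_days,
        mean_cost=float(days["total_cost"].mean()),
        sd_cost=float(days["total_cost"].std(ddof=1)) if n_days > 1 else 0.0,
        q75_cost=float(days["total_cost"].quantile(0.75)),
        mean_unserved_ip=float(days["unserved_ip"].mean()),
        sd_unserved_ip=float(days["unserved_ip"].std(ddof=1)) if n_days > 1 else 0.0,
        mean_unserved_op=float(days["unserved_op"].mean()),
        sd_unserved_op=float(days["unserved_op"].std(ddof=1)) if n_days > 1 else 0.0,
        occupancy=occupancy_rate(days, config),
        days=days,
    )


def occupancy_rate(day_results: pd.DataFrame, config: ProblemConfig) -> float:
    """Fraction of offered service slots actually used, over the sample.

    The denominator counts every offered slot: the full regular capacity
    profile plus the configured overtime capacity, whether used or not.
    """
    if len(day_results) == 0:
        raise ValueError("need at least one simulated day")
    offered = sum(config.regular_capacity) + sum(config.overtime_capacity)
    return float(day_results["served"].sum() / (offered * len(day_results)))


@dataclass(frozen=True)
class PolicyComparison:
    """Per-policy summaries plus Welch t-tests against the reference."""

    reference: str
    summaries: dict[str, SimulationSummary]
    table: pd.DataFrame

    def summary(self, policy: str) -> SimulationSummary:
        return self.summaries[policy]


def compare_policies(
    config: ProblemConfig,
    policies=("optimal",) + POLICY_NAMES,
    n_days: int = 10_000,
    seed: int = 0,
    reference: str | None = None,
    common_random_numbers: bool = True,
    alpha: float = 0.05,
) -> PolicyComparison:
    """Simulate every policy and test each against the reference.

    Entries of ``policies`` may be names ("optimal", "P1".."P5") or
    ``(name, policy_object)`` pairs for pre-built policies (e.g. a solved
    :class:`~radcap.solver.PolicyTable`, so the MDP is not re-solved).
    """
    named = []
    for entry in policies:
        if isinstance(entry, str):
            named.append((entry, make_policy(entry, config)))
        else:
            named.append(tuple(entry))
    if len(named) < 2:
        raise ValueError("need at least two policies to compare")
    ref_name = reference or named[0][0]

    shared = _day_seeds(seed, n_days) if common_random_numbers else None
    summaries: dict[str, SimulationSummary] = {}
    for idx, (name, pol) in enumerate(named):
        seeds = shared if shared is not None else _day_seeds(seed + 7919 * (idx + 1), n_days)
        summaries[name] = simulate_many(pol, config, n_days, seeds, policy_name=name)

    ref = summaries[ref_name]
    rows = []
    for name, summ in summaries.items():
        if name == ref_name:
            t_stat, p_val = 0.0, 1.0
        elif summ.days["total_cost"].equals(ref.days["total_cost"]):
            t_stat, p_val = 0.0, 1.0  # identical samples (e.g. same policy, CRN)
        else:
            t_stat, p_val = stats.ttest_ind(
                summ.days["total_cost"], ref.days["total_cost"], equal_var=False
            )
        rows.append(
            {
                "policy": name,
                "mean_cost": summ.mean_cost,
                "sd_cost": summ.sd_cost,
                "q75_cost": summ.q75_cost,
                "mean_unserved_ip": summ.mean_unserved_ip,
                "sd_unserved_ip": summ.sd_unserved_ip,
                "mean_unserved_op": summ.mean_unserved_op,
                "sd_unserved_op": summ.sd_unserved_op,
                "occupancy": summ.occupancy,
                "t_vs_reference": float(t_stat),
                "p_value": float(p_val),
                "significant_5pct": bool(name != ref_name and p_val < alpha),
            }
        )
    return PolicyComparison(
        reference=ref_name, summaries=summaries, table=pd.DataFrame(rows)
    )
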