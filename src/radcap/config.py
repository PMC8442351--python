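"""Problem configuration, appointment schedules and capacity profiles.

A business day in the modelled radiology unit consists of ``n_regular``
15-minute regular periods followed by ``n_overtime`` overtime periods.
Outpatients (OPs) are pre-scheduled per period and may no-show with
slot-specific probability; inpatients (IPs) and emergency patients (EPs)
arrive at most one per period with Bernoulli probabilities.  The scanner
fleet mixes fast machines (one exam per period) with at most one slow
machine (one exam every second period), which makes per-period capacity
a 2-periodic sequence.

All periods are 1-based in every public interface; internal containers
are plain 0-based sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ProblemConfig",
    "ConfigurationError",
    "build_double_overbooking",
    "build_flight_overbooking",
    "build_capacity_profile",
    "baseline_config",
    "load_config",
    "save_config",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


def build_double_overbooking(
    n_regular: int,
    base_per_period: int,
    n_extra: int,
    start_period: int = 1,
    gap: int = 6,
) -> list[int]:
    """Schedule with extra OPs spread across the day ("double-booking").

    One extra outpatient is placed at ``start_period`` and then every
    ``gap`` periods, ``n_extra`` times in total.  With the default
    ``(start_period=1, gap=6)`` and six extras over 37 periods the extras
    fall on periods 1, 7, 13, 19, 25 and 31.

    Parameters
    ----------
    n_regular : number of regular periods.
    base_per_period : OPs scheduled in every period before overbooking.
    n_extra : number of overbooked slots to place.
    start_period : 1-based period of the first extra slot.
    gap : stride between consecutive extra slots.

    Returns
    -------
    list of int, length ``n_regular``; its sum is
    ``base_per_period * n_regular + n_extra``.
    """
    if n_regular < 1 or base_per_period < 0 or n_extra < 0:
        raise ConfigurationError("counts must be nonnegative and n_regular >= 1")
    if n_extra > 0:
        last = start_period + (n_extra - 1) * gap
        if start_period < 1 or last > n_regular:
            raise ConfigurationError(
                f"overbooked slot at period {last} exceeds horizon {n_regular}"
            )
    schedule = [base_per_period] * n_regular
    for j in range(n_extra):
        schedule[start_period - 1 + j * gap] += 1
    return schedule


def build_flight_overbooking(
    n_regular: int, base_per_period: int, n_extra: int
) -> list[int]:
    """Schedule with every overbooked OP stacked into the first period."""
    if n_regular < 1 or base_per_period < 0 or n_extra < 0:
        raise ConfigurationError("counts must be nonnegative and n_regular >= 1")
    schedule = [base_per_period] * n_regular
    schedule[0] += n_extra
    return schedule


def build_capacity_profile(
    n_regular: int, n_fast: int, n_slow: int, slow_phase: int = 0
) -> list[int]:
    """Per-period number of exams that can start, for a mixed fleet.

    Fast scanners start one exam every period.  The (at most one) slow
    scanner takes two periods per exam, so it can start an exam only on
    every second period; with ``slow_phase=0`` its start periods are
    1, 3, 5, ...  With ``(n_fast, n_slow) = (2, 1)`` over 37 periods the
    profile alternates 3, 2, 3, ..., 3 (19 threes, 18 twos).
    """
    if n_fast < 0 or n_slow not in (0, 1) or slow_phase not in (0, 1):
        raise ConfigurationError("need n_fast >= 0, n_slow in {0,1}, slow_phase in {0,1}")
    return [
        n_fast + (n_slow if (i % 2) == slow_phase else 0) for i in range(n_regular)
    ]


@dataclass(frozen=True)
class ProblemConfig:
    """Full parameterisation of the one-day capacity-allocation MDP.

    ``show_probs`` is ragged: one show probability in (0, 1] per scheduled
    OP slot per regular period, ``len(show_probs[i]) == schedule[i]``.
    Arrival probabilities are stored per period so that period-varying
    extensions need no refactor; :func:`baseline_config` fills them with a
    constant.
    """

    n_regular: int
    n_overtime: int
    regular_capacity: tuple[int, ...]
    overtime_capacity: tuple[int, ...]
    schedule: tuple[int, ...]
    wc_ip: float
    wc_op: float
    oc_ip: float
    oc_op: float
    pc_ip: float
    pc_op: float
    p_ip: tuple[float, ...]
    p_ep: tuple[float, ...]
    show_probs: tuple[tuple[float, ...], ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        n, k = self.n_regular, self.n_overtime
        if n < 1 or k < 0:
            raise ConfigurationError("n_regular must be >= 1 and n_overtime >= 0")
        for name, seq, length in (
            ("regular_capacity", self.regular_capacity, n),
            ("overtime_capacity", self.overtime_capacity, k),
            ("schedule", self.schedule, n),
            ("p_ip", self.p_ip, n),
            ("p_ep", self.p_ep, n),
            ("show_probs", self.show_probs, n),
        ):
            if len(seq) != length:
                raise ConfigurationError(f"{name} must have length {length}, got {len(seq)}")
        for name, cap_seq in (
            ("regular_capacity", self.regular_capacity),
            ("overtime_capacity", self.overtime_capacity),
        ):
            if any(c < 1 for c in cap_seq):
                raise ConfigurationError(f"every entry of {name} must be >= 1")
        if any(a < 0 for a in self.schedule):
            raise ConfigurationError("schedule entries must be >= 0")
        for name in ("wc_ip", "wc_op", "oc_ip", "oc_op", "pc_ip", "pc_op"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost {name} must be >= 0")
        for name, probs in (("p_ip", self.p_ip), ("p_ep", self.p_ep)):
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ConfigurationError(f"{name} entries must lie in [0, 1]")
        for i, (ag, slot_probs) in enumerate(zip(self.schedule, self.show_probs), start=1):
            if len(slot_probs) != ag:
                raise ConfigurationError(
                    f"show_probs for period {i} has {len(slot_probs)} entries, "
                    f"schedule says {ag}"
                )
            if any(not 0.0 < p <= 1.0 for p in slot_probs):
                raise ConfigurationError(
                    f"show probabilities for period {i} must lie in (0, 1]"
                )

    # -- convenience accessors (all 1-based) -------------------------------
    def capacity(self, period: int) -> int:
        """Service capacity of regular period ``period`` (1-based)."""
        return self.regular_capacity[period - 1]

    def overtime_cap(self, k: int) -> int:
        """Service capacity of overtime period ``k`` (1-based)."""
        return self.overtime_capacity[k - 1]

    def cumulative_schedule(self, period: int) -> int:
        """Total OPs scheduled in periods 1..period."""
        return sum(self.schedule[:period])

    @property
    def total_scheduled(self) -> int:
        return sum(self.schedule)

    def with_show_probs(self, show_probs: Sequence[Sequence[float]]) -> "ProblemConfig":
        return replace(
            self, show_probs=tuple(tuple(float(p) for p in row) for row in show_probs)
        )


def _expand_show_probs(
    show_probs, schedule: Sequence[int]
) -> tuple[tuple[float, ...], ...]:
    """Accept a scalar (constant show probability) or a ragged sequence."""
    if isinstance(show_probs, (int, float)):
        return tuple(tuple(float(show_probs) for _ in range(ag)) for ag in schedule)
    return tuple(tuple(float(p) for p in row) for row in show_probs)


def baseline_config(
    *,
    n_regular: int = 37,
    n_overtime: int = 4,
    overbooking: str = "double",
    base_per_period: int = 2,
    n_extra: int = 6,
    overbook_start: int = 1,
    overbook_gap: int = 6,
    overtime_resources: int = 2,
    n_fast: int = 2,
    n_slow: int = 1,
    slow_phase: int = 0,
    cost_level: str = "baseline",
    arrival_level: str = "baseline",
    show_probs=0.8,
) -> ProblemConfig:
    """Build the case-study configuration (or a variant of it).

    Defaults reproduce the baseline instance: 37 regular + 4 overtime
    periods, 74 scheduled OPs plus 6 double-overbooked, fleet of 2 fast +
    1 slow scanner, two overtime resources, baseline cost and arrival
    levels.  ``show_probs`` may be a scalar (constant per slot) or a
    ragged per-period sequence, e.g. from
    :func:`radcap.noshow.generate_show_probabilities`.
    """
    from .costs import arrival_preset, cost_preset  # local: avoid cycle

    if overbooking == "double":
        schedule = build_double_overbooking(
            n_regular, base_per_period, n_extra, overbook_start, overbook_gap
        )
    elif overbooking == "flight":
        schedule = build_flight_overbooking(n_regular, base_per_period, n_extra)
    elif overbooking == "none":
        schedule = [base_per_period] * n_regular
    else:
        raise ConfigurationError(f"unknown overbooking rule {overbooking!r}")
    costs = cost_preset(cost_level)
    p_ip, p_ep = arrival_preset(arrival_level)
    return ProblemConfig(
        n_regular=n_regular,
        n_overtime=n_overtime,
        regular_capacity=tuple(
            build_capacity_profile(n_regular, n_fast, n_slow, slow_phase)
        ),
        overtime_capacity=tuple([overtime_resources] * n_overtime),
        schedule=tuple(schedule),
        wc_ip=costs.wc_ip,
        wc_op=costs.wc_op,
        oc_ip=costs.oc_ip,
        oc_op=costs.oc_op,
        pc_ip=costs.pc_ip,
        pc_op=costs.pc_op,
        p_ip=tuple([p_ip] * n_regular),
        p_ep=tuple([p_ep] * n_regular),
        show_probs=_expand_show_probs(show_probs, schedule),
        meta={
            "overbooking": overbooking,
            "overtime_resources": overtime_resources,
            "cost_level": cost_level,
            "arrival_level": arrival_level,
        },
    )


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def save_config(config: ProblemConfig, path: str | Path) -> None:
    """Write a configuration to a flat YAML file (round-trippable)."""
    doc = {
        "n_regular": config.n_regular,
        "n_overtime": config.n_overtime,
        "regular_capacity": list(config.regular_capacity),
        "overtime_capacity": list(config.overtime_capacity),
        "schedule": list(config.schedule),
        "wc_ip": config.wc_ip,
        "wc_op": config.wc_op,
        "oc_ip": config.oc_ip,
        "oc_op": config.oc_op,
        "pc_ip": config.pc_ip,
        "pc_op": config.pc_op,
        "p_ip": list(config.p_ip),
        "p_ep": list(config.p_ep),
        "show_probs": [list(row) for row in config.show_probs],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_SCALAR_OK = ("p_ip", "p_ep")


def load_config(path: str | Path) -> ProblemConfig:
    """Load and validate a configuration from YAML.

    Two convenience blocks are accepted in place of explicit sequences:
    ``overbooking: {rule: double|flight|none, base: int, extras: int,
    start: int, gap: int}`` builds ``schedule``, and ``fleet: {fast: int,
    slow: int, slow_phase: int}`` builds ``regular_capacity``.  ``p_ip``,
    ``p_ep`` and ``show_probs`` may be scalars.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    n = raw.get("n_regular")
    if n is None:
        raise ConfigurationError(f"{path}: missing required key n_regular")

    if "overbooking" in raw and "schedule" not in raw:
        ob = raw.pop("overbooking")
        rule = ob.get("rule", "none")
        base = ob.get("base", 2)
        extras = ob.get("extras", 0)
        if rule == "double":
            raw["schedule"] = build_double_overbooking(
                n, base, extras, ob.get("start", 1), ob.get("gap", 6)
            )
        elif rule == "flight":
            raw["schedule"] = build_flight_overbooking(n, base, extras)
        elif rule == "none":
            raw["schedule"] = [base] * n
        else:
            raise ConfigurationError(f"unknown overbooking rule {rule!r}")
    if "fleet" in raw and "regular_capacity" not in raw:
        fl = raw.pop("fleet")
        raw["regular_capacity"] = build_capacity_profile(
            n, fl.get("fast", 2), fl.get("slow", 0), fl.get("slow_phase", 0)
        )

    required = [
        "n_regular", "n_overtime", "regular_capacity", "overtime_capacity",
        "schedule", "wc_ip", "wc_op", "oc_ip", "oc_op", "pc_ip", "pc_op",
        "p_ip", "p_ep", "show_probs",
    ]
    missing = [key for key in required if key not in raw]
    if missing:
        raise ConfigurationError(f"{path}: missing required keys {missing}")

    for key in _SCALAR_OK:
        if isinstance(raw[key], (int, float)):
            raw[key] = [float(raw[key])] * n
    schedule = list(raw["schedule"])
    raw["show_probs"] = _expand_show_probs(raw["show_probs"], schedule)

    return ProblemConfig(
        n_regular=int(raw["n_regular"]),
        n_overtime=int(raw["n_overtime"]),
        regular_capacity=tuple(int(c) for c in raw["regular_capacity"]),
        overtime_capacity=tuple(int(c) for c in raw["overtime_capacity"]),
        schedule=tuple(int(a) for a in schedule),
        wc_ip=float(raw["wc_ip"]),
        wc_op=float(raw["wc_op"]),
        oc_ip=float(raw["oc_ip"]),
        oc_op=float(raw["oc_op"]),
        pc_ip=float(raw["pc_ip"]),
        pc_op=float(raw["pc_op"]),
        p_ip=tuple(float(p) for p in raw["p_ip"]),
        p_ep=tuple(float(p) for p in raw["p_ep"]),
        show_probs=raw["show_probs"],
    )
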