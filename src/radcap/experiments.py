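"""Scenario-grid experiments: the full factorial policy comparison.

The study design crosses overbooking rule (double, flight), number of
overtime resources (1, 2), cost level (baseline, low, high), IP/EP
arrival level (baseline, low, high) and policy (optimal, P1..P5); at the
published levels that is 2 x 2 x 3 x 3 x 6 = 216 scenario-policy cells.
Each (rule, resources, costs, arrivals) scenario is simulated once per
policy over a common set of random days and summarised like the study's
cost and unserved-patient tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .config import ProblemConfig, baseline_config
from .policies import POLICY_NAMES
from .simulate import compare_policies

__all__ = ["ScenarioGrid", "run_grid", "format_mean_sd_table"]


@dataclass(frozen=True)
class ScenarioGrid:
    """Factor levels of the factorial experiment plan."""

    overbooking: tuple[str, ...] = ("double", "flight")
    overtime_resources: tuple[int, ...] = (1, 2)
    cost_levels: tuple[str, ...] = ("baseline", "low", "high")
    arrival_levels: tuple[str, ...] = ("baseline", "low", "high")
    policies: tuple[str, ...] = ("optimal",) + POLICY_NAMES
    #: extra keyword arguments passed to baseline_config per scenario
    config_kwargs: dict = field(default_factory=dict, compare=False)

    @property
    def n_cells(self) -> int:
        return (
            len(self.overbooking) * len(self.overtime_resources)
            * len(self.cost_levels) * len(self.arrival_levels) * len(self.policies)
        )

    def scenarios(self):
        yield from product(
            self.overbooking, self.overtime_resources,
            self.cost_levels, self.arrival_levels,
        )

    def build_config(self, rule: str, resources: int, costs: str, arrivals: str) -> ProblemConfig:
        return baseline_config(
            overbooking=rule,
            overtime_resources=resources,
            cost_level=costs,
            arrival_level=arrivals,
            **self.config_kwargs,
        )


def run_grid(grid: ScenarioGrid, n_days: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Run every scenario of the grid; one row per (scenario, policy).

    Columns include the scenario factors, the cost mean/SD/75th
    percentile, unserved-count means/SDs, occupancy, and the Welch t-test
    of each policy against the first policy of the grid (the reference,
    normally "optimal") at the 5% level.
    """
    frames = []
    for idx, (rule, resources, costs, arrivals) in enumerate(grid.scenarios()):
        config = grid.build_config(rule, resources, costs, arrivals)
        comparison = compare_policies(
            config, policies=grid.policies, n_days=n_days, seed=seed + idx
        )
        table = comparison.table.copy()
        table.insert(0, "overbooking", rule)
        table.insert(1, "overtime_resources", resources)
        table.insert(2, "cost_level", costs)
        table.insert(3, "arrival_level", arrivals)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def format_mean_sd_table(results: pd.DataFrame, value: str = "cost") -> pd.DataFrame:
    """Pivot grid results to "mean (SD)" strings, one column per policy.

    ``value`` is "cost" for the total-cost table or "unserved_ip" /
    "unserved_op" for the unserved-patient tables.
    """
    if value == "cost":
        mean_col, sd_col, fmt = "mean_cost", "sd_cost", "{:.2f} ({:.2f})"
    else:
        mean_col, sd_col, fmt = f"mean_{value}", f"sd_{value}", "{:.2f} ± {:.2f}"
    out = results.copy()
    out["cell"] = [
        fmt.format(m, s) for m, s in zip(out[mean_col], out[sd_col])
    ]
    return out.pivot_table(
        index=["overbooking", "overtime_resources", "cost_level", "arrival_level"],
        columns="policy",
        values="cell",
        aggfunc="first",
    )
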