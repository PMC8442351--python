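import numpy as np
import pytest

from conftest import make_config
from oracles import count_deterministic_policies, exhaustive_policy_minimum
from radcap.solver import (
    backward_overtime,
    policy_to_frame,
    solve,
    terminal_values,
    values_to_frame,
)
from radcap.states import OvertimeState


class TestTerminalValues:
    def test_penalties(self, tiny_config):
        values = terminal_values(tiny_config)
        assert values[OvertimeState(0, 0)] == 0.0
        assert values[OvertimeState(1, 0)] == pytest.approx(24.96)

    def test_linear_in_counts(self):
        config = make_config(n_regular=4, schedule=(2, 2, 2, 2),
                             regular_capacity=(1, 1, 1, 1))
        values = terminal_values(config)
        assert values[OvertimeState(3, 4)] == pytest.approx(3 * 24.96 + 4 * 12.48)


class TestBackwardOvertime:
    def test_zero_costs_give_zero_values(self):
        config = make_config(oc=0.0, pc_ip=0.0, pc_op=0.0)
        values, policies = backward_overtime(config, terminal_values(config))
        assert all(v == 0.0 for table in values for v in table.values())
        # tie-break representative: first action in the IP-descending order
        assert policies[0][OvertimeState(1, 1)] == (1, 0)

    def test_serve_both_when_capacity_allows(self):
        config = make_config(n_overtime=1, overtime_capacity=(2,))
        values, policies = backward_overtime(config, terminal_values(config))
        assert policies[0][OvertimeState(1, 1)] == (1, 1)
        assert values[0][OvertimeState(1, 1)] == pytest.approx(5.52)

    def test_high_ip_penalty_prioritises_inpatient(self):
        config = make_config(pc_ip=1000.0, pc_op=1.0)
        _, policies = backward_overtime(config, terminal_values(config))
        assert policies[0][OvertimeState(1, 1)] == (1, 0)


class TestSolve:
    def test_zero_cost_problem_has_zero_value(self):
        config = make_config(wc_ip=0, wc_op=0, oc=0, pc_ip=0, pc_op=0)
        result = solve(config)
        assert result.expected_day_cost == 0.0
        assert all(v == 0.0 for t in result.values.regular for v in t.values())

    def test_degenerate_day_costs_nothing(self):
        config = make_config(schedule=(0, 0, 0), p_ip=0.0, p_ep=0.0)
        assert solve(config).expected_day_cost == 0.0

    def test_single_period_serves_the_inpatient(self):
        config = make_config(
            n_regular=1, n_overtime=0, schedule=(0,), regular_capacity=(1,),
            overtime_capacity=(), p_ip=0.0, p_ep=0.0, pc_ip=10.0,
        )
        result = solve(config)
        state = (1, 0, 0)
        assert result.values.regular[0][state] == pytest.approx(0.0)
        assert result.policy.regular[0][state] == (1, 0, 0)

    def test_matches_exhaustive_policy_enumeration(self, oracle_config):
        """DP value at every period-1 state equals the exact minimum over
        all deterministic Markov policies."""
        n_policies = count_deterministic_policies(oracle_config)
        assert n_policies <= 1000  # keep the oracle honest and tractable
        best = exhaustive_policy_minimum(oracle_config)
        v1 = solve(oracle_config).values.regular[0]
        assert set(v1) == set(best)
        for state, value in best.items():
            assert v1[state] == pytest.approx(value, abs=1e-9)

    def test_deterministic_world_equals_outcome_tree(self):
        """With all probabilities 1 the day unfolds deterministically and
        the DP value equals the single trajectory's cost."""
        config = make_config(
            n_regular=2, n_overtime=1, schedule=(1, 1), regular_capacity=(1, 1),
            overtime_capacity=(1,), p_ip=1.0, p_ep=1.0, show=1.0,
        )
        # trajectory: z1=(1,1,1) -> serve EP, both IP/OP wait; arrivals add
        # one of each type plus the period-2 OP -> z2=(2,2,1); serve EP
        # again; s1=(2,2); serve cheapest-to-leave in overtime; penalties.
        result = solve(config)
        best = exhaustive_policy_minimum(config)
        assert result.values.regular[0][(1, 1, 1)] == pytest.approx(
            best[(1, 1, 1)], abs=1e-9
        )

    def test_value_monotone_in_state(self, tiny_config):
        for table in solve(tiny_config).values.regular:
            for (w_ip, w_op, w_ep), v in table.items():
                for bigger in ((w_ip + 1, w_op, w_ep), (w_ip, w_op + 1, w_ep),
                               (w_ip, w_op, w_ep + 1)):
                    if bigger in table:
                        assert table[bigger] >= v - 1e-9

    def test_less_capacity_never_helps(self):
        rich = make_config(regular_capacity=(2, 2, 2))
        poor = make_config(regular_capacity=(1, 1, 1))
        v_rich = solve(rich).values.regular[0]
        v_poor = solve(poor).values.regular[0]
        for state in set(v_rich) & set(v_poor):
            assert v_rich[state] <= v_poor[state] + 1e-9

    def test_baseline_smoke(self, baseline):
        result = solve(baseline)
        assert result.n_states == 52_680
        assert np.isfinite(result.expected_day_cost)
        assert result.expected_day_cost > 0
        assert all(np.isfinite(v) and v >= 0
                   for v in result.values.regular[0].values())


class TestExport:
    def test_policy_frame_round_trip(self, tiny_config):
        result = solve(tiny_config)
        frame = policy_to_frame(result.policy)
        assert set(frame.columns) == {
            "stage", "period", "w_ip", "w_op", "w_ep", "a_ip", "a_op", "a_ep"
        }
        regular = frame[frame.stage == "regular"]
        assert len(regular) == sum(len(t) for t in result.policy.regular)
        # actions in the export are the stored argmins
        row = regular.iloc[0]
        stored = result.policy.regular[row.period - 1][
            (row.w_ip, row.w_op, row.w_ep)
        ]
        assert (row.a_ip, row.a_op, row.a_ep) == tuple(stored)

    def test_values_frame_contains_terminal(self, tiny_config):
        frame = values_to_frame(solve(tiny_config).values)
        assert (frame.stage == "terminal").any()
        assert (frame.value >= 0).all()
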