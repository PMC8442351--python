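import numpy as np
import pandas as pd
import pytest

from conftest import make_config
from oracles import welch_t
from radcap.policies import make_policy
from radcap.simulate import (
    compare_policies,
    occupancy_rate,
    simulate_day,
    simulate_many,
)


class TestSimulateDay:
    def test_empty_day_costs_nothing(self):
        config = make_config(schedule=(0, 0, 0), p_ip=0.0, p_ep=0.0)
        day = simulate_day(make_policy("P2", config), config, np.random.default_rng(0))
        assert day.total_cost == 0.0
        assert day.unserved_ip == day.unserved_op == 0

    def test_deterministic_trajectory_matches_hand_computation(self):
        """All probabilities 1: the day unfolds along a single trajectory
        whose cost decomposition is computed by hand."""
        config = make_config(
            n_regular=2, n_overtime=1, schedule=(1, 1),
            regular_capacity=(1, 1), overtime_capacity=(1,),
            p_ip=1.0, p_ep=1.0, show=1.0,
            wc_ip=1.0, wc_op=2.0, oc=3.0, pc_ip=10.0, pc_op=5.0,
        )
        day = simulate_day(make_policy("P3", config), config, np.random.default_rng(0))
        # z1=(1,1,1): serve the EP only (capacity 1); wait cost 1+2=3
        # arrivals -> z2=(2,2,1): serve EP; wait cost 2+4=6
        # s1=(2,2): P3 serves one IP in overtime, cost 3
        # terminal (1,2): penalty 10 + 2*5 = 20
        assert day.waiting_cost == pytest.approx(9.0)
        assert day.overtime_cost == pytest.approx(3.0)
        assert day.penalty_cost == pytest.approx(20.0)
        assert day.total_cost == pytest.approx(32.0)
        assert (day.unserved_ip, day.unserved_op) == (1, 2)
        assert day.served_regular == 2 and day.served_overtime == 1

    def test_seeded_reproducibility(self, small_solved):
        config, result = small_solved
        day_a = simulate_day(result.policy, config, np.random.default_rng(42))
        day_b = simulate_day(result.policy, config, np.random.default_rng(42))
        assert day_a == day_b

    def test_cost_decomposition_sums(self, small_solved):
        config, result = small_solved
        for seed in range(20):
            day = simulate_day(result.policy, config, np.random.default_rng(seed))
            assert day.total_cost == pytest.approx(
                day.waiting_cost + day.overtime_cost + day.penalty_cost
            )

    def test_patient_conservation(self, small_solved):
        """Per day and per patient type: arrivals = served + unserved;
        every emergency arrival is served."""
        config, result = small_solved
        policies = [result.policy] + [make_policy(p, config) for p in ("P1", "P2")]
        for policy in policies:
            for seed in range(30):
                day = simulate_day(policy, config, np.random.default_rng(seed))
                assert day.arrived_ip == day.served_ip + day.unserved_ip
                assert day.arrived_op == day.served_op + day.unserved_op
                assert day.arrived_ep == day.served_ep

    def test_infeasible_policy_fails_hard(self, tiny_config):
        class BadPolicy:
            def regular_action(self, period, state, rng):
                return (0, 0, 0)  # refuses to seat the emergency

            def overtime_action(self, k, state, rng):
                return (0, 0)

        with pytest.raises(RuntimeError, match="infeasible"):
            simulate_day(
                BadPolicy(),
                make_config(p_ip=1.0, p_ep=1.0, show=1.0),
                np.random.default_rng(0),
            )


class TestSimulateMany:
    def test_degenerate_config_zero_mean(self):
        config = make_config(schedule=(0, 0, 0), p_ip=0.0, p_ep=0.0)
        summary = simulate_many(make_policy("P2", config), config, 50, 0)
        assert summary.mean_cost == 0.0 and summary.sd_cost == 0.0

    def test_solver_simulator_consistency(self, small_solved):
        """The simulated mean cost under the optimal policy agrees with
        the solver's expected day cost within Monte-Carlo error."""
        config, result = small_solved
        summary = simulate_many(result.policy, config, 4000, 7)
        assert abs(summary.mean_cost - result.expected_day_cost) <= 3 * summary.se_cost

    def test_summary_statistics_match_sample(self, small_solved):
        config, result = small_solved
        summary = simulate_many(result.policy, config, 200, 3)
        assert summary.mean_cost == pytest.approx(summary.days["total_cost"].mean())
        assert summary.q75_cost == pytest.approx(
            summary.days["total_cost"].quantile(0.75)
        )


class TestOccupancy:
    def test_hand_built_two_day_sample(self):
        config = make_config()  # offered = 3 regular + 1 overtime = 4 slots/day
        days = pd.DataFrame({"served": [4, 2]})
        assert occupancy_rate(days, config) == pytest.approx(6 / 8)

    def test_saturated_demand_fills_every_slot(self):
        config = make_config(
            schedule=(3, 3, 3), p_ip=1.0, p_ep=1.0, show=1.0,
            regular_capacity=(2, 2, 2), overtime_capacity=(1,),
        )
        summary = simulate_many(make_policy("P2", config), config, 10, 0)
        assert summary.occupancy == 1.0

    def test_no_patients_zero_occupancy(self):
        config = make_config(schedule=(0, 0, 0), p_ip=0.0, p_ep=0.0)
        summary = simulate_many(make_policy("P2", config), config, 10, 0)
        assert summary.occupancy == 0.0


class TestComparePolicies:
    def test_policy_against_itself_not_significant(self, small_solved):
        config, result = small_solved
        comparison = compare_policies(
            config,
            policies=[("optimal", result.policy), ("again", result.policy)],
            n_days=100,
            seed=5,
        )
        row = comparison.table.set_index("policy").loc["again"]
        assert row["t_vs_reference"] == 0.0
        assert not row["significant_5pct"]

    def test_welch_statistic_matches_textbook_formula(self, small_solved):
        config, result = small_solved
        comparison = compare_policies(
            config,
            policies=[("optimal", result.policy), "P3"],
            n_days=300,
            seed=9,
        )
        got = comparison.table.set_index("policy").loc["P3", "t_vs_reference"]
        want = welch_t(
            comparison.summaries["P3"].days["total_cost"],
            comparison.summaries["optimal"].days["total_cost"],
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_common_random_numbers_share_arrivals(self, small_solved):
        """Under CRN, two runs of the same heuristic see identical days."""
        config, _ = small_solved
        comparison = compare_policies(
            config,
            policies=[("a", make_policy("P2", config)), ("b", make_policy("P2", config))],
            n_days=50,
            seed=11,
        )
        pd.testing.assert_frame_equal(
            comparison.summaries["a"].days, comparison.summaries["b"].days
        )

    def test_optimal_not_beaten_beyond_sampling_error(self, small_solved):
        config, result = small_solved
        comparison = compare_policies(
            config,
            policies=[("optimal", result.policy), "P1", "P2", "P3", "P4", "P5"],
            n_days=2000,
            seed=13,
        )
        table = comparison.table.set_index("policy")
        opt = table.loc["optimal"]
        for name in ("P1", "P2", "P3", "P4", "P5"):
            alt = table.loc[name]
            se = np.hypot(
                opt["sd_cost"] / np.sqrt(2000), alt["sd_cost"] / np.sqrt(2000)
            )
            assert opt["mean_cost"] <= alt["mean_cost"] + 3 * se
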