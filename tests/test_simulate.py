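"""Synthetic cohort generation: profiles, choice policies, titration agents."""

import numpy as np
import pytest

from effortchoice import (
    Level,
    OptionId,
    Task,
    TitrationConfig,
    final_offer_average,
    rank_options,
    run_phase,
)
from effortchoice.simulate import (
    AgentSpec,
    CohortConfig,
    block_order_permutations,
    gen_choice_data,
    gen_cohort,
    gen_profile,
    gen_titration_policy,
    generating_model_is_identifiable,
    identifiable_task_orders,
)

CONFIG = CohortConfig(master_seed=0)


class TestGenProfile:
    def test_reproducible_from_seed(self):
        a = gen_profile(CONFIG, 42, participant="p")
        b = gen_profile(CONFIG, 42, participant="p")
        assert a == b

    def test_high_concentration_pins_accuracies_to_targets(self):
        config = CohortConfig(master_seed=0, concentration=1e7)
        profile = gen_profile(config, 1)
        for option, acc in profile.accuracy.items():
            target = 0.80 if option.level == Level.LOW else 0.60
            assert acc == pytest.approx(round(target * 15) / 15, abs=1 / 15)

    def test_accuracies_live_on_the_k_over_15_grid(self):
        profile = gen_profile(CONFIG, 7)
        for acc in profile.accuracy.values():
            assert acc * 15 == pytest.approx(round(acc * 15))

    def test_cohort_mean_low_accuracy_near_point_eight(self):
        seeds = np.random.SeedSequence(5).spawn(500)
        lows = [
            gen_profile(CONFIG, s)[OptionId(Task.MEMORY, Level.LOW)] for s in seeds
        ]
        se = np.std(lows, ddof=1) / np.sqrt(len(lows))
        # the k/15 rounding shifts the mean by < 0.01
        assert abs(np.mean(lows) - 0.80) < 3 * se + 0.01


class TestGenChoiceData:
    def test_total_choice_trials_is_ninety(self, group_mean_profile):
        agent = AgentSpec(policy="random")
        data = gen_choice_data(agent, group_mean_profile, 0)
        assert data.n_choices == 90
        assert len(data.counts) == 15

    def test_noiseless_demand_agent_is_perfectly_consistent(self, group_mean_profile):
        agent = AgentSpec(
            policy="demand_ranked", direction="DA", heuristic="all", lapse_rate=0.0
        )
        data = gen_choice_data(agent, group_mean_profile, 0)
        model = rank_options(group_mean_profile, "all", "DA")
        for winner, loser in model.constraints:
            assert data.wins(winner, loser) == (6, 6)

    def test_random_agent_mean_k_is_three(self, group_mean_profile):
        agent = AgentSpec(policy="random")
        ks = []
        for seed in range(400):
            data = gen_choice_data(agent, group_mean_profile, seed)
            ks.extend(k for _, k in data.counts.values())
        assert np.mean(ks) == pytest.approx(3.0, abs=0.05)

    def test_task_agent_leaves_within_task_pairs_at_chance(self, group_mean_profile):
        agent = AgentSpec(
            policy="task_ranked",
            task_order=(Task.HYBRID, Task.MEMORY, Task.MOTOR),
            lapse_rate=0.0,
        )
        within_ks = []
        for seed in range(300):
            data = gen_choice_data(agent, group_mean_profile, seed)
            for (a, b), (n, k) in data.counts.items():
                if a.task == b.task:
                    within_ks.append(k)
                else:
                    rank = {t: i for i, t in enumerate(agent.task_order)}
                    expected = 6 if rank[a.task] < rank[b.task] else 0
                    assert k == expected
        assert np.mean(within_ks) == pytest.approx(3.0, abs=0.1)

    def test_bias_agent_prefers_only_its_tasks_pairs(self, group_mean_profile):
        agent = AgentSpec(
            policy="single_task_bias", biased_task=Task.MOTOR, lapse_rate=0.0
        )
        data = gen_choice_data(agent, group_mean_profile, 3)
        for (a, b), (n, k) in data.counts.items():
            a_in, b_in = a.task == Task.MOTOR, b.task == Task.MOTOR
            if a_in != b_in:
                assert (k == 6) if a_in else (k == 0)


class TestTitrationPolicies:
    def test_value_agent_reward_trace_matches_hand_stepping(self):
        agent = AgentSpec(policy="titration_value", indifference_francs=0.0)
        trace = run_phase(
            gen_titration_policy(agent, "reward"), TitrationConfig.reward(), seed=0
        )
        # tie at 200 -> secondary, then hybrid until the offer climbs back
        offers = [r.secondary_offer for r in trace.records if r.set_index == 1]
        assert offers == [200, 150, 175, 188, 196, 200]
        assert final_offer_average(trace) == 200

    def test_loyal_hybrid_reward_finals_all_300(self):
        agent = AgentSpec(policy="titration_loyal", loyal_target="hybrid")
        trace = run_phase(
            gen_titration_policy(agent, "reward"), TitrationConfig.reward(), seed=0
        )
        finals = [r.secondary_offer for r in trace.records if r.decision_index == 6]
        assert finals == [300, 300, 300]

    def test_loyal_secondary_demand_rises_to_ceiling_and_stays(self):
        agent = AgentSpec(policy="titration_loyal", loyal_target="secondary")
        trace = run_phase(
            gen_titration_policy(agent, "demand"), TitrationConfig.demand(), seed=0
        )
        offers = [r.secondary_offer for r in trace.records]
        assert max(offers) == 12
        assert offers[-6:] == [12] * 6  # clamped at the ceiling by set 3

    def test_non_titration_policy_is_rejected(self):
        with pytest.raises(ValueError):
            gen_titration_policy(AgentSpec(policy="random"), "reward")


class TestIdentifiability:
    def test_block_orders_come_from_low_and_high_rankings(self, group_mean_profile):
        perms = block_order_permutations(group_mean_profile)
        # low ranking: motor > hybrid > memory; high: motor > memory > hybrid
        assert (Task.MOTOR, Task.HYBRID, Task.MEMORY) in perms
        assert (Task.MOTOR, Task.MEMORY, Task.HYBRID) in perms
        assert len(perms) == 4

    def test_identifiable_orders_exclude_block_orders(self, group_mean_profile):
        orders = identifiable_task_orders(group_mean_profile)
        assert len(orders) == 2
        assert not set(orders) & block_order_permutations(group_mean_profile)

    def test_tie_free_profile_models_are_identifiable(self, group_mean_profile):
        for direction in ("DA", "CS"):
            for heuristic in ("all", "low", "high"):
                assert generating_model_is_identifiable(
                    group_mean_profile, direction, heuristic
                )

    def test_tied_tasks_break_identifiability(self, uniform_profile):
        assert not generating_model_is_identifiable(uniform_profile, "DA", "all")


class TestGenCohort:
    def test_referential_integrity_and_label_coverage(self):
        cohort = gen_cohort(CohortConfig(master_seed=9))
        truth = cohort.truth_frame()
        assert set(truth.participant) == set(cohort.profiles)
        assert set(cohort.choices) | set(cohort.traces) == set(cohort.profiles)
        assert set(truth.policy) == {
            "demand_ranked",
            "task_ranked",
            "single_task_bias",
            "random",
            "titration_value",
            "titration_loyal",
        }

    def test_same_master_seed_gives_byte_identical_csvs(self, tmp_path):
        for sub in ("a", "b"):
            gen_cohort(CohortConfig(master_seed=4)).write(tmp_path / sub)
        for name in ("performance.csv", "choices.csv", "titration.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()
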