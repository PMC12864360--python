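"""Synthetic cohorts with known ground-truth decision policies.

Agents emulate the behavioral hypotheses the analysis is built to detect:

* ``demand_ranked`` — chooses according to a demand-related model (DA or CS
  under one of the three heuristics) derived from its own practice profile;
* ``task_ranked`` — follows a fixed task-order preference, choosing at
  chance within a task;
* ``single_task_bias`` — prefers (or avoids) one task's options in
  inter-task pairs, at chance elsewhere;
* ``random`` — chance everywhere;
* ``titration_value`` — in the adjusting-offer phases, picks whichever
  option currently offers better value relative to an indifference point;
* ``titration_loyal`` — sticks with one option regardless of the offers.

Choice noise is a lapse rate ``eps``: with probability ``eps`` the agent
chooses against its own ranking. A lapse model (rather than a softmax on
score differences) keeps the generator purely ordinal, matching what the
ordinal preference models can express.

Practice accuracies are drawn from beta distributions centred on the design
targets — 80% correct for low-demand options and 60% for high-demand ones —
then discretized to the k/15 grid of the 15 practice trials.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .choices import PairwiseChoiceData
from .models import PerformanceProfile, rank_options
from .options import ALL_OPTIONS, ALL_PAIRS, Level, OptionId, Task
from .titration import Policy, TitrationConfig, TitrationTrace, run_phase

__all__ = [
    "AgentSpec",
    "CohortConfig",
    "Cohort",
    "gen_profile",
    "gen_choice_data",
    "gen_titration_policy",
    "gen_cohort",
    "identifiable_task_orders",
    "block_order_permutations",
]

POLICIES = (
    "demand_ranked",
    "task_ranked",
    "single_task_bias",
    "random",
    "titration_value",
    "titration_loyal",
)


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth decision policy of one synthetic participant."""

    policy: str
    direction: str | None = None  # DA | CS (demand_ranked)
    heuristic: str | None = None  # all | low | high (demand_ranked)
    task_order: tuple[Task, ...] | None = None  # task_ranked
    biased_task: Task | None = None  # single_task_bias
    bias_direction: str = "for"  # "for" | "against"
    lapse_rate: float = 0.0
    indifference_francs: float = 0.0  # titration_value, reward phase (tau)
    indifference_squares: float = 4.0  # titration_value, demand phase (lambda)
    loyal_target: str | None = None  # "hybrid" | "secondary" (titration_loyal)

    def __post_init__(self):
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")
        required = {
            "demand_ranked": ("direction", "heuristic"),
            "task_ranked": ("task_order",),
            "single_task_bias": ("biased_task",),
            "titration_loyal": ("loyal_target",),
        }
        for attr in required.get(self.policy, ()):
            if getattr(self, attr) is None:
                raise ValueError(f"policy {self.policy} requires {attr}")

    def describe(self) -> str:
        if self.policy == "demand_ranked":
            return f"demand_ranked:{self.direction}-{self.heuristic}"
        if self.policy == "task_ranked":
            return "task_ranked:" + "-".join(t.value for t in self.task_order)
        if self.policy == "single_task_bias":
            return f"single_task_bias:{self.bias_direction}:{self.biased_task.value}"
        if self.policy == "titration_loyal":
            return f"titration_loyal:{self.loyal_target}"
        return self.policy


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and the accuracy-generating distribution.

    Accuracy means follow the pilot calibration of the tasks: 0.80 for
    low-demand and 0.60 for high-demand options. ``concentration`` is the
    beta pseudo-count (a + b); 35 gives between-subject SDs of roughly
    0.07–0.08, a realistic spread for calibrated accuracy tasks.
    """

    master_seed: int
    n_per_policy: dict[str, int] = field(
        default_factory=lambda: {
            "demand_ranked": 12,
            "task_ranked": 12,
            "single_task_bias": 6,
            "random": 6,
            "titration_value": 8,
            "titration_loyal": 8,
        }
    )
    accuracy_mean_low: float = 0.80
    accuracy_mean_high: float = 0.60
    concentration: float = 35.0
    n_trials: int = 15
    lapse_rate: float = 0.05

    def __post_init__(self):
        for mu in (self.accuracy_mean_low, self.accuracy_mean_high):
            if not 0.0 < mu < 1.0:
                raise ValueError("accuracy means must lie in (0, 1)")


def gen_profile(
    config: CohortConfig, participant_seed, participant: str = "sim"
) -> PerformanceProfile:
    """Draw one practice profile from the cohort accuracy distribution."""
    rng = np.random.default_rng(participant_seed)
    accuracy: dict[OptionId, float] = {}
    for opt in ALL_OPTIONS:
        mu = (
            config.accuracy_mean_low
            if opt.level == Level.LOW
            else config.accuracy_mean_high
        )
        a = mu * config.concentration
        b = (1.0 - mu) * config.concentration
        p = rng.beta(a, b)
        k = int(round(p * config.n_trials))
        accuracy[opt] = k / config.n_trials
    return PerformanceProfile(
        participant=participant, accuracy=accuracy, n_trials=config.n_trials
    )


def _pair_win_probability(
    agent: AgentSpec, profile: PerformanceProfile, a: OptionId, b: OptionId
) -> float:
    """Probability that the canonical-first option ``a`` is chosen over ``b``."""
    eps = agent.lapse_rate
    if agent.policy == "random":
        return 0.5
    if agent.policy == "single_task_bias":
        a_in = a.task == agent.biased_task
        b_in = b.task == agent.biased_task
        if a_in == b_in:
            return 0.5
        p_biased = 1.0 - eps if agent.bias_direction == "for" else eps
        return p_biased if a_in else 1.0 - p_biased
    if agent.policy == "task_ranked":
        if a.task == b.task:
            return 0.5
        rank = {t: i for i, t in enumerate(agent.task_order)}
        return 1.0 - eps if rank[a.task] < rank[b.task] else eps
    if agent.policy == "demand_ranked":
        model = rank_options(profile, agent.heuristic, agent.direction)
        winner = model.winner(a, b)
        if winner is None:
            return 0.5
        return 1.0 - eps if winner == a else eps
    raise ValueError(f"policy {agent.policy} does not define pairwise choices")


def gen_choice_data(
    agent: AgentSpec, profile: PerformanceProfile, seed
) -> PairwiseChoiceData:
    """Simulate the 90-trial choice phase: 6 choices on each of the 15 pairs."""
    rng = np.random.default_rng(seed)
    counts = {}
    for a, b in ALL_PAIRS:
        p = _pair_win_probability(agent, profile, a, b)
        k = int(rng.binomial(6, p))
        counts[(a, b)] = (6, k)
    return PairwiseChoiceData(participant=profile.participant, counts=counts)


def gen_titration_policy(agent: AgentSpec, phase: str = "reward", seed=None) -> Policy:
    """Turn a titration agent into a policy usable by :func:`run_phase`.

    Value agents choose the secondary task when its offer is worth taking:
    in the reward phase when the secondary offer exceeds the hybrid offer by
    at least ``indifference_francs`` (ties go to the secondary task), in the
    demand phase when the secondary square count is below
    ``indifference_squares``. Loyal agents always pick their target. Lapses
    flip the choice with probability ``lapse_rate``, reproducibly from
    ``seed``.
    """
    if agent.policy not in ("titration_value", "titration_loyal"):
        raise ValueError(f"{agent.policy} is not a titration policy")
    if phase not in ("reward", "demand"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = np.random.default_rng(seed)

    def policy(hybrid_offer: float, secondary_offer: float, history) -> str:
        if agent.policy == "titration_loyal":
            choice = agent.loyal_target
        elif phase == "reward":
            take = secondary_offer - hybrid_offer >= agent.indifference_francs
            choice = "secondary" if take else "hybrid"
        else:
            take = secondary_offer < agent.indifference_squares
            choice = "secondary" if take else "hybrid"
        if agent.lapse_rate > 0 and rng.random() < agent.lapse_rate:
            choice = "hybrid" if choice == "secondary" else "secondary"
        return choice

    return policy


def generating_model_is_identifiable(
    profile: PerformanceProfile, direction: str, heuristic: str
) -> bool:
    """True when the demand model (direction, heuristic) built from
    ``profile`` is unique within the 12-model battery and tie-free.

    Exact accuracy ties on the k/15 grid drop constraints and can make two
    demand models (or a demand and a task model) share a constraint set;
    agents generated from such a model cannot win the best/second-best ratio
    criterion, so recovery studies condition on identifiability.
    """
    from .models import build_all_models

    battery = build_all_models(profile)
    gen = next(m for m in battery if m.model_id == f"{direction}-{heuristic}")
    if gen.tie_flag:
        return False
    return not any(
        m.constraints == gen.constraints
        for m in battery
        if m.model_id != gen.model_id
    )


def block_order_permutations(profile: PerformanceProfile) -> set[tuple[Task, ...]]:
    """Task permutations whose inter-task pattern coincides with a demand model.

    The low/high-heuristic demand models rank whole tasks in a block: sorted
    by that heuristic's accuracy, descending for DA and ascending for CS.
    A task-order agent whose order equals one of these (up to four)
    permutations is observationally confounded with a demand model on every
    inter-task pair.
    """
    perms: set[tuple[Task, ...]] = set()
    tasks = (Task.MEMORY, Task.MOTOR, Task.HYBRID)
    for level in (Level.LOW, Level.HIGH):
        acc = {t: profile[OptionId(t, level)] for t in tasks}
        if len(set(acc.values())) < 3:
            continue  # ties drop constraints; no full block order arises
        desc = tuple(sorted(tasks, key=lambda t: -acc[t]))
        perms.add(desc)
        perms.add(tuple(reversed(desc)))
    return perms


def identifiable_task_orders(profile: PerformanceProfile) -> list[tuple[Task, ...]]:
    """Task permutations NOT confounded with any demand model for this profile."""
    blocked = block_order_permutations(profile)
    return [
        p
        for p in itertools.permutations((Task.MEMORY, Task.MOTOR, Task.HYBRID))
        if p not in blocked
    ]


def recovery_study(
    n_per_family: int = 100,
    lapse_rate: float = 0.05,
    seed: int = 0,
    n_random: int = 100,
) -> dict[str, float]:
    """Model-recovery simulation under the study's own conditions.

    Simulates ``n_per_family`` demand-ranked and task-ranked agents with the
    given lapse rate and identifiable generating orders (profiles whose grid
    ties would confound the generating model with another are redrawn; task
    orders avoid the profile's block-order permutations), plus ``n_random``
    random responders, and classifies everyone with the standard battery and
    criteria. Returns the recovered fractions and the random agents'
    no-best-fit and bias-none rates.
    """
    from .bayes import classify, fit_models, task_bias_test
    from .models import build_all_models

    config = CohortConfig(master_seed=seed)
    ss = np.random.SeedSequence(seed)
    combos = [(d, h) for d in ("DA", "CS") for h in ("all", "low", "high")]
    results = {"demand": 0, "task": 0, "random_nbf": 0, "random_bias_none": 0}

    for family in ("demand", "task"):
        for i in range(n_per_family):
            child = ss.spawn(1)[0]
            if family == "demand":
                direction, heuristic = combos[i % 6]
                while True:
                    prof_seed, choice_seed = child.spawn(2)
                    profile = gen_profile(config, prof_seed, participant=f"{family}{i}")
                    if generating_model_is_identifiable(profile, direction, heuristic):
                        break
                    child = ss.spawn(1)[0]
                agent = AgentSpec(
                    policy="demand_ranked",
                    direction=direction,
                    heuristic=heuristic,
                    lapse_rate=lapse_rate,
                )
                target = "demand_related"
            else:
                prof_seed, choice_seed = child.spawn(2)
                profile = gen_profile(config, prof_seed, participant=f"{family}{i}")
                orders = identifiable_task_orders(profile)
                if not orders:
                    continue
                agent = AgentSpec(
                    policy="task_ranked",
                    task_order=orders[i % len(orders)],
                    lapse_rate=lapse_rate,
                )
                target = "task_driven"
            data = gen_choice_data(agent, profile, choice_seed)
            fit = fit_models(build_all_models(profile), data)
            if classify(fit).category == target:
                results[family] += 1

    for i in range(n_random):
        child = ss.spawn(1)[0]
        prof_seed, choice_seed = child.spawn(2)
        profile = gen_profile(config, prof_seed, participant=f"rand{i}")
        data = gen_choice_data(AgentSpec(policy="random"), profile, choice_seed)
        fit = fit_models(build_all_models(profile), data)
        if classify(fit).category == "no_best_fit":
            results["random_nbf"] += 1
        results["random_bias_none"] += sum(
            task_bias_test(data, t).direction == "none" for t in Task
        )

    return {
        "demand_recovered": results["demand"] / n_per_family,
        "task_recovered": results["task"] / n_per_family,
        "random_no_best_fit": results["random_nbf"] / n_random,
        # fraction of individual per-task bias tests returning "none"
        "random_bias_none": results["random_bias_none"] / (3 * n_random),
    }


@dataclass
class Cohort:
    """Bundle of simulated inputs plus ground-truth labels."""

    config: CohortConfig
    agents: dict[str, AgentSpec]
    profiles: dict[str, PerformanceProfile]
    choices: dict[str, PairwiseChoiceData]
    traces: dict[str, dict[str, TitrationTrace]]  # participant -> phase -> trace

    def performance_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "option": opt.key,
                "accuracy": prof[opt],
                "n_trials": prof.n_trials,
            }
            for pid, prof in self.profiles.items()
            for opt in ALL_OPTIONS
        ]
        return pd.DataFrame(rows)

    def choices_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "option_a": a.key,
                "option_b": b.key,
                "n": n,
                "k": k,
            }
            for pid, data in self.choices.items()
            for (a, b), (n, k) in sorted(
                data.counts.items(), key=lambda kv: (kv[0][0].key, kv[0][1].key)
            )
        ]
        return pd.DataFrame(rows)

    def titration_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant": pid,
                "condition": trace.condition,
                "phase": trace.phase,
                "set": rec.set_index,
                "decision": rec.decision_index,
                "secondary_offer": rec.secondary_offer,
                "choice": rec.choice,
                "performed": rec.performed,
            }
            for pid, phases in self.traces.items()
            for trace in phases.values()
            for rec in trace.records
        ]
        return pd.DataFrame(rows)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"participant": pid, "policy": spec.policy, "label": spec.describe()}
                for pid, spec in self.agents.items()
            ]
        )

    def write(self, outdir: str | Path) -> None:
        """Write the fixture CSVs plus a seed manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.performance_frame().to_csv(outdir / "performance.csv", index=False)
        self.choices_frame().to_csv(outdir / "choices.csv", index=False)
        self.titration_frame().to_csv(outdir / "titration.csv", index=False)
        self.truth_frame().to_csv(outdir / "truth.csv", index=False)
        manifest = {
            "master_seed": self.config.master_seed,
            "n_participants": len(self.agents),
            "n_per_policy": self.config.n_per_policy,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _default_agent(policy: str, index: int, config: CohortConfig, profile) -> AgentSpec:
    eps = config.lapse_rate
    if policy == "demand_ranked":
        direction = ("DA", "CS")[index % 2]
        heuristic = ("all", "low", "high")[(index // 2) % 3]
        return AgentSpec(
            policy=policy, direction=direction, heuristic=heuristic, lapse_rate=eps
        )
    if policy == "task_ranked":
        orders = identifiable_task_orders(profile)
        if not orders:  # profile ties every block order; fall back to all perms
            orders = list(
                itertools.permutations((Task.MEMORY, Task.MOTOR, Task.HYBRID))
            )
        return AgentSpec(
            policy=policy, task_order=orders[index % len(orders)], lapse_rate=eps
        )
    if policy == "single_task_bias":
        tasks = (Task.MEMORY, Task.MOTOR, Task.HYBRID)
        return AgentSpec(
            policy=policy,
            biased_task=tasks[index % 3],
            bias_direction=("for", "against")[(index // 3) % 2],
            lapse_rate=eps,
        )
    if policy == "titration_value":
        return AgentSpec(policy=policy, lapse_rate=eps)
    if policy == "titration_loyal":
        return AgentSpec(
            policy=policy,
            loyal_target=("hybrid", "secondary")[index % 2],
            lapse_rate=eps,
        )
    return AgentSpec(policy="random")


def gen_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort: profiles, choice data, titration traces, labels.

    Ranked/bias/random agents get choice-phase data; titration agents get one
    reward and one demand trace. Task-order agents are assigned orders that
    are identifiable against the demand models implied by their own profile.
    Byte-identical output for a fixed master seed.
    """
    ss = np.random.SeedSequence(config.master_seed)
    agents: dict[str, AgentSpec] = {}
    profiles: dict[str, PerformanceProfile] = {}
    choices: dict[str, PairwiseChoiceData] = {}
    traces: dict[str, dict[str, TitrationTrace]] = {}

    pid_counter = 0
    for policy in POLICIES:
        n = config.n_per_policy.get(policy, 0)
        for index in range(n):
            pid_counter += 1
            pid = f"P{pid_counter:03d}"
            child = ss.spawn(1)[0]
            prof_seed, choice_seed, reward_seed, demand_seed = child.spawn(4)
            profile = gen_profile(config, prof_seed, participant=pid)
            agent = _default_agent(policy, index, config, profile)
            agents[pid] = agent
            profiles[pid] = profile
            if policy in ("titration_value", "titration_loyal"):
                condition = ("motor", "memory")[index % 2]
                traces[pid] = {
                    "reward": run_phase(
                        gen_titration_policy(agent, "reward", reward_seed),
                        TitrationConfig.reward(),
                        seed=reward_seed.spawn(1)[0],
                        participant=pid,
                        condition=condition,
                    ),
                    "demand": run_phase(
                        gen_titration_policy(agent, "demand", demand_seed),
                        TitrationConfig.demand(),
                        seed=demand_seed.spawn(1)[0],
                        participant=pid,
                        condition=condition,
                    ),
                }
            else:
                choices[pid] = gen_choice_data(agent, profile, choice_seed)

    return Cohort(
        config=config, agents=agents, profiles=profiles, choices=choices, traces=traces
    )
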