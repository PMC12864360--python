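"""Adjusting-offer titration: the reward (francs) and demand (squares) phases.

Both phases repeatedly offer a choice between the hybrid task at a fixed
offer and a secondary task (motor or memory) whose offer adjusts after each
decision, staircasing toward an indifference point.

Reward phase: both options start at 200 francs; after each decision the
secondary offer moves by 50, 25, 13, 8, 4, 1 francs across the six decisions
of a set — up if the hybrid was chosen, down if the secondary was. Offers
reset to 200 at the start of each of the three sets. Decision francs of the
chosen option accumulate and map to a $1–$5 bonus through fixed payment
bands.

Demand phase: the hybrid is fixed at 4 squares (scaled to match 7 squares of
a single-component task); the secondary task starts at 7 squares and moves
by one square per decision — up if the secondary was chosen, down if the
hybrid was — clamped to [1, 12]. Squares carry across sets.

A participant's phase score is the mean, over sets, of the secondary offer
presented at the sixth decision (the *final offering*).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ValidationError, WrongPhaseError

__all__ = [
    "TitrationConfig",
    "DecisionRecord",
    "TitrationTrace",
    "PaymentSchedule",
    "DEFAULT_PAYMENT_SCHEDULE",
    "next_secondary_offer",
    "run_phase",
    "total_francs",
    "payment_category",
    "final_offer_average",
]

Policy = Callable[[float, float, list["DecisionRecord"]], str]
# signature: (hybrid_offer, secondary_offer, history) -> "hybrid" | "secondary"


@dataclass(frozen=True)
class TitrationConfig:
    """Parameters of one incentive phase."""

    phase: str  # "reward" | "demand"
    initial_secondary_offer: float
    hybrid_offer: float
    adjustments: tuple[float, ...]
    set_length: int = 6
    n_sets: int = 3
    floor: float | None = None
    ceiling: float | None = None
    reset_each_set: bool = True
    min_performed: int = 3
    max_performed: int = 5

    def __post_init__(self):
        if len(self.adjustments) != self.set_length:
            raise ValueError("need one adjustment per decision in a set")
        if self.floor is not None and not (
            self.floor < self.initial_secondary_offer
        ):
            raise ValueError("floor must lie below the initial offer")
        if self.ceiling is not None and self.initial_secondary_offer > self.ceiling:
            raise ValueError("initial offer must not exceed the ceiling")

    @classmethod
    def reward(cls) -> "TitrationConfig":
        """Franc phase: 200-franc start, decreasing adjustment ladder."""
        return cls(
            phase="reward",
            initial_secondary_offer=200,
            hybrid_offer=200,
            adjustments=(50, 25, 13, 8, 4, 1),
            reset_each_set=True,
        )

    @classmethod
    def demand(cls) -> "TitrationConfig":
        """Square phase: secondary starts at 7 squares, hybrid fixed at 4;
        unit steps clamped to [1, 12]; squares persist across sets."""
        return cls(
            phase="demand",
            initial_secondary_offer=7,
            hybrid_offer=4,
            adjustments=(1, 1, 1, 1, 1, 1),
            floor=1,
            ceiling=12,
            reset_each_set=False,
        )


@dataclass(frozen=True)
class DecisionRecord:
    phase: str
    set_index: int  # 1-based
    decision_index: int  # 1..set_length
    secondary_offer: float  # offer PRESENTED at this decision
    choice: str  # "hybrid" | "secondary"
    performed: bool


@dataclass(frozen=True)
class TitrationTrace:
    participant: str
    condition: str  # secondary task: "motor" | "memory"
    phase: str
    records: tuple[DecisionRecord, ...]
    config: TitrationConfig

    def __post_init__(self):
        expected = self.config.n_sets * self.config.set_length
        if len(self.records) not in (0, expected):
            raise ValidationError(
                f"expected {expected} records, got {len(self.records)}"
            )


@dataclass(frozen=True)
class PaymentSchedule:
    """Franc-total bands mapping to dollar bonuses.

    ``upper_bounds[i]`` is the inclusive franc ceiling of band i; totals above
    the last bound earn the top amount. 2,500 francs falls in the $1 band
    (the printed $2 band starts at 2,501).
    """

    upper_bounds: tuple[int, ...] = (2500, 3200, 3900, 4600)
    amounts: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)

    def dollars(self, francs: float) -> float:
        if francs < 0:
            raise ValueError(f"franc total cannot be negative: {francs}")
        for bound, amount in zip(self.upper_bounds, self.amounts):
            if francs <= bound:
                return amount
        return self.amounts[-1]


DEFAULT_PAYMENT_SCHEDULE = PaymentSchedule()


def next_secondary_offer(
    config: TitrationConfig,
    current_offer: float,
    decision_index: int,
    choice: str,
) -> float:
    """Secondary offer presented at the next decision, after one choice.

    Reward phase: the offer rises by the decision's adjustment when the
    hybrid was chosen and falls when the secondary was. Demand phase: the
    square count rises when the secondary was chosen and falls when the
    hybrid was, clamped to [floor, ceiling]. Per-set resets are handled by
    :func:`run_phase`.
    """
    if not 1 <= decision_index <= config.set_length:
        raise ValueError(
            f"decision_index must be in 1..{config.set_length}, got {decision_index}"
        )
    if choice not in ("hybrid", "secondary"):
        raise ValueError(f"unknown choice {choice!r}")
    delta = config.adjustments[decision_index - 1]
    if config.phase == "reward":
        offer = current_offer + delta if choice == "hybrid" else current_offer - delta
    else:
        offer = current_offer - delta if choice == "hybrid" else current_offer + delta
    if config.floor is not None:
        offer = max(offer, config.floor)
    if config.ceiling is not None:
        offer = min(offer, config.ceiling)
    return offer


def run_phase(
    policy: Policy,
    config: TitrationConfig,
    seed: int | None = None,
    participant: str = "sim",
    condition: str = "motor",
) -> TitrationTrace:
    """Simulate one full phase (n_sets x set_length decisions) under a policy.

    Three to five decisions per set are randomly flagged as performed,
    reproducibly from ``seed``. The policy sees the current offers and the
    decision history.
    """
    rng = np.random.default_rng(seed)
    records: list[DecisionRecord] = []
    offer = config.initial_secondary_offer
    for set_index in range(1, config.n_sets + 1):
        if config.reset_each_set:
            offer = config.initial_secondary_offer
        n_perf = int(rng.integers(config.min_performed, config.max_performed + 1))
        performed_at = set(
            rng.choice(config.set_length, size=n_perf, replace=False)
        )
        for decision_index in range(1, config.set_length + 1):
            choice = policy(config.hybrid_offer, offer, records)
            records.append(
                DecisionRecord(
                    phase=config.phase,
                    set_index=set_index,
                    decision_index=decision_index,
                    secondary_offer=offer,
                    choice=choice,
                    performed=(decision_index - 1) in performed_at,
                )
            )
            offer = next_secondary_offer(config, offer, decision_index, choice)
    return TitrationTrace(
        participant=participant,
        condition=condition,
        phase=config.phase,
        records=tuple(records),
        config=config,
    )


def total_francs(trace: TitrationTrace) -> float:
    """Sum of the chosen option's offer over every decision of a reward trace."""
    if trace.phase != "reward":
        raise WrongPhaseError(
            f"franc totals are defined for the reward phase, got {trace.phase!r}"
        )
    total = 0.0
    for rec in trace.records:
        total += (
            trace.config.hybrid_offer if rec.choice == "hybrid" else rec.secondary_offer
        )
    return total


def payment_category(
    francs: float, schedule: PaymentSchedule = DEFAULT_PAYMENT_SCHEDULE
) -> float:
    """Dollar bonus earned by a franc total under the payment bands."""
    return schedule.dollars(francs)


def final_offer_average(trace: TitrationTrace) -> float:
    """Mean secondary offer presented at the sixth decision of each set."""
    finals = []
    for set_index in range(1, trace.config.n_sets + 1):
        match = [
            r
            for r in trace.records
            if r.set_index == set_index
            and r.decision_index == trace.config.set_length
        ]
        if not match:
            raise ValidationError(
                f"set {set_index} is missing its final (decision "
                f"{trace.config.set_length}) record"
            )
        finals.append(match[0].secondary_offer)
    return float(np.mean(finals))
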