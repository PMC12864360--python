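"""Construction of the 12 candidate preference models.

Six *demand-related* models are built per participant from their practice
accuracy: a demand-avoidant (DA) ranking prefers options the participant
performs best on, a challenge-seeking (CS) ranking prefers options they
perform worst on, and each direction is combined with one of three scoring
heuristics — ``all`` (each option scored by its own accuracy), ``low``
(every option scored by its task's low-demand accuracy) and ``high``
(scored by the task's high-demand accuracy).

Six *task-order* models are fixed across participants: one per permutation
of the three tasks, constraining every option of a higher-ranked task to be
chosen over every option of a lower-ranked task, with the three within-task
pairs left unconstrained.

Every model is a set of directional pairwise constraints "the winner is
chosen over the loser more than half the time" (a modal-choice
specification); constraint sets are acyclic and transitively closed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

from .errors import IncompleteProfileError
from .options import ALL_OPTIONS, Level, OptionId, Task, canonical_pair, parse_option

__all__ = [
    "PerformanceProfile",
    "PreferenceModel",
    "score_options",
    "rank_options",
    "build_demand_models",
    "build_task_models",
    "build_all_models",
    "DIRECTIONS",
    "HEURISTICS",
]

DIRECTIONS = ("DA", "CS")
HEURISTICS = ("all", "low", "high")


@dataclass(frozen=True)
class PerformanceProfile:
    """Per-option practice accuracy for one participant.

    Accuracy is the proportion correct over ``n_trials`` practice trials per
    option (15 in the experiment).
    """

    participant: str
    accuracy: dict[OptionId, float]
    n_trials: int = 15

    def __post_init__(self):
        missing = [o for o in ALL_OPTIONS if o not in self.accuracy]
        if missing:
            raise IncompleteProfileError(missing)
        for opt, acc in self.accuracy.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"accuracy for {opt} out of [0, 1]: {acc}")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    def __getitem__(self, option: OptionId) -> float:
        return self.accuracy[option]


@dataclass(frozen=True)
class PreferenceModel:
    """A named set of directional pairwise constraints over the six options.

    ``constraints`` holds ordered (winner, loser) pairs; a pair absent in
    both directions is unconstrained and contributes nothing to the Bayes
    factor. ``tie_flag`` marks demand models in which exact cross-task score
    ties forced some pairs to be dropped.
    """

    model_id: str
    family: str  # "demand" | "task"
    constraints: frozenset[tuple[OptionId, OptionId]]
    direction: str | None = None  # "DA" | "CS" for demand models
    heuristic: str | None = None  # "all" | "low" | "high" for demand models
    task_order: tuple[Task, ...] | None = None  # for task models
    tie_flag: bool = False

    def __post_init__(self):
        seen = set()
        for w, l in self.constraints:
            if (l, w) in self.constraints:
                raise ValueError(f"pair {w}/{l} constrained in both directions")
            seen.add(canonical_pair(w, l))
        if len(seen) != len(self.constraints):
            raise ValueError("duplicate constraint on an unordered pair")

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def winner(self, a: OptionId, b: OptionId) -> OptionId | None:
        """Constrained winner of the unordered pair {a, b}, or None."""
        if (a, b) in self.constraints:
            return a
        if (b, a) in self.constraints:
            return b
        return None

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "family": self.family,
            "constraints": sorted(
                [w.key, l.key] for w, l in self.constraints
            ),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, payload: str) -> "PreferenceModel":
        d = json.loads(payload)
        cons = frozenset(
            (parse_option(w), parse_option(l)) for w, l in d["constraints"]
        )
        return cls(model_id=d["model_id"], family=d["family"], constraints=cons)


def score_options(
    profile: PerformanceProfile, heuristic: str
) -> dict[OptionId, float]:
    """Score each option under a demand heuristic.

    ``all`` scores an option by its own accuracy; ``low``/``high`` score both
    options of a task by that task's low-/high-demand accuracy, so the two
    options of a task are tied by construction.
    """
    if heuristic not in HEURISTICS:
        raise ValueError(f"unknown heuristic {heuristic!r}")
    if heuristic == "all":
        return {o: profile[o] for o in ALL_OPTIONS}
    level = Level.LOW if heuristic == "low" else Level.HIGH
    return {o: profile[OptionId(o.task, level)] for o in ALL_OPTIONS}


def rank_options(
    profile: PerformanceProfile, heuristic: str, direction: str
) -> PreferenceModel:
    """Build one demand-related model by ranking options on their scores.

    DA ranks by descending score (prefer options with the best performance),
    CS by ascending score. Under the low/high heuristics the two options of a
    task are tied by construction and ordered low-before-high for DA,
    high-before-low for CS. Exact cross-task score ties leave those pairs
    unconstrained and set ``tie_flag``.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    scores = score_options(profile, heuristic)

    constraints: set[tuple[OptionId, OptionId]] = set()
    tie_flag = False
    for a, b in itertools.combinations(ALL_OPTIONS, 2):
        same_task = a.task == b.task
        if same_task and heuristic in ("low", "high"):
            # tied by construction: ordered by the family's motivation
            low, high = (a, b) if a.level == Level.LOW else (b, a)
            constraints.add((low, high) if direction == "DA" else (high, low))
            continue
        sa, sb = scores[a], scores[b]
        if sa == sb:
            tie_flag = True
            continue
        better = a if sa > sb else b
        worse = b if better is a else a
        if direction == "DA":
            constraints.add((better, worse))
        else:
            constraints.add((worse, better))

    return PreferenceModel(
        model_id=f"{direction}-{heuristic}",
        family="demand",
        constraints=frozenset(constraints),
        direction=direction,
        heuristic=heuristic,
        tie_flag=tie_flag,
    )


def build_demand_models(profile: PerformanceProfile) -> list[PreferenceModel]:
    """The six performance-dependent models: {DA, CS} x {all, low, high}."""
    return [
        rank_options(profile, heuristic, direction)
        for direction in DIRECTIONS
        for heuristic in HEURISTICS
    ]


def _task_model_id(order: tuple[Task, ...]) -> str:
    return "TASK-" + "-".join(t.value for t in order)


def build_task_models() -> list[PreferenceModel]:
    """The six fixed task-order models, one per permutation of the tasks.

    Each model constrains the 12 inter-task pairs (every option of a
    higher-ranked task beats every option of a lower-ranked task); the three
    within-task pairs stay unconstrained. Participant-independent.
    """
    models = []
    for order in itertools.permutations((Task.MEMORY, Task.MOTOR, Task.HYBRID)):
        rank = {task: i for i, task in enumerate(order)}
        constraints = set()
        for a, b in itertools.combinations(ALL_OPTIONS, 2):
            if a.task == b.task:
                continue
            if rank[a.task] < rank[b.task]:
                constraints.add((a, b))
            else:
                constraints.add((b, a))
        models.append(
            PreferenceModel(
                model_id=_task_model_id(order),
                family="task",
                constraints=frozenset(constraints),
                task_order=order,
            )
        )
    return models


def build_all_models(profile: PerformanceProfile) -> list[PreferenceModel]:
    """The full 12-model battery for one participant."""
    return build_demand_models(profile) + build_task_models()
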