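import pytest

from effortchoice import (
    ALL_PAIRS,
    Level,
    OptionId,
    PairwiseChoiceData,
    PerformanceProfile,
    Task,
)


def opt(task: str, level: str) -> OptionId:
    return OptionId(Task(task), Level(level))


@pytest.fixture
def group_mean_profile() -> PerformanceProfile:
    """Cohort-average practice accuracies for the six options."""
    return PerformanceProfile(
        participant="group-mean",
        accuracy={
            opt("motor", "low"): 0.883,
            opt("motor", "high"): 0.757,
            opt("memory", "low"): 0.837,
            opt("memory", "high"): 0.709,
            opt("hybrid", "low"): 0.842,
            opt("hybrid", "high"): 0.625,
        },
    )


@pytest.fixture
def uniform_profile() -> PerformanceProfile:
    """Degenerate profile: every option at 50% accuracy."""
    return PerformanceProfile(
        participant="uniform",
        accuracy={opt(t, l): 0.5 for t in ("memory", "motor", "hybrid") for l in ("low", "high")},
    )


def make_choice_data(participant="p1", n=6, k_fn=None) -> PairwiseChoiceData:
    """Choice data with k per canonical pair given by k_fn(a, b) (default n/2)."""
    counts = {}
    for a, b in ALL_PAIRS:
        k = k_fn(a, b) if k_fn is not None else n // 2
        counts[(a, b)] = (n, k)
    return PairwiseChoiceData(participant=participant, counts=counts)


def consistent_data(model, participant="p1", n=6) -> PairwiseChoiceData:
    """Data perfectly consistent with a model: k = n toward each winner,
    unconstrained pairs split evenly."""

    def k_fn(a, b):
        w = model.winner(a, b)
        if w is None:
            return n // 2
        return n if w == a else 0

    return make_choice_data(participant=participant, n=n, k_fn=k_fn)
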