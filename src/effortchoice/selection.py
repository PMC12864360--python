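"""Model/Results interface over the order-constrained Bayes-factor engine.

`PreferenceSelection` bundles one participant's pairwise choice data with a
candidate battery of preference models (by default the standard 12: six
demand-related models built from the participant's performance profile plus
the six fixed task-order models). `fit()` computes the encompassing-prior
Bayes factor of every model and returns a `PreferenceSelectionResults`
carrying the BFs, the two-criterion classification, bias diagnostics and a
printable summary, in the spirit of statsmodels' Model/Results split.
"""

from __future__ import annotations

import pandas as pd

from .bayes import (
    DEFAULT_THRESHOLD,
    BiasResult,
    Classification,
    FitResult,
    classify,
    fit_models,
    task_bias_test,
)
from .choices import PairwiseChoiceData
from .models import PerformanceProfile, PreferenceModel, build_all_models
from .options import Task

__all__ = ["PreferenceSelection", "PreferenceSelectionResults"]


class PreferenceSelection:
    """Order-constrained Bayesian model selection for one participant.

    Parameters
    ----------
    data
        Pairwise choice counts over the 15 option pairs.
    models
        Candidate models. If omitted, ``profile`` must be given and the
        standard 12-model battery is built from it.
    profile
        Practice performance, used to construct the demand-related models.
    """

    def __init__(
        self,
        data: PairwiseChoiceData,
        models: list[PreferenceModel] | None = None,
        profile: PerformanceProfile | None = None,
    ):
        if models is None:
            if profile is None:
                raise ValueError("supply either models or a performance profile")
            models = build_all_models(profile)
        self.data = data
        self.models = list(models)
        self.profile = profile

    @classmethod
    def from_dataframes(
        cls,
        choices: pd.DataFrame,
        performance: pd.DataFrame,
        participant: str,
    ) -> "PreferenceSelection":
        """Build from tidy tables (see :mod:`effortchoice.io` for schemas)."""
        from .io import choices_from_frame, profile_from_frame

        data = choices_from_frame(choices, participant)
        profile = profile_from_frame(performance, participant)
        return cls(data, profile=profile)

    def fit(self, threshold: float = DEFAULT_THRESHOLD) -> "PreferenceSelectionResults":
        fit = fit_models(self.models, self.data)
        cls_ = classify(fit, threshold=threshold)
        return PreferenceSelectionResults(self, fit, cls_, threshold)


class PreferenceSelectionResults:
    """Fitted Bayes factors and classification for one participant."""

    def __init__(
        self,
        model: PreferenceSelection,
        fit: FitResult,
        classification: Classification,
        threshold: float,
    ):
        self.model = model
        self.fit_result = fit
        self.classification = classification
        self.threshold = threshold

    @property
    def bayes_factors(self) -> pd.Series:
        return pd.Series(self.fit_result.bf, name="bayes_factor").sort_values(
            ascending=False
        )

    @property
    def category(self) -> str:
        return self.classification.category

    @property
    def best_model(self) -> str | None:
        return self.classification.best_model

    def task_bias(self, task: Task | str) -> BiasResult:
        """Single-task bias test on this participant's data."""
        return task_bias_test(self.model.data, Task(task), threshold=self.threshold)

    def to_frame(self) -> pd.DataFrame:
        """One row per model: BF, constraint count, family."""
        fr = self.fit_result
        return pd.DataFrame(
            {
                "participant": fr.participant,
                "model_id": list(fr.bf),
                "family": [fr.family[m] for m in fr.bf],
                "n_constraints": [fr.n_constraints[m] for m in fr.bf],
                "bayes_factor": [fr.bf[m] for m in fr.bf],
            }
        ).sort_values("bayes_factor", ascending=False, ignore_index=True)

    def summary(self) -> str:
        cls_ = self.classification
        lines = [
            "Order-constrained preference model selection",
            "=" * 44,
            f"participant:     {self.fit_result.participant}",
            f"models fitted:   {len(self.fit_result.bf)}",
            f"threshold:       BF > {self.threshold} (both criteria, strict)",
            f"category:        {cls_.category}",
        ]
        if cls_.best_model is not None:
            lines += [
                f"best model:      {cls_.best_model} (BF = {cls_.best_bf:.4g})",
                f"runner-up BF:    {cls_.runnerup_bf:.4g}",
            ]
        lines.append("-" * 44)
        for model_id, bf in self.bayes_factors.items():
            lines.append(f"{model_id:<28s} BF = {bf:.4g}")
        return "\n".join(lines)
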