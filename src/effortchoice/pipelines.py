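"""End-to-end pipeline drivers for the two experiments.

Experiment 1: per participant, build the 12-model battery from the practice
profile, compute encompassing-prior Bayes factors on the pairwise choices,
classify with the two 3.12 criteria, and run the single-task bias test on
participants without a best-fitting model.

Experiment 2: per participant and incentive phase, average the final
(sixth-decision) secondary offers across sets, z-score between subjects
within each phase, and report the Pearson correlation between phases plus
each phase's excess kurtosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .bayes import DEFAULT_THRESHOLD, classify, fit_models, task_bias_test
from .choices import PairwiseChoiceData
from .errors import DegenerateInputError
from .models import PerformanceProfile, build_all_models
from .options import Task
from .scoring import excess_kurtosis, pearson, reverse_demand_scale, zscores
from .titration import TitrationTrace, final_offer_average

__all__ = ["Exp1Result", "Exp2Result", "run_exp1_pipeline", "run_exp2_pipeline"]

logger = logging.getLogger("effortchoice")


@dataclass
class Exp1Result:
    """Tables produced by the choice-phase model-selection pipeline."""

    fits: pd.DataFrame  # one row per participant x model
    classifications: pd.DataFrame  # one row per participant
    biases: pd.DataFrame  # one row per no-best-fit participant x task
    category_counts: dict[str, int] = field(default_factory=dict)
    bias_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class Exp2Result:
    """Tables produced by the titration scoring pipeline."""

    scores: pd.DataFrame  # participant, phase, final_offer_mean, z
    summary: dict  # pearson r, per-phase kurtosis


def run_exp1_pipeline(
    profiles: dict[str, PerformanceProfile],
    choices: dict[str, PairwiseChoiceData],
    threshold: float = DEFAULT_THRESHOLD,
) -> Exp1Result:
    """Fit and classify every participant with both profile and choice data.

    Participants present in only one of the two inputs are logged and
    skipped, never silently dropped.
    """
    fit_rows, class_rows, bias_rows = [], [], []
    shared = sorted(set(profiles) & set(choices))
    for pid in sorted(set(profiles) ^ set(choices)):
        which = "choices" if pid in profiles else "profile"
        logger.warning("participant %s skipped: missing %s", pid, which)

    for pid in shared:
        models = build_all_models(profiles[pid])
        fit = fit_models(models, choices[pid])
        cls_ = classify(fit, threshold=threshold)
        logger.info(
            "participant %s: category=%s best=%s bf=%s",
            pid,
            cls_.category,
            cls_.best_model,
            f"{cls_.best_bf:.4g}" if cls_.best_bf is not None else "-",
        )
        for model_id, bf in fit.bf.items():
            fit_rows.append(
                {
                    "participant": pid,
                    "model_id": model_id,
                    "family": fit.family[model_id],
                    "n_constraints": fit.n_constraints[model_id],
                    "bayes_factor": bf,
                }
            )
        class_rows.append(
            {
                "participant": pid,
                "category": cls_.category,
                "best_model": cls_.best_model,
                "best_bf": cls_.best_bf,
                "runnerup_bf": cls_.runnerup_bf,
            }
        )
        if cls_.category == "no_best_fit":
            for task in Task:
                bias = task_bias_test(choices[pid], task, threshold=threshold)
                bias_rows.append(
                    {
                        "participant": pid,
                        "task": task.value,
                        "direction": bias.direction,
                        "bf": bias.bf,
                        "k": bias.k,
                        "n": bias.n,
                    }
                )

    classifications = pd.DataFrame(
        class_rows,
        columns=["participant", "category", "best_model", "best_bf", "runnerup_bf"],
    )
    biases = pd.DataFrame(
        bias_rows, columns=["participant", "task", "direction", "bf", "k", "n"]
    )
    category_counts = (
        classifications["category"].value_counts().to_dict()
        if not classifications.empty
        else {}
    )
    if biases.empty:
        bias_counts = {}
    else:
        grouped = (
            biases[biases["direction"] != "none"]
            .groupby(["task", "direction"])
            .size()
            .to_dict()
        )
        bias_counts = {f"{t}:{d}": int(c) for (t, d), c in grouped.items()}
    return Exp1Result(
        fits=pd.DataFrame(
            fit_rows,
            columns=[
                "participant",
                "model_id",
                "family",
                "n_constraints",
                "bayes_factor",
            ],
        ),
        classifications=classifications,
        biases=biases,
        category_counts=category_counts,
        bias_counts=bias_counts,
    )


def run_exp2_pipeline(
    traces: dict[str, dict[str, TitrationTrace]],
    reverse_demand: bool = False,
) -> Exp2Result:
    """Score titration traces and correlate the two incentive phases.

    ``reverse_demand`` flips the demand-phase z scale so that both axes read
    "more willing to take the secondary task" in the same direction (used
    for reporting; the correlation sign flips accordingly).
    """
    rows = []
    for pid, phases in sorted(traces.items()):
        for phase, trace in sorted(phases.items()):
            rows.append(
                {
                    "participant": pid,
                    "condition": trace.condition,
                    "phase": phase,
                    "final_offer_mean": final_offer_average(trace),
                }
            )
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise DegenerateInputError("no titration traces supplied")

    scores["z"] = float("nan")
    for phase, sub in scores.groupby("phase"):
        z = zscores(sub["final_offer_mean"].to_numpy())
        scores.loc[sub.index, "z"] = z
    if reverse_demand:
        demand_mask = scores["phase"] == "demand"
        scores.loc[demand_mask, "z"] = reverse_demand_scale(
            scores.loc[demand_mask, "z"].to_numpy()
        )

    wide = scores.pivot(index="participant", columns="phase", values="z").dropna()
    summary: dict = {"reverse_demand": reverse_demand}
    if {"reward", "demand"} <= set(wide.columns) and len(wide) >= 3:
        summary["pearson_r"] = pearson(
            wide["reward"].to_numpy(), wide["demand"].to_numpy()
        )
    for phase, sub in scores.groupby("phase"):
        if len(sub) >= 4:
            summary[f"kurtosis_{phase}"] = excess_kurtosis(
                sub["final_offer_mean"].to_numpy()
            )
    return Exp2Result(scores=scores, summary=summary)
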