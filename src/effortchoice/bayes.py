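"""Order-constrained Bayes factors for pairwise binary choice.

Each preference model restricts the 15 pair choice probabilities
``p_ij = P(choose i over j)`` to a region of the hypercube: ``p > 1/2`` on
every constrained pair (modal choice). With independent Uniform(0, 1) priors
on each pair probability (the *encompassing* prior) and binomial likelihoods,
the Bayes factor of a constrained model against the unconstrained
encompassing model is the ratio of posterior to prior mass of the constraint
region:

    BF = [ prod over constraints  P(p > 1/2 | Beta(1 + k, 1 + n - k)) ]
         / (1/2)^m

for m constraints, where k of n choices in a pair went to the constraint's
winner. Independence across pairs makes both masses products, so the BF has
this closed form; :func:`mc_oracle_bayes_factor` re-estimates it by brute
Monte Carlo as an independent check. Models are compared to each other by the
ratio of their encompassing BFs.

Model selection follows two criteria: the best model's BF must exceed 3.12
(substantial evidence on the Kass–Raftery scale), and the ratio of best to
second-best BF must also exceed 3.12; otherwise the participant is
classified *no best fit*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .choices import PairwiseChoiceData
from .models import PreferenceModel
from .options import ALL_PAIRS, Task

__all__ = [
    "pair_posterior_prob",
    "prior_mass",
    "bayes_factor",
    "mc_oracle_bayes_factor",
    "fit_models",
    "classify",
    "task_bias_test",
    "FitResult",
    "Classification",
    "BiasResult",
    "DEFAULT_THRESHOLD",
]

#: Kass & Raftery "substantial evidence" cut-off used by both selection criteria.
DEFAULT_THRESHOLD = 3.12


def pair_posterior_prob(k: int, n: int) -> float:
    """P(p > 1/2) under the Beta(1 + k, 1 + n - k) posterior from a flat prior.

    ``k`` of ``n`` choices went to the putative winner of a pair.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    # P(p > 1/2 | Beta(a, b)) = I_{1/2}(b, a) by symmetry of the regularized
    # incomplete beta function.
    return float(special.betainc(n - k + 1, k + 1, 0.5))


def prior_mass(model: PreferenceModel) -> float:
    """Prior probability of the constraint region: (1/2)^m for m constraints."""
    return 0.5 ** model.n_constraints


def bayes_factor(model: PreferenceModel, data: PairwiseChoiceData) -> float:
    """Closed-form encompassing-prior Bayes factor of ``model`` given ``data``.

    Unconstrained pairs contribute nothing; the empty model has BF exactly 1.
    """
    posterior = 1.0
    for winner, loser in model.constraints:
        k, n = data.wins(winner, loser)
        posterior *= pair_posterior_prob(k, n)
    return posterior / prior_mass(model)


def mc_oracle_bayes_factor(
    model: PreferenceModel,
    data: PairwiseChoiceData,
    n_samples: int = 10**6,
    seed: int | None = None,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo estimate of the same Bayes factor.

    Draws independent per-pair samples from the Beta posteriors and from the
    uniform prior and estimates BF as the ratio of the fractions landing in
    the constraint region. Returns ``(estimate, standard_error)``; the SE is
    the delta-method propagation of the two binomial fractions. Deterministic
    given ``seed``. This estimator is deliberately independent of
    :func:`bayes_factor` and serves as its oracle.
    """
    if n_samples < 10**4:
        raise ValueError("n_samples must be at least 10^4 for a usable estimate")
    if model.n_constraints == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    cons = sorted(model.constraints, key=lambda wl: (wl[0].key, wl[1].key))

    post_in = np.ones(n_samples, dtype=bool)
    prior_in = np.ones(n_samples, dtype=bool)
    for winner, loser in cons:
        k, n = data.wins(winner, loser)
        post_in &= rng.beta(1 + k, 1 + n - k, size=n_samples) > 0.5
        prior_in &= rng.random(n_samples) > 0.5

    f_post = post_in.mean()
    f_prior = prior_in.mean()
    if f_prior == 0.0:
        raise RuntimeError(
            "no prior draws fell inside the constraint region; increase n_samples"
        )
    bf = f_post / f_prior
    # delta-method SE; if no posterior hit landed, bound the numerator
    # variance by one pseudo-hit so the SE is not spuriously zero
    fp = max(f_post, 1.0 / n_samples)
    var = (bf**2 if f_post > 0 else (fp / f_prior) ** 2) * (
        (1 - fp) / (fp * n_samples) + (1 - f_prior) / (f_prior * n_samples)
    )
    return float(bf), float(math.sqrt(var))


@dataclass(frozen=True)
class FitResult:
    """Bayes factors of a model battery for one participant."""

    participant: str
    bf: dict[str, float]
    n_constraints: dict[str, int]
    family: dict[str, str]

    def best_two(self) -> tuple[tuple[str, float], tuple[str, float]]:
        """(best, second-best) as (model_id, bf), ties broken by model id."""
        ranked = sorted(self.bf.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) == 1:
            return ranked[0], (None, 0.0)
        return ranked[0], ranked[1]


@dataclass(frozen=True)
class Classification:
    """Per-participant model-selection outcome."""

    participant: str
    category: str  # "demand_related" | "task_driven" | "no_best_fit"
    best_model: str | None
    best_bf: float | None
    runnerup_bf: float | None


@dataclass(frozen=True)
class BiasResult:
    """Single-task bias verdict for one participant and task.

    ``bf_for``/``bf_against`` are point-null Bayes factors (marginal
    likelihood of the pooled count under p ~ Uniform(1/2, 1), resp.
    Uniform(0, 1/2), against the p = 1/2 point null). The simple
    encompassing-prior versions are retained as diagnostics.
    """

    participant: str
    task: Task
    direction: str  # "for" | "against" | "none"
    bf: float
    bf_for: float
    bf_against: float
    bf_for_encompassing: float
    bf_against_encompassing: float
    k: int
    n: int


def fit_models(
    models: list[PreferenceModel], data: PairwiseChoiceData
) -> FitResult:
    """Closed-form Bayes factor for every model; order-independent."""
    if not models:
        raise ValueError("at least one model is required")
    bf: dict[str, float] = {}
    ncon: dict[str, int] = {}
    fam: dict[str, str] = {}
    for m in models:
        bf[m.model_id] = bayes_factor(m, data)
        ncon[m.model_id] = m.n_constraints
        fam[m.model_id] = m.family
    return FitResult(
        participant=data.participant, bf=bf, n_constraints=ncon, family=fam
    )


_CATEGORY = {"demand": "demand_related", "task": "task_driven"}


def classify(fit: FitResult, threshold: float = DEFAULT_THRESHOLD) -> Classification:
    """Apply the two selection criteria (both strict) to a fitted battery."""
    (best_id, best_bf), (_, second_bf) = fit.best_two()
    ratio_ok = best_bf > threshold * second_bf if second_bf > 0 else best_bf > 0
    if best_bf > threshold and ratio_ok:
        return Classification(
            participant=fit.participant,
            category=_CATEGORY[fit.family[best_id]],
            best_model=best_id,
            best_bf=best_bf,
            runnerup_bf=second_bf,
        )
    return Classification(
        participant=fit.participant,
        category="no_best_fit",
        best_model=None,
        best_bf=None,
        runnerup_bf=None,
    )


def _pooled_task_count(data: PairwiseChoiceData, task: Task) -> tuple[int, int]:
    """Pooled (K, N) over the 8 inter-task pairs involving ``task``."""
    K = N = 0
    for a, b in ALL_PAIRS:
        a_in, b_in = a.task == task, b.task == task
        if a_in == b_in:  # within-task pair, or pair not involving the task
            continue
        n, k = data.counts[(a, b)]
        N += n
        K += k if a_in else n - k
    return K, N


def _point_null_bf(K: int, N: int, upper: bool) -> float:
    """BF of p ~ Uniform(1/2, 1) (or (0, 1/2)) against the p = 1/2 point null."""
    # marginal likelihood: 2 * C(N,K) * B(K+1, N-K+1) * P(Beta(K+1,N-K+1) in half)
    #                    = 2/(N+1) * I-half-mass;  null likelihood: C(N,K) 2^-N
    if upper:
        half_mass = special.betainc(N - K + 1, K + 1, 0.5)
    else:
        half_mass = special.betainc(K + 1, N - K + 1, 0.5)
    log_marg = math.log(2.0) - math.log(N + 1) + _safe_log(half_mass)
    log_null = float(
        special.gammaln(N + 1)
        - special.gammaln(K + 1)
        - special.gammaln(N - K + 1)
        - N * math.log(2.0)
    )
    return math.exp(log_marg - log_null)


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def task_bias_test(
    data: PairwiseChoiceData, task: Task, threshold: float = DEFAULT_THRESHOLD
) -> BiasResult:
    """Test whether choices show a bias for or against one task.

    Pools the 48 inter-task choices involving ``task`` (8 pairs x 6
    presentations) and asks whether the rate of choosing that task's options
    departs from chance in either direction, separating genuine single-task
    preferences from random responding.
    """
    K, N = _pooled_task_count(data, task)
    bf_for = _point_null_bf(K, N, upper=True)
    bf_against = _point_null_bf(K, N, upper=False)
    enc_for = pair_posterior_prob(K, N) / 0.5
    enc_against = pair_posterior_prob(N - K, N) / 0.5

    if bf_for > threshold and bf_for >= bf_against:
        direction, bf = "for", bf_for
    elif bf_against > threshold:
        direction, bf = "against", bf_against
    else:
        direction, bf = "none", max(bf_for, bf_against)
    return BiasResult(
        participant=data.participant,
        task=task,
        direction=direction,
        bf=bf,
        bf_for=bf_for,
        bf_against=bf_against,
        bf_for_encompassing=enc_for,
        bf_against_encompassing=enc_against,
        k=K,
        n=N,
    )
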