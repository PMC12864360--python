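# effortchoice

Order-constrained Bayesian preference modelling and adjusting-offer
titration for effort-based decision experiments.

## The problem

When people choose between cognitive tasks, are they avoiding demand
(picking what they are good at), seeking challenge, or just loyal to a task
regardless of how well they perform it? `effortchoice` implements a
two-part analysis for experiments built around six task options — a memory,
a motor, and a hybrid (memory + motor) task, each at a low and a high demand
level:

1. **Choice phase.** Each participant makes 90 binary choices (15 option
   pairs × 6 presentations). Twelve ordinal preference models are fitted per
   participant: six *demand-related* rankings derived from their own
   practice accuracy (demand-avoidant DA vs challenge-seeking CS, crossed
   with an `all` / `low` / `high` scoring heuristic), and six fixed
   *task-order* rankings (one per permutation of the three tasks).
2. **Titration phase.** An adjusting-offer staircase pits a fixed hybrid
   task against a secondary task whose offer moves after every decision —
   in experimental francs (reward phase) or in squares of task demand
   (demand phase) — to locate each participant's indifference point.

It is aimed at researchers analysing (or simulating) such cognitive-effort
choice experiments: the package ships a synthetic-cohort generator with
known ground-truth policies, so every stage of the pipeline can be validated
by model recovery without any real data.

## The statistic at the core

Each preference model *M* is a set of *m* pairwise constraints
`P(choose i over j) > 1/2`. With independent Uniform(0,1) priors on each
pair probability `p_ij` and binomial choice counts `k_ij / n_ij`, the
Bayes factor of *M* against the unconstrained (encompassing) model is the
ratio of posterior to prior mass of the constraint region, which factorises:

```
BF_M = ∏ over constraints (i ≻ j)  Pr( p > 1/2 | Beta(1 + k_ij, 1 + n_ij − k_ij) )  /  (1/2)^m
```

A participant is classified as demand-related or task-driven only if the
best model's BF exceeds 3.12 **and** the best/second-best BF ratio exceeds
3.12 (both strict); otherwise they are *no best fit*, and a pooled
beta-binomial test checks for a residual bias for or against a single task.
A brute-force Monte-Carlo estimator of the same Bayes factor
(`mc_oracle_bayes_factor`) is included as an independent numerical check.

## Worked example

```python
from effortchoice import PreferenceSelection
from effortchoice.simulate import AgentSpec, CohortConfig, gen_profile, gen_choice_data

config = CohortConfig(master_seed=11)
profile = gen_profile(config, 42, participant="S01")
agent = AgentSpec(policy="demand_ranked", direction="DA", heuristic="all",
                  lapse_rate=0.05)
data = gen_choice_data(agent, profile, seed=7)

results = PreferenceSelection(data, profile=profile).fit()
print(results.summary())
```

```
Order-constrained preference model selection
============================================
participant:     S01
models fitted:   12
threshold:       BF > 3.12 (both criteria, strict)
category:        demand_related
best model:      DA-all (BF = 1.106e+04)
runner-up BF:    0.003301
--------------------------------------------
DA-all                       BF = 1.106e+04
DA-low                       BF = 0.003301
TASK-motor-memory-hybrid     BF = 9.972e-05
...
```

The simulated agent ranked options by its own accuracy with a 5% lapse
rate; the fit recovers exactly that policy: the DA-all model's constraint
region holds four orders of magnitude more posterior mass than its prior
volume (BF ≈ 1.1 × 10⁴), no rival model comes close, and both selection
criteria are met, so the participant is classified demand-related.

The titration side works the same way from policies to scores:

```python
from effortchoice import TitrationConfig, run_phase, total_francs, payment_category

trace = run_phase(lambda *_: "hybrid", TitrationConfig.reward(), seed=0)
total_francs(trace)          # 3600.0  (18 decisions x 200 francs)
payment_category(3600)       # 3.0     (the $3 band covers 3,201-3,900 francs)
```

There is also a CLI over the same pipelines:

```bash
effortchoice simulate --seed 7 --out cohort/
effortchoice classify --performance cohort/performance.csv \
                      --choices cohort/choices.csv --out exp1/
effortchoice score    --titration cohort/titration.csv --out exp2/
```

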