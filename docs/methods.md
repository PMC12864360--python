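# Methods

This note documents the statistical model, the conventions the package
commits to where the experimental design leaves them open, the synthetic
cohort generator, and the known limitations.

## Preference models

Six options are defined by crossing three tasks (memory, motor, hybrid) with
two demand levels. A preference model is a set of directional constraints
"option *i* is chosen over option *j* more than half the time" — a
modal-choice (majority) specification. Constraint sets are required to be
acyclic and transitively closed; a pair may also be left unconstrained, in
which case it carries no evidence about the model.

**Demand-related models** are built per participant from practice accuracy
(15 trials per option). A scoring heuristic maps the profile to one score
per option: `all` uses each option's own accuracy; `low` / `high` assign
both options of a task that task's low-/high-demand accuracy, deliberately
tying the two within-task options. Demand-avoidant (DA) models rank by
descending score, challenge-seeking (CS) by ascending score. Two
conventions resolve what the scores alone cannot:

* Within-task ties under the `low`/`high` heuristics are ordered
  low-before-high for DA and high-before-low for CS — each family's
  motivation applied to the only remaining dimension.
* Exact cross-task score ties (common on the k/15 accuracy grid) drop the
  affected constraints rather than impose an arbitrary direction, and set a
  `tie_flag` on the model. A tie means the profile expresses no
  performance-based preference for that pair; the Bayes engine handles
  variable constraint counts naturally.

**Task-order models** (one per permutation of the three tasks) constrain
all 12 inter-task pairs and leave the 3 within-task pairs free. They are
participant-independent.

Model ids are stable join keys: `DA-all`, `DA-low`, `DA-high`, `CS-all`,
`CS-low`, `CS-high`, and `TASK-<task>-<task>-<task>`.

## Bayes factors and classification

Choice counts per pair are modelled as independent binomials with
independent Uniform(0,1) priors on each pair probability (the encompassing
prior). The Bayes factor of a constrained model against the encompassing
model is posterior over prior mass of the constraint region; independence
across pairs gives the closed form

    BF = [ ∏ constraints  I_{1/2}(n−k+1, k+1) ] / (1/2)^m ,

where `I` is the regularized incomplete beta function, k of n choices went
to the constrained winner, and m is the number of constraints. The boundary
p = 1/2 has measure zero, so constraints are treated as strict. The empty
model has BF exactly 1, and BFs multiply over disjoint constraint sets —
both identities are asserted in the test suite. `mc_oracle_bayes_factor`
re-estimates the same quantity by Monte Carlo (beta posterior draws over
uniform prior draws, delta-method standard error) and serves as an
independent oracle; closed form and oracle agree within 3 SEs at 10⁶
samples across randomized instances.

Classification uses two strict criteria at the conventional "substantial
evidence" cut-off 3.12: the best model's BF must exceed 3.12, and the
best/second-best ratio must exceed 3.12; otherwise the participant is
*no best fit*. Because every model's BF is computed against the same
encompassing model, the ratio of two models' BFs is their direct pairwise
Bayes factor.

### Single-task bias test

Participants without a best-fitting model may still prefer or avoid one
task while being indifferent between the other two — a pattern no full
ranking captures. The test pools the 8 inter-task pairs involving the task
(48 choices at the default 6 per pair) and compares `p ~ Uniform(1/2, 1)`
(bias for) and `p ~ Uniform(0, 1/2)` (bias against) against the point null
p = 1/2. The simple encompassing-prior version
`P(p > 1/2 | posterior) / (1/2)` is retained as a diagnostic but cannot be
the operative statistic: it is bounded above by 2 regardless of how extreme
the data are, so no bias could ever clear the 3.12 criterion. The
point-null form makes strong biases detectable (48/48 choices give
BF ≈ 10¹³) while balanced data give BF < 1. The test operates at task
level (both of a task's options pooled); an option-level variant can be
obtained by calling it with a single option's pairs.

## Titration phases

Both phases stage 3 sets of 6 decisions between the hybrid task at a fixed
offer and a secondary task whose offer adjusts after each decision.

* **Reward**: both options start at 200 francs; the secondary offer moves
  by 50, 25, 13, 8, 4, 1 francs across the set's six decisions (up when the
  hybrid is chosen, down when the secondary is) and resets to 200 at each
  new set. Decision-6 offers are therefore confined to [100, 300], attained
  exactly by the two constant policies.
* **Demand**: the hybrid is fixed at 4 squares (difficulty-matched to 7
  squares of a single-component task); the secondary starts at 7 squares
  and moves one square per decision (up when chosen, down otherwise),
  clamped to [1, 12]. Squares persist across sets — without carry-over the
  advertised floor of 1 square would be unreachable from 7 with six unit
  decrements, so persistence is the only reading consistent with the design.

Per phase, 3–5 of each set's six decisions are randomly flagged as actually
performed; all scoring is invariant to these flags. Franc totals sum the
chosen option's offer over all 18 decisions (decisions, not performed
blocks, carry the incentive) and map to a $1–$5 bonus through the bands
≤2500 / 2501–3200 / 3201–3900 / 3901–4600 / ≥4601. A total of exactly
2500 francs falls in the $1 band, since the printed $2 band starts at 2501.
The per-phase score is the *final offering*: the secondary offer presented
at (not after) each set's sixth decision, averaged over the three sets.

An exhaustive sweep of all 2⁶ per-set policies confirms the constant
policies' totals (3 × 791 = 2373 and 3 × 1200 = 3600 francs) but also shows
always-hybrid is *not* the franc-maximising strategy: choosing the hybrid
three times to push the secondary offer to 288 and then harvesting it
(H,H,H,S,S,S) yields 1444 per set.

## Between-subject scoring

Final-offer averages are z-scored within each incentive phase using the
between-subject mean and sample (n−1) SD. Excess (Fisher) kurtosis uses the
population-moment estimator, under which the symmetric two-point
distribution gives exactly −2. Correlation between phases is Pearson's r;
the demand-phase scale may be flipped (z → −z) for reporting so both axes
read in the same direction, which flips the sign of r correspondingly.
Degenerate inputs (zero spread, too few values) raise structured errors
rather than returning NaNs.

## Synthetic cohorts

The generator produces the inputs the analysis assumes, with ground-truth
labels retained for recovery scoring.

* **Accuracy profiles** are drawn per option from beta distributions with
  means at the tasks' calibration targets — 0.80 for low-demand and 0.60
  for high-demand options — and concentration 35 (between-subject SD ≈
  0.07, a realistic spread for difficulty-calibrated tasks), then
  discretized to the k/15 grid of the practice block.
* **Choice policies**: ranked agents (demand- or task-ordered) choose their
  model's winner with probability 1 − ε and lapse with probability ε
  (default ε = 0.05), and choose at 1/2 on unconstrained pairs;
  single-task-bias agents apply 1 − ε only to inter-task pairs involving
  their task; random agents choose at 1/2 everywhere. A lapse model is used
  rather than a softmax on score differences so the generator injects no
  cardinal information the ordinal models could not express.
* **Titration agents**: value agents take the secondary task when its offer
  beats the hybrid's by at least τ francs (ties toward the secondary, an
  arbitrary documented choice) or its demand is below λ squares; loyal
  agents always take their target. Both lapse at rate ε.

All randomness flows from a master seed through `numpy.random.SeedSequence`
spawning, so cohorts are byte-identical on regeneration.

What the generator does **not** emulate: learning or fatigue across trials
(profiles are static), sequential dependence between choices (pair choices
are exchangeable binomials), and cardinal utility differences. Passing
recovery tests therefore show that the pipeline identifies the policies it
models, not that real participants are free of history effects.

### Identifiability

Two structural limits of the six-option design are surfaced explicitly:

* On the k/15 grid, exact accuracy ties are common; they drop constraints
  and can make two demand models (e.g. DA-low and DA-high when the tasks
  rank identically on both levels) share a constraint set exactly. Such
  duplicated models can never satisfy the best/second-best ratio criterion.
  `generating_model_is_identifiable` screens for this, and the recovery
  study (`recovery_study`) conditions on it, as well as assigning task
  agents orders that avoid their profile's block-order permutations
  (`identifiable_task_orders`).
* When a low/high-heuristic demand model's inter-task pattern coincides
  with a task model and the within-task pairs split evenly, the two Bayes
  factors coincide exactly and the participant is no-best-fit by
  construction — demonstrated in the test suite.

### False positives under random responding

With only 6 presentations per pair, single-pair evidence is weak
(posterior mass between 0.008 and 0.992), but products over 12–15 pairs
have heavy-tailed variation: a 12-constraint task model clears BF > 3.12 on
pure-chance data roughly 8% of the time, and with twelve candidate models
the double criterion still admits ≈ 20% of random responders (measured
76–82% no-best-fit across seeds at n = 500). This is a property of the
selection procedure at this sample size, not of the implementation — the
closed form is verified against the Monte-Carlo oracle — and should be kept
in mind when interpreting demand/task classifications of noisy
participants. The single-task bias test is far more conservative: ~97% of
per-task tests on random data return "none".

## Numerical choices and problem sizes

* Beta tail probabilities use `scipy.special.betainc` directly; Bayes
  factors are plain double-precision products (≤ 15 factors, no underflow
  at the magnitudes involved). The bias test works in log space.
* The Monte-Carlo oracle refuses fewer than 10⁴ samples and raises when no
  prior draw lands in the constraint region; with zero posterior hits the
  SE is floored at one pseudo-hit to avoid a spuriously zero error bar.
* Default simulation sizes — 100 agents per family for recovery, 100 random
  responders, 20 oracle instances at 10⁶ samples, 20-agent titration
  cohorts — keep the full validation run to a few seconds while leaving
  Monte-Carlo error well below the margins being asserted.
* `classify` breaks exact BF ties by model id for determinism; an exact tie
  at the top always yields no-best-fit because the ratio criterion is
  strict.

## Limitations

* The 3.12 double criterion's false-positive rate under random responding
  (above) is the main interpretive caveat.
* The bias test's point-null form answers "is there any bias", not "how
  large"; its BF is not comparable in scale to the ranking models' BFs.
* Payment banding assigns 2500 francs to the lower band by convention; the
  printed bands leave that single value unassigned.
* The optional CSV loaders expect the package's own tidy schemas; mapping a
  foreign deposit's layout onto them is left to a thin user-written hook.
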