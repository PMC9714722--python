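# Methods

## Decision model

Persuasive attempts are modeled as a finite MDP ⟨S, A, R, T, γ⟩ over 8
abstract states and 5 actions (persuasion types). Learning is batch and
purely tabular: a training log of transitions ⟨s, a, r, s′⟩ is turned into
weighted empirical tables

- R(s, a, s′) = weighted mean reward of matching transitions,
- T(s, a, ·) = weighted relative frequency of observed next states,

and Q-values solve Q(s,a) = Σ_s′ T(s,a,s′)[R(s,a,s′) + γ max_a′ Q(s′,a′)]
by synchronous value iteration. There is no online learning, exploration,
or function approximation; the intended deployment retrains from the frozen
batch when needed.

### Complexity levels

The four nested policy rules are: (1) argmax of the overall mean reward,
state-blind; (2) argmax of the state-conditional mean reward; (3) greedy on
Q from uniformly weighted estimates; (4) greedy on Q from
similarity-weighted estimates, one policy per target person. Level 2's
criterion is computed as Σ_s′ T(s,a,s′) R(s,a,s′) with empirical T, which
equals the direct sample mean of rewards observed at (s, a); level 3 with
γ = 0 reduces exactly to level 2, a structural identity the tests exercise.

### Reward

Self-reported effort e ∈ {0,…,10} maps to r ∈ [−1, 1] piecewise-linearly,
anchored at the training-batch mean effort ē: r = −1 + e/ē for e < ē,
r = 1 − (10−e)/(10−ē) for e > ē, r = 0 at e = ē. The map is continuous at
ē and nondecreasing; it treats "one scale point above the mean" and "one
point below" symmetrically in proportion to the available headroom. ē is
frozen with the training batch and rejected outside (0, 10), where a branch
degenerates.

### State abstraction

The ten raw 5-point questionnaire answers are binarized at their per-feature
training-batch means (value ≥ mean → 1). Three bits are then selected by an
action-value relevance score: for each candidate bit f, the two-state MDP
induced by f alone is estimated and scored as Σ_a |V(f=1, a) − V(f=0, a)|,
where V is the per-side mean reward (level 2) or the single-bit Q-value at
γ (levels 3–4). The top three scores are kept, ordered score-descending
into bit significance; ties break to the lowest feature index. A constant
bit scores exactly 0. This is a deliberately flat selection — it captures
the "does this bit change action values" test of recursive
state-abstraction algorithms without growing their tree, because the target
state space is fixed at 2³ = 8. Thresholds and the selection are frozen
with the training batch, mirroring ē.

### Similarity weighting

Each person is a six-dimensional trait vector (five personality dimensions
on a 1–7 instrument scale, stage-of-change for physical activity on 1–5),
min–max scaled to [0, 1] by the instrument bounds rather than the observed
sample extremes, so vectors are stable as the cohort grows (a configurable
choice). For a target person, Euclidean distances to every person in the
bank map linearly to similarities (smallest distance → 1, largest → 0);
when all distances coincide — including a single-person bank — similarities
are all 1 and the personalized level collapses onto the unweighted one. Per
contributor j, the weight is w_j = max(s_j/Σ_k s_k, 0.0001); the floor
keeps every sample minimally influential. The mapping between the extremes
is linear; that reading is isolated in `pairwise_similarity` if an
alternative is ever wanted. A target person present in the bank contributes
at distance 0.

## Numerical choices

- Value iteration: Q initialized at 0, synchronous sweeps, stopping when the
  sup-norm change is below tol·(1−γ)/γ, which by the contraction bound
  guarantees the returned table is within tol (default 1e−9) of the true
  fixed point — far below any decision margin at this scale. Output is
  deterministic and order-invariant.
- Unvisited (s, a) cells: reward 0 (the neutral reward of a mean-effort
  response) and a uniform next-state row. This keeps value iteration
  well-defined and is unbiased under the reward centering.
- Ties between action values (within 1e−12) are all recorded in
  `argmax_sets`; the chosen action is either the canonical-order minimum
  (deterministic mode) or uniform among maximizers (the mode the agreement
  analysis prescribes). Canonical order is commitment, consensus, authority,
  action planning, no persuasion.
- Estimated cell rewards are means of values in [−1, 1] and are asserted,
  not clipped.

## Synthetic cohorts

The simulator emulates the published persuasion-log schema: per person, five
sessions, each with ten raw state answers, an assigned activity (id + type),
a persuasion type, and the effort later reported for it; plus a companion
trait table. Ground truth is a per-(state, action) mean-effort table in
[0, 10], a next-state kernel, and Gaussian effort noise rounded and clipped
to the 0–10 integer scale. Protocol rules are enforced: random persuasion
types in sessions 1–2 (the training data), one activity of each type in
sessions 1–2 and again in 3–4 in random order, a random type in session 5,
and no activity — nor any member of its declared similarity group — ever
repeated for a person. Dropout is per-session Bernoulli (default 0; later
sessions are simply absent). Trait-cluster effects can plant populations
whose best actions differ, the situation the similarity-weighted level
exists to exploit.

Defaults are chosen to resemble the study conditions: 516 people (the size
of the trained batch), five sessions, effort noise SD 2.5 (the order of the
effort SDs reported on this 0–10 scale). Three designated "signal" answers
carry the latent state bits (high answers {4, 5} for bit 1, low {1, 2} for
bit 0, so binarization at the mean recovers them); the remaining seven are
uniform noise. What the simulator does *not* emulate: item-level response
styles and correlated answers, time trends such as novelty effects, informed
dropout, or any natural-language content. Tests passing on these cohorts
therefore validate the estimation and decision machinery, not the
behavioral realism of any particular dataset.

Note that feature selection defines the state numbering by score order, so
a recovered policy matches a planted one up to the induced bit permutation;
the tests map planted optima through that permutation explicitly.

## Agreement analysis

To ask whether optimal policies transfer between activity types, the
analysis draws 1,000 transitions per included type without replacement
(2,000 when pooling both), computes the level's optimal policy with uniform
random tie-breaking, repeats 100 times, and concatenates the per-state
choices into one label list per data type. Lists are compared with Cohen's
κ (expected agreement from the two lists' marginal frequencies) and
interpreted on the Landis–Koch bands (<0 poor, 0–0.20 slight, 0.21–0.40
fair, 0.41–0.60 moderate, 0.61–0.80 substantial, 0.81–1.00 almost perfect).
Two identical constant lists have undefined chance-corrected agreement and
are defined here as κ = 1. Reference analyses compare two independent
resamples of the same data type, an upper bound on attainable agreement.
Level-4 policies are collapsed to a single reference person — by default
the component-wise median trait vector of the cohort — which is an explicit
configuration, not a claim about how any particular study did it. Drawing
without replacement is likewise a configurable reading (`replace=True`
flips it).

## Power and sample-size calibrations

`bayes_power` simulates two conditions of standard-normal outcomes with a
true mean difference δ and computes, per simulated experiment, the
directional Bayes factor for "the second mean is larger". The BF is
constructed from an improper flat prior on the mean difference with pooled
variance: the posterior of the difference is a scaled t, p = P(μ₂ − μ₁ > 0 |
data), BF = p/(1 − p). Under equal prior odds BF ≥ 19 is equivalent to
p ≥ 0.95, which makes the Monte-Carlo power equal (in expectation) to the
closed-form one-sided power Φ(δ√(n/2) − z₀.₉₅); the suite asserts that
equivalence. At the design point n = 129, δ = 0.3, 500 simulations, the
power is ≈ 0.78.

`regression_sample_size` implements Cohen's noncentral-F rule for multiple
regression. The required noncentrality L is solved from the noncentral
chi-square power equation (the large-denominator-df limit his tables
tabulate) rather than hard-coded; n = ceil(L/f² + u) with a `plus-one`
convention flag, floored at u + 2 (the smallest n with a residual degree of
freedom). Three predictors, medium effect (f² = 0.15), α = 0.05, power 0.80
give n = 76, and ×5 actions 380.

`q_error_study` quantifies estimation error versus training-set size:
reference Q-values and the reference-optimal policy come from the full
transition set; per size and repetition, a uniform subsample without
replacement is re-estimated and two errors recorded — the mean |Q̂ − Q| over
the 40 (s, a) cells, and the mean per-state reference-Q gap between the
subsample's greedy action and the reference-optimal action. Both are 0 at
the full size by construction and decrease with size in expectation.

## Problem sizes used in the test suite

The suite works at sizes chosen to make the statistical checks decisive:
planted-policy recovery and parameter-recovery tests use cohorts of up to
2,500 people (≈10,000 transitions, effort margin 2 points, noise SD 1);
the Q-error study runs on a 2,366-transition synthetic log with 20
repetitions per size; the tie-break uniformity check uses 500 repetitions;
value iteration is validated against a 200-step backward-induction oracle
on 100 random dense MDPs within the analytic tail bound γ²⁰⁰/(1−γ) + tol.

## Known limitations

- The estimators are tabular; with 8 states × 5 actions × 8 next states,
  cohorts much below a few hundred transitions leave many cells at their
  neutral defaults, and level differences become tie-break noise.
- The similarity model is a single global metric over six traits; it cannot
  express trait-action interactions beyond what the weighted reestimation
  picks up, and the floor means very dissimilar people still leak a little
  influence into every personal policy.
- Feature selection is greedy and marginal (one bit at a time); bits that
  are informative only jointly can be missed. This is intentional — the
  abstraction targets a fixed 2³ state space.
- The agreement analysis inherits the reference-person choice for level 4;
  per-person policy lists would need a different aggregation.
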